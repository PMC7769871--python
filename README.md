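# pigamu

Defined-daily-dose antimicrobial usage (AMU) monitoring for farrow-to-finish
pig farms.

National AMU monitoring programmes quantify prescribed antimicrobials not by
raw ingredient mass but as numbers of **defined daily doses** — here the
Swiss variant, DDDch, the assumed average daily maintenance dose in
mg per kg bodyweight of an antimicrobial for its main indication in pigs.
For a prescription allocated to one age category,

```
nDDDch = ingredient mass (mg) / (DDDch (mg/kg) × standard weight (kg))
```

with the ESVAC standard weights of 4 kg (piglets), 12 kg (weaners), 50 kg
(fatteners) and 220 kg (sows). Per-ingredient terms are summed per farm,
age category and antimicrobial class; dividing a category total by the
number of animals kept (sows) or produced per year (all other categories)
gives **nDDDch/animal/year**, an estimate of potential treatment days per
animal, and the four category values sum to a farm total per animal.

The package is aimed at veterinary epidemiologists and herd-health
monitoring programmes. It provides:

- **formulary** — validated reference data: DDDch registry keyed by
  (ingredient, route/formulation), product compositions (combination
  products carry one component per ingredient), standard weights, and the
  WHO highest-priority critically important antimicrobial (HPCIA) classes
  (cephalosporins, fluoroquinolones, macrolides, polypeptides). DDDch
  values are user configuration; the packaged demo formulary is
  illustrative, not the national reference.
- **quantification** — `quantify` and `per_animal_year`, with strict
  handling of unknown products/doses and of zero census denominators.
- **reporting** — category and antimicrobial-class distribution tables
  under both metrics (nDDDch vs. ingredient mass), HPCIA shares, and
  descriptive statistics with a t-based 95% CI.
- **inference** — Kruskal–Wallis across age categories (tie-corrected, with
  an exact/Monte-Carlo permutation option), Bonferroni-corrected pairwise
  post-hoc tests, and the seven simple linear regressions (six within-herd
  category pairs plus herd size → farm total) with adjusted R² and
  residual diagnostics.
- **synthetic** — a calibrated cohort generator (zero-inflated lognormal
  usage, truncated-lognormal herd sizes, latent links between sow and
  piglet usage and between herd size and total usage) whose emitted
  prescription records round-trip exactly through the pipeline.

## Worked example

```
pigamu simulate --n-farms 71 --seed 1 --out demo
pigamu run --formulary demo/formulary --usage demo/usage.csv \
           --census demo/census.csv --out out
```

The first command writes a 71-farm synthetic cohort (876 prescription
records with this seed) plus a provenance JSON; the second quantifies it
and writes the full report bundle. With seed 1:

- `out/category_distribution.csv` starts
  `piglet,257978.27,...` — piglets account for 46% of all defined daily
  doses but only 8% of ingredient mass, the signature divergence of the
  two metrics (light animals, many doses).
- `out/regressions.csv` reports `sow->piglet` slope 0.43, p = 0.007,
  adj. R² = 0.088 and `herd_size->total` slope 0.049, p = 0.003,
  adj. R² = 0.109 — in this cohort only the sow–piglet and herd-size
  models are significant, the other five within-herd pairs are not.
- `out/descriptives_per_animal.csv` gives per-category medians of
  0.62 / 0.77 / 0.07 / 1.83 nDDDch/animal/year (piglets / weaners /
  fatteners / sows): sows are treated most per animal, fatteners least.
- `out/manifest.json` records an HPCIA share of 20.0% of all defined
  daily doses, alongside input checksums and the run configuration.

The same pipeline runs on real data by pointing `--formulary` at a
directory with the documented `weights.csv` / `dddch.csv` / `products.csv`
tables and `--usage`/`--census` at the corresponding records.

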