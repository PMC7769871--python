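ingredient,class,route,dose_mg_per_kg,hpcia
amoxicillin,penicillins,injectable,20,0
amoxicillin,penicillins,oral_other,40,0
sulfadimidine,sulfonamides,oral_premix,25,0
trimethoprim,trimethoprim,oral_premix,5,0
chlortetracycline,tetracyclines,oral_premix,40,0
tulathromycin,macrolides,injectable,2.5,1
colistin,polypeptides,oral_other,5,1
ceftiofur,cephalosporins,injectable,3,1
enrofloxacin,fluoroquinolones,injectable,5,1
gentamicin,aminoglycosides,injectable,4,0
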