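product_id,ingredient,concentration_mg_per_unit,unit,route
amoxi_inject,amoxicillin,100,ml,injectable
amoxi_oral,amoxicillin,500,g,oral_other
sulfatrim_premix,sulfadimidine,100,g,oral_premix
sulfatrim_premix,trimethoprim,20,g,oral_premix
ctc_premix,chlortetracycline,150,g,oral_premix
tula_inject,tulathromycin,100,ml,injectable
colistin_oral,colistin,120,g,oral_other
ceftiofur_inject,ceftiofur,50,ml,injectable
enro_inject,enrofloxacin,50,ml,injectable
genta_inject,gentamicin,40,ml,injectable
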