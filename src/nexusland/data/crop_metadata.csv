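crop_id,group,switchable,dry_fraction,kcal_per_kg_dry,loss_fraction,fert_n_kg_ha,base_yield_t_ha
barley,cereal,True,0.87,3320,0.05,110,4.5
groundnut,oil,True,0.94,5670,0.06,20,2.8
maize,cereal,True,0.86,3650,0.05,160,12.0
millet,cereal,True,0.89,3400,0.06,60,2.0
potato,root,True,0.21,3670,0.08,120,32.0
rapeseed,oil,True,0.92,5450,0.05,140,3.2
rice,cereal,True,0.87,3690,0.06,130,6.5
sorghum,cereal,True,0.89,3390,0.06,80,4.0
soybean,oil,True,0.91,4460,0.05,25,3.0
sunflower,oil,True,0.93,5700,0.06,60,2.4
wheat,cereal,True,0.87,3340,0.05,140,5.0
sugarbeet,sugar,False,0.23,3870,0.07,120,70.0
vegetables,vegetable,False,0.10,2500,0.10,150,25.0
pulses,pulse,False,0.89,3450,0.06,15,2.5
olives_fruit,woody,False,0.35,2800,0.08,50,6.0
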