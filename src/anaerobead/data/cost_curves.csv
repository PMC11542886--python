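item,base_cost_usd2021,base_size,unit,exponent,install_factor,lifetime_yr,source
concrete,600,1,m3,1.0,1.3,30,placeholder unit price incl. formwork
rockwool,250,1,m3,1.0,1.2,30,placeholder insulation board price
carbon_steel,2.5,1,kg,1.0,1.4,30,placeholder plate steel price
stainless_steel,6.0,1,kg,1.0,1.4,30,placeholder 304 SS price
hdpe,3.0,1,kg,1.0,1.3,30,placeholder pipe resin price
peg_encapsulant,12.0,1,kg,1.0,1.0,30,placeholder PEG hydrogel bead price
water_pump,6000,50,m3/d,0.6,1.5,15,placeholder centrifugal pump curve
heat_exchanger,15000,50,kW,0.7,1.5,15,placeholder plate HX curve
vacuum_pump,8000,5,kW,0.6,1.5,15,placeholder liquid-ring pump curve
membrane_contactor,400,1,m2,1.0,1.5,10,placeholder hollow-fiber module price
gas_holder,20000,100,Nm3/d,0.6,1.4,15,placeholder double-membrane holder curve
iron_sponge_scrubber,5000,100,Nm3/d,0.6,1.4,15,placeholder H2S scrubber curve
control_system,20000,1,unit,0.05,1.2,15,placeholder PLC and instrumentation
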