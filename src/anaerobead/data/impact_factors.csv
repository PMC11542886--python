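flow,unit,category,factor,source
concrete,m3,GWP100,300.0,placeholder structural concrete cradle-to-gate
rockwool,m3,GWP100,120.0,placeholder mineral wool cradle-to-gate
carbon_steel,kg,GWP100,1.9,placeholder hot-rolled steel cradle-to-gate
stainless_steel,kg,GWP100,4.5,placeholder 304 SS cradle-to-gate
hdpe,kg,GWP100,1.9,placeholder HDPE granulate cradle-to-gate
peg_encapsulant,kg,GWP100,3.4,placeholder polyethylene-glycol hydrogel cradle-to-gate
membrane_contactor,m2,GWP100,15.0,placeholder polymeric module cradle-to-gate
equipment,USD,GWP100,0.4,placeholder economic input-output proxy per 2021 USD
electricity,kWh,GWP100,0.440506,grid factor derived from 0.79 kWh per kg COD at 348 kg CO2eq per tonne
natural_gas,MJ,GWP100,0.0686,placeholder NG supply plus combustion per MJ LHV
natural_gas_offset,MJ,GWP100,0.018,placeholder NG well-to-gate supply chain per MJ LHV displaced
fugitive_ch4,kg,GWP100,28.0,GWP100 of methane (configurable)
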