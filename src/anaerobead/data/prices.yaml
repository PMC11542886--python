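# Energy prices, financial settings and physical constants (2021 USD basis).
# All values are editable stand-ins documented in docs/methods.md.
electricity_usd_per_kwh: 0.08
natural_gas_usd_per_mj: 0.005
discount_rate: 0.05
project_years: 30
maintenance_fraction: 0.025   # of installed capital per year
boiler_efficiency: 0.80
pump_efficiency: 0.70
compressor_efficiency: 0.65
ch4_lhv_mj_per_kg: 50.0
h2_lhv_mj_per_kg: 120.0
ch4_lhv_mj_per_nm3: 35.8
biogas_leak_fraction: 0.02    # uncollected fraction of produced biogas
degassing_efficiency: 0.85    # effluent membrane contactor CH4 recovery
ch4_gwp100: 28.0
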