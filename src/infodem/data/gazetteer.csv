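surface_form,country
italy,IT
italian,IT
rome,IT
milan,IT
turin,IT
naples,IT
venice,IT
bologna,IT
florence,IT
bergamo,IT
lombardy,IT
veneto,IT
united kingdom,GB
uk,GB
britain,GB
great britain,GB
british,GB
england,GB
scotland,GB
wales,GB
london,GB
manchester,GB
liverpool,GB
glasgow,GB
edinburgh,GB
leeds,GB
bristol,GB
united states,US
usa,US
america,US
american,US
new york,US
los angeles,US
chicago,US
houston,US
seattle,US
boston,US
miami,US
san francisco,US
philadelphia,US
texas,US
california,US
florida,US
canada,CA
canadian,CA
toronto,CA
montreal,CA
vancouver,CA
ottawa,CA
calgary,CA
edmonton,CA
winnipeg,CA
quebec,CA
ontario,CA
alberta,CA
china,CN
chinese,CN
wuhan,CN
beijing,CN
shanghai,CN
hubei,CN
guangzhou,CN
shenzhen,CN
hong kong,CN
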