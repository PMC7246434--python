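# Fleet-average road-transport emission factors, g per vehicle-km.
# COPERT 4 v10.0 / EMEP-EEA style averages over all road types for the
# Catalan licensed passenger-car fleet (2012 fleet, 2013 emission guide).
# Editable for other fleets or reference years. Keys are quoted because
# bare NO/N2O would parse as YAML 1.1 booleans.
"NOx": 0.8287
"PM10": 0.0397
"PM2.5": 0.0339
"PM": 0.0265
"CO": 3.4391
"NH3": 0.0201
"VOC": 0.31
"NMVOC": 0.2887
"CH4": 0.0212
"NO": 0.6666
"NO2": 0.1621
"N2O": 0.0058
"SO2": 0.15
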