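lulc,1996,2000,2005,2010,2015,2018
paddy_field,27.12,26.73,23.76,17.43,16.54,16.31
dry_land,22.39,22.03,18.38,20.50,19.20,18.81
woodland,9.05,9.08,11.85,12.34,12.09,11.97
grassland,0.81,0.81,0.03,0.00,0.00,0.00
river_lake,12.20,12.21,13.17,12.92,12.87,12.85
natural_wetland,2.85,2.84,2.86,1.98,1.96,1.95
manmade_wetland,8.19,8.38,10.53,14.31,13.52,13.25
builtup,14.93,15.52,17.87,19.99,23.36,24.41
unused,2.46,2.42,1.55,0.53,0.45,0.44
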