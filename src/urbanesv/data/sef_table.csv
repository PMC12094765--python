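lulc,1996,2000,2005,2010,2015,2018
paddy_field,0.0462,0.0460,0.0399,0.0245,0.0205,0.0182
dry_land,0.0397,0.0394,0.0324,0.0301,0.0239,0.0212
woodland,0.0867,0.0866,0.1086,0.0923,0.0791,0.0702
grassland,0.0056,0.0057,0.0002,0.0000,0.0000,0.0000
river_lake,0.6686,0.6669,0.7214,0.5875,0.5106,0.4508
natural_wetland,0.0653,0.0656,0.0668,0.0387,0.0312,0.0279
manmade_wetland,0.1474,0.1508,0.1868,0.2123,0.1696,0.1512
builtup,0.0598,0.0612,0.0705,0.0665,0.0657,0.0618
unused,0.0002,0.0002,0.0001,0.0000,0.0000,0.0000
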