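lulc,AP,RM,WS,GR,CR,EP,HR,SR,NC,BC,AL
dry_land,0.85,0.4,0.02,0.67,0.36,0.1,0.27,1.03,0.12,0.13,0.06
paddy_field,1.36,0.09,-2.63,1.11,0.57,0.17,2.72,0.01,0.19,0.21,0.09
woodland,0.25,0.58,0.30,1.90,5.67,1.67,3.84,2.31,0.18,2.10,0.92
grassland,0.30,0.45,0.25,1.56,4.12,1.36,3.02,1.90,0.15,1.73,0.76
river_lake,0.80,0.23,8.29,0.77,2.29,5.55,102.24,0.93,0.07,2.55,1.89
natural_wetland,0.51,0.50,2.59,1.90,3.60,3.60,24.23,2.31,0.18,7.87,4.73
manmade_wetland,0.50,0.36,3.42,1.75,3.49,3.02,15.75,0.90,0.15,6.77,4.26
builtup,-0.01,0.03,-0.34,-0.56,0.01,-2.50,-5.63,0.02,-0.20,0.10,0.11
unused,0.00,0.00,0.00,0.02,0.00,0.10,0.03,0.02,0.00,0.02,0.01
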