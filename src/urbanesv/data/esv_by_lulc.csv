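year,lulc,esv_billion,share_pct
1996,paddy_field,3.8,4.62
1996,dry_land,3.27,3.97
1996,woodland,7.13,8.67
1996,grassland,0.46,0.56
1996,river_lake,54.97,66.86
1996,natural_wetland,5.37,6.53
1996,manmade_wetland,12.12,14.74
1996,builtup,-4.92,-5.98
1996,unused,0.02,0.02
1996,total,82.21,100
2000,paddy_field,3.79,4.6
2000,dry_land,3.25,3.94
2000,woodland,7.14,8.67
2000,grassland,0.47,0.57
2000,river_lake,54.96,66.68
2000,natural_wetland,5.41,6.56
2000,manmade_wetland,12.43,15.08
2000,builtup,-5.04,-6.12
2000,unused,0.02,0.02
2000,total,82.42,100
2005,paddy_field,3.25,3.68
2005,dry_land,2.63,2.98
2005,woodland,8.83,10
2005,grassland,0.02,0.02
2005,river_lake,58.69,66.44
2005,natural_wetland,5.43,6.15
2005,manmade_wetland,15.2,17.21
2005,builtup,-5.74,-6.49
2005,unused,0.01,0.01
2005,total,88.34,100
2010,paddy_field,2.52,2.67
2010,dry_land,3.1,3.28
2010,woodland,9.5,10.04
2010,grassland,0,0
2010,river_lake,60.49,63.93
2010,natural_wetland,3.99,4.22
2010,manmade_wetland,21.85,23.1
2010,builtup,-6.85,-7.24
2010,unused,0,0
2010,total,94.61,100
2015,paddy_field,2.69,2.67
2015,dry_land,3.14,3.11
2015,woodland,10.35,10.28
2015,grassland,0,0
2015,river_lake,66.84,66.37
2015,natural_wetland,4.09,4.06
2015,manmade_wetland,22.2,22.05
2015,builtup,-8.6,-8.54
2015,unused,0,0
2015,total,100.7,100
2018,paddy_field,2.66,2.68
2018,dry_land,3.11,3.13
2018,woodland,10.3,10.36
2018,grassland,0,0
2018,river_lake,66.14,66.53
2018,natural_wetland,4.09,4.11
2018,manmade_wetland,22.18,22.31
2018,builtup,-9.06,-9.11
2018,unused,0,0
2018,total,99.42,100
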