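region,year,lulc,area_ha
Wuhan,1996,paddy_field,232424
Wuhan,1996,dry_land,191904
Wuhan,1996,woodland,77584
Wuhan,1996,grassland,6901
Wuhan,1996,river_lake,104530
Wuhan,1996,natural_wetland,24400
Wuhan,1996,manmade_wetland,70202
Wuhan,1996,builtup,127926
Wuhan,1996,unused,21044
Wuhan,2000,paddy_field,229036
Wuhan,2000,dry_land,188737
Wuhan,2000,woodland,77784
Wuhan,2000,grassland,6901
Wuhan,2000,river_lake,104621
Wuhan,2000,natural_wetland,24304
Wuhan,2000,manmade_wetland,71810
Wuhan,2000,builtup,132954
Wuhan,2000,unused,20768
Wuhan,2005,paddy_field,203638
Wuhan,2005,dry_land,157486
Wuhan,2005,woodland,101566
Wuhan,2005,grassland,283
Wuhan,2005,river_lake,112853
Wuhan,2005,natural_wetland,24504
Wuhan,2005,manmade_wetland,90230
Wuhan,2005,builtup,153111
Wuhan,2005,unused,13244
Wuhan,2010,paddy_field,149370
Wuhan,2010,dry_land,175703
Wuhan,2010,woodland,105739
Wuhan,2010,grassland,2
Wuhan,2010,river_lake,110734
Wuhan,2010,natural_wetland,16956
Wuhan,2010,manmade_wetland,122591
Wuhan,2010,builtup,171266
Wuhan,2010,unused,4554
Wuhan,2015,paddy_field,141773
Wuhan,2015,dry_land,164556
Wuhan,2015,woodland,103585
Wuhan,2015,grassland,2
Wuhan,2015,river_lake,110255
Wuhan,2015,natural_wetland,16819
Wuhan,2015,manmade_wetland,115822
Wuhan,2015,builtup,200218
Wuhan,2015,unused,3885
Wuhan,2018,paddy_field,139784
Wuhan,2018,dry_land,161204
Wuhan,2018,woodland,102573
Wuhan,2018,grassland,2
Wuhan,2018,river_lake,110117
Wuhan,2018,natural_wetland,16740
Wuhan,2018,manmade_wetland,113538
Wuhan,2018,builtup,209182
Wuhan,2018,unused,3775
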