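region,year,s
Dongxihu,1996,1.04
Dongxihu,2000,0.97
Dongxihu,2005,1.01
Dongxihu,2010,1.07
Dongxihu,2015,1.08
Dongxihu,2018,1.03
Hannan,1996,1.04
Hannan,2000,0.94
Hannan,2005,1.18
Hannan,2010,1.1
Hannan,2015,0.97
Hannan,2018,1.02
Caidian,1996,0.96
Caidian,2000,0.97
Caidian,2005,1.08
Caidian,2010,1.06
Caidian,2015,0.98
Caidian,2018,0.9
Jiangxia,1996,0.95
Jiangxia,2000,0.9
Jiangxia,2005,0.98
Jiangxia,2010,0.95
Jiangxia,2015,1.11
Jiangxia,2018,1.02
Huangpi,1996,1.01
Huangpi,2000,1.03
Huangpi,2005,1.01
Huangpi,2010,1.01
Huangpi,2015,1.12
Huangpi,2018,1.11
Xinzhou,1996,1.04
Xinzhou,2000,1.09
Xinzhou,2005,0.96
Xinzhou,2010,0.97
Xinzhou,2015,0.92
Xinzhou,2018,0.98
Jiangan,1996,1.04
Jiangan,2000,0.96
Jiangan,2005,1.02
Jiangan,2010,1.07
Jiangan,2015,1.03
Jiangan,2018,1.03
Jianghan,1996,1.04
Jianghan,2000,0.96
Jianghan,2005,1.02
Jianghan,2010,1.07
Jianghan,2015,1.03
Jianghan,2018,1.03
Qiaokou,1996,1.04
Qiaokou,2000,0.96
Qiaokou,2005,1.02
Qiaokou,2010,1.07
Qiaokou,2015,1.03
Qiaokou,2018,1.03
Hangyang,1996,1.04
Hangyang,2000,0.96
Hangyang,2005,1.02
Hangyang,2010,1.07
Hangyang,2015,1.03
Hangyang,2018,1.03
Wuchang,1996,1.04
Wuchang,2000,0.96
Wuchang,2005,1.02
Wuchang,2010,1.07
Wuchang,2015,1.03
Wuchang,2018,1.03
Qingshan,1996,1.04
Qingshan,2000,0.96
Qingshan,2005,1.02
Qingshan,2010,1.07
Qingshan,2015,1.03
Qingshan,2018,1.03
Hongshan,1996,1.04
Hongshan,2000,0.96
Hongshan,2005,1.02
Hongshan,2010,1.07
Hongshan,2015,1.03
Hongshan,2018,1.03
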