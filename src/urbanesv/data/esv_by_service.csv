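year,service,esv_billion,share_pct
1996,AP,2.67,3.24
1996,RM,0.91,1.11
1996,WS,2.30,2.80
1996,GR,3.12,3.79
1996,CR,5.45,6.63
1996,EP,3.24,3.94
1996,HR,53.24,64.76
1996,SR,2.67,3.25
1996,NC,0.34,0.41
1996,BC,5.14,6.25
1996,AL,3.15,3.83
1996,total,82.21,100.00
2000,AP,2.67,3.23
2000,RM,0.92,1.11
2000,WS,2.33,2.82
2000,GR,3.12,3.78
2000,CR,5.48,6.65
2000,EP,3.23,3.92
2000,HR,53.29,64.66
2000,SR,2.68,3.25
2000,NC,0.34,0.41
2000,BC,5.20,6.31
2000,AL,3.19,3.86
2000,total,82.42,100.00
2005,AP,2.42,2.73
2005,RM,0.91,1.03
2005,WS,3.17,3.59
2005,GR,3.08,3.49
2005,CR,6.02,6.82
2005,EP,3.47,3.93
2005,HR,56.81,64.31
2005,SR,2.75,3.11
2005,NC,0.30,0.34
2005,BC,5.83,6.60
2005,AL,3.58,4.05
2005,total,88.34,100.00
2010,AP,2.35,2.48
2010,RM,1.01,1.07
2010,WS,4.24,4.48
2010,GR,3.19,3.37
2010,CR,6.66,7.03
2010,EP,3.67,3.88
2010,HR,59.14,62.51
2010,SR,3.04,3.22
2010,NC,0.28,0.29
2010,BC,6.82,7.21
2010,AL,4.21,4.45
2010,total,94.61,100.00
2015,AP,2.47,2.45
2015,RM,1.07,1.06
2015,WS,4.53,4.49
2015,GR,3.27,3.25
2015,CR,7.08,7.03
2015,EP,3.57,3.55
2015,HR,63.67,63.23
2015,SR,3.22,3.19
2015,NC,0.26,0.26
2015,BC,7.14,7.09
2015,AL,4.42,4.39
2015,total,100.70,100.00
2018,AP,2.45,2.46
2018,RM,1.06,1.07
2018,WS,4.48,4.50
2018,GR,3.22,3.24
2018,CR,7.05,7.09
2018,EP,3.41,3.43
2018,HR,62.78,63.15
2018,SR,3.20,3.22
2018,NC,0.25,0.25
2018,BC,7.12,7.17
2018,AL,4.41,4.43
2018,total,99.42,100.00
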