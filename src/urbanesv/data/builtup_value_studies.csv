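study,AP,RM,WS,GR,CR,EP,HR,SR,NC,BC,AL
Chengdu,0,0,0,0,0,-2.28,-5.2,0,0,0,0
Dehua,0,0,0,-2.42,0,-2.46,-7.52,0,0,0,0.09
Xianyang,0,0,0,0,0,-2.34,-9.7,0,0,0,0
Henan,0.28,0.3,-3.71,0,0,-2.46,-5.35,0.02,0,0.34,1.2
Qinba,0,0,0,0,0,-1.53,-4.69,0,0,0,0
Shunde,0.01,0.03,-0.34,0.11,0.1,0.31,0.21,0.13,0.01,0.12,0.05
Hubei,0,0,0,0,0,-2.46,-7.55,0,0,0,0
Qinglong,0.01,0,0,0,0,-2.46,-7.51,0.02,0,0.34,0.01
Gaoyang,0,0,0,-1.6,0,-3.71,-3.48,0,0,0,0
Changsha,0,0,0,-0.22,,-9.09,-4.24,0,0,0,0
Wuhan,-0.38,0,0,-0.22,0,-1.56,-5.02,0,0,0,0
Tiantai,0.01,0,0,-2.42,0,0,-7.51,0.02,-2.46,0.34,0.01
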