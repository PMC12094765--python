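study,AP,RM,WS,GR,CR,EP,HR,SR,NC,BC,AL
Wuhan,1.05,1.05,,1.01,1.00,1.01,1.03,0.05,,0.91,0.24
Bengbu,2.19,,,1.37,,0.00,0.05,,,1.00,0.00
Hanshiqiao,0.85,0.85,0.85,0.85,0.85,0.85,0.85,0.85,0.85,0.85,1.95
Shanghai,0.51,,,,0.18,0.06,0.04,0.28,,0.18,0.84
Beijing,,,1.79,,1.78,1.84,1.20,,,2.16,
Haikou,0.34,0.23,,0.46,0.08,0.44,0.73,0.00,,0.03,0.58
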