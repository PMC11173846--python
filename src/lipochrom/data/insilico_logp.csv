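compound_id,ChA log P,Con log P,ALOGP,log P,Clog P,Mlog P,S+log P,S+log D,log D_5,log D_7,log D_8,log D_7.4
1,2.35,2.85,2.98,3.03,2.3173,1.664,1.664,2.596,2.85,2.72,2.13,2.366
2,2.69,3.21,3.02,3.38,2.9049,1.928,1.928,3.108,3.21,3.19,3.08,3.124
3,3.54,3.98,4.27,4.28,2.6716,2.647,2.647,4.009,3.98,3.95,3.73,3.818
4,3.79,4.20,4.02,4.52,4.1351,2.882,2.882,4.005,4.2,4.17,3.96,4.044
5,4.65,5.16,4.95,5.42,5.1131,3.337,3.337,4.590,5.16,5.15,5.03,5.078
6,2.51,2.54,2.81,,2.1569,1.871,1.871,2.909,2.54,2.51,2.30,2.384
7,3.03,3.14,3.51,,2.5473,2.127,2.127,2.770,3.14,3.02,2.46,2.684
8,3.37,3.50,3.36,,3.1349,2.377,2.377,3.467,3.50,3.48,3.38,3.42
9,2.31,2.45,3.06,3.42,2.6964,2.040,2.040,2.913,2.21,2.41,2.20,2.284
10,2.83,3.05,3.81,3.98,3.0865,2.281,2.281,2.953,2.81,2.92,2.36,2.584
11,1.81,2.03,2.87,3.48,2.2487,1.918,1.918,2.481,1.98,2.00,1.78,1.868
12,2.33,2.63,3.72,4.03,2.6387,2.161,2.161,2.736,2.49,2.53,1.93,2.17
13,2.19,2.46,2.34,3.12,1.2077,1.552,1.552,2.403,2.12,2.42,2.21,2.294
14,2.71,3.06,2.96,3.68,1.5977,1.789,1.789,2.895,2.72,2.93,2.37,2.594
15,4.80,5.45,5.14,6.14,4.9270,3.850,3.850,4.692,5.45,5.42,5.20,5.288
16,5.67,6.41,5.71,7.05,5.9050,4.262,4.262,5.167,6.41,6.39,6.28,6.324
17,5.67,6.41,5.72,7.05,5.9050,4.262,4.262,5.201,6.41,6.39,6.28,6.324
18,4.98,5.55,5.22,5.78,5.0844,3.485,3.485,4.832,5.55,5.42,4.85,5.078
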