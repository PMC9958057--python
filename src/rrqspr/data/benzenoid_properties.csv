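sno,BP,CT,CP,CV,GE,LogP,MR,HL,PI,MW,EM,HAC
1,80.1,323.79,47.69,263.5,121.68,2.03,25.28,0.66,8,78.11,78.04695,6
2,218,484.95,38.97,409.5,252.38,3.03,42.45,1.67,13.6832,128.17,128.0626,10
3,340,586.11,32.43,555.5,383.08,4.03,59.62,2.68,19.3137,178.23,178.0783,14
4,340,586.11,32.43,555.5,383.08,4.03,59.62,2.68,19.4483,178.23,178.0783,14
5,432.02,650.8,27.41,701.5,513.78,5.9,76.79,3.69,24.9308,228.3,228.0909,18
6,436.7,650.8,27.41,701.5,513.78,5.03,76.79,3.69,25.1875,228.3,228.0909,18
7,438,650.8,27.41,701.5,513.78,5.03,76.79,3.69,25.1012,228.3,228.0909,18
8,448,650.8,27.41,701.5,513.78,5.03,76.79,3.69,25.1922,228.3,228.0909,18
9,438,650.8,27.41,701.5,513.78,5.03,76.79,3.69,25.2745,228.3,228.0909,18
10,404,625.65,30.73,619.5,491.18,5.08,68.36,3.47,22.5055,202.25,202.0783,16
11,524.6,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.544,278.3,278.1096,22
12,547.5,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.7255,278.3,278.1096,22
13,524,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.8805,278.3,278.1096,22
14,524.7,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.8795,278.3,278.1096,22
15,547.5,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.7627,278.3,278.1096,22
16,525,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.999,278.3,278.1096,22
17,524.7,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.9386,278.3,278.1096,22
18,520,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.9432,278.3,278.1096,22
19,524.7,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.839,278.3,278.1096,22
20,518,714.53,23.47,847.5,644.48,6.02,93.96,4.7,30.9418,278.3,278.1096,22
21,400,689.17,26.08,765.5,621.88,5.34,85.53,4.48,28.2453,252.3,252.0939,20
22,467.5,689.17,26.08,765.5,621.88,5.34,85.53,4.48,28.3361,252.3,252.0939,20
23,495,689.17,26.08,765.5,621.88,5.34,85.53,4.48,28.222,252.3,252.0939,20
24,500,728.06,24.85,829.5,729.98,5.66,94.28,5.27,31.4251,276.3,276.0939,22
25,604,779.67,20.33,993.5,775.18,7.02,111.13,5.71,36.1557,328.4,328.1252,26
26,525,767.68,23.7,893.5,838.08,5.98,103.02,6.06,34.5718,300.4,300.0939,24
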