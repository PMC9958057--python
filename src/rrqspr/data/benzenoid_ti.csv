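sno,RRR_-1
1,1.5
2,2.2778
3,3.0556
4,3.0833
5,3.8333
6,3.8889
7,3.8611
8,3.8889
9,3.9167
10,3.8889
11,4.6111
12,4.6389
13,4.6667
14,4.6667
15,4.6389
16,4.7222
17,4.6944
18,4.6944
19,4.6667
20,4.6944
21,4.2222
22,3.9444
23,4.1944
24,4.5278
25,5.3889
26,4.8333
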