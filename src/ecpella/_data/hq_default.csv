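level,a,b,c
1,70.0,8.00,62.0000
2,80.0,8.00,35.1020
3,90.0,8.00,23.3333
4,100.0,8.00,17.0248
5,112.0,8.00,12.4005
6,124.0,8.00,9.6094
7,136.0,8.00,8.8163
8,148.0,8.00,8.6486
9,160.0,8.00,8.4681
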