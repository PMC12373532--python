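item_id,immediate_amount,delayed_amount,delay_days
1,54,55,117
2,55,75,61
3,19,25,53
4,31,85,7
5,14,25,19
6,47,50,160
7,15,35,13
8,25,60,14
9,78,80,162
10,40,55,62
11,11,30,7
12,67,75,119
13,34,35,186
14,27,50,21
15,69,85,91
16,49,60,89
17,80,85,157
18,24,35,29
19,33,80,14
20,28,30,179
21,34,50,30
22,25,30,80
23,41,75,20
24,54,60,111
25,54,80,30
26,22,25,136
27,20,55,7
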