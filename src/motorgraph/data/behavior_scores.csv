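subject_id,arat_pre,arat_post,hpt_pre,hpt_post
1,3,3,29.31,21.06
2,57,57,27.5,22.99
3,9,10,37.12,32.52
4,3,16,20.93,20.6
5,-,-,24.61,23.62
6,27,40,30.51,28.00
7,57,57,26.48,21.79
8,23,40,26.69,20.71
9,-,-,37.84,34.97
10,56,57,20.05,18.22
11,7,7,19.46,18.62
12,3,4,20.29,18.58
13,0,2,26.77,24.25
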