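group_size,k,count
10,0,22
10,1,14
10,2,19
10,3,11
10,4,4
10,5,10
10,6,8
10,7,2
10,8,2
10,9,0
10,10,0
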