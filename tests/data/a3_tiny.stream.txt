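# task: A3
# annotations: A,0,3;B,4,3;A,9,3;C,13,3;B,17,3
1 0 0 0
0 0 1 1
0 0 1 1
0 0 1 1
0 1 0 0
0 0 0 0
0 0 0 0
0 0 0 0
0 0 0 0
1 0 0 0
0 0 1 1
0 0 1 1
0 0 1 1
1 1 0 0
0 0 0 0
0 0 0 0
0 0 0 0
0 1 0 0
0 0 0 0
0 0 0 0
0 0 0 0
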