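x,y
0.0,1.0
1.0,1.8
2.0,1.3
3.0,3.7
4.0,2.9
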