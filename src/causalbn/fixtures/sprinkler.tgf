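1 R
2 S
3 W
#
1 2
1 3
2 3
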