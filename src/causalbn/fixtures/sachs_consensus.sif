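PKC pp Raf
PKC pp Mek
PKC pp JNK
PKC pp P38
PKC pp PKA
PKA pp Raf
PKA pp Mek
PKA pp ERK
PKA pp AKT
PKA pp JNK
PKA pp P38
Raf pp Mek
Mek pp ERK
ERK pp AKT
PLCg pp PIP2
PLCg pp PIP3
PIP3 pp PIP2
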