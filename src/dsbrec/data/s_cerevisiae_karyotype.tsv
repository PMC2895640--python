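name	size_kb
chrI	230
chrII	813
chrIII	315
chrIV	1532
chrV	577
chrVI	270
chrVII	1091
chrVIII	563
chrIX	440
chrX	745
chrXI	667
chrXII	1078
chrXIII	924
chrXIV	784
chrXV	1091
chrXVI	948
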