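# Default TYR1 heteroallele map for scoring Tyr+ recombinants.
#
# ty  = 5' truncation of the TYR1 ORF (nt 1-700)
# yr1 = 3' truncation (nt 300-1358); the two share a 400 bp overlap.
# TYR1 = full-length reconstituted ORF; y = overlap-only reciprocal product.
#
# Amplicon sizes are the printed diagnostic PCR product sizes; they are kept
# verbatim rather than recomputed from the ORF coordinates (the full-length
# amplicon includes 2 bp of primer-determined flank beyond the 1358 nt ORF).
tolerance_bp: 50
alleles:
  - name: TYR1
    start: 1
    end: 1358
    amplicon_bp: 1360
  - name: yr1
    start: 300
    end: 1358
    amplicon_bp: 1060
  - name: ty
    start: 1
    end: 700
    amplicon_bp: 700
  - name: y
    start: 300
    end: 700
    amplicon_bp: 400
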