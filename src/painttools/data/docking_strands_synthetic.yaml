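# SYNTHETIC default docking-strand library (Exchange-PAINT P-series naming
# convention). These 9-mers were generated once to be mutually orthogonal
# (self- and cross-complementary runs <= 3 bp, GC 3-5 of 9, no homopolymer
# run of 4) and are placeholders for a lab's published docking sequences:
# override with your own library via --docking-config / load_docking_library(path).
# The imager strand for each entry is the reverse complement (3'-dye by convention).
P0: GCTAAAGAC
P1: ACATACACG
P2: AACTTGTTG
P3: GAATCGCTT
P4: GACTGGCAT
P5: ACTCAGAAA
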