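# Synthetic position count table for the 16-bp bacterial parS motif,
# built around the quasi-palindromic consensus TGTTTCACGTGAAACA from a
# notional alignment of 1030 sites. Counts are self-reverse-complement
# symmetric (column i mirrors column 15-i under complementation); the
# two central-flank positions (5 and 12, 1-based) carry mild degeneracy.
# This is a stand-in training set, not the published parS alignment.
ID parS_synthetic
PO A C G T
01 0 0 0 1030
02 0 0 1030 0
03 0 0 0 1030
04 0 0 0 1030
05 4 3 3 1020
06 0 1030 0 0
07 1030 0 0 0
08 0 1030 0 0
09 0 0 1030 0
10 0 0 0 1030
11 0 0 1030 0
12 1020 3 3 4
13 1030 0 0 0
14 1030 0 0 0
15 0 1030 0 0
16 1030 0 0 0
XX
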