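# Named primer sets for in-silico amplification.
#
# universal_V4 is the standard eukaryote-wide 18S V4 metabarcoding pair
# (TAReuk454FWD1 / TAReukREV3, Stoeck et al. 2010), which frames the
# ~380-450 bp search space for guide design.  The non-metazoan and nested
# V4 pairs are alternative configurations for the same machinery.
#
# Primers are written 5'->3' as synthesized: the reverse primer is the
# reverse complement of its footprint on the template plus strand.
primers:
  universal_V4:
    forward_name: TAReuk454FWD1
    forward: CCAGCASCYGCGGTAATTCC
    reverse_name: TAReukREV3
    reverse: ACTTTCGTTCTTGATYRA
  nonmetazoan:
    forward_name: 18s-EUK581-F
    forward: GTGCCAGCAGCCGCG
    reverse_name: 18s-EUK1134-R
    reverse: TTTAAGTTTCAGCCTTGCG
  universal_V4_nested:
    forward_name: E572F
    forward: CYGCGGTAATTCCAGCTC
    reverse_name: E1009R
    reverse: AYGGTATCTRATCRTCTTYG

# sgRNA in-vitro-transcription template scheme: T7 promoter prepended 5' of
# the 20-nt target site, scaffold-overlap sequence appended 3'.  The overlap
# is the 14-nt anneal region to the scaffold oligo of single-tube sgRNA
# synthesis kits.
sgrna_template:
  promoter: TTCTAATACGACTCACTATAG
  overlap: GTTTTAGAGCTAGA
  require_leading_g: false
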