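# Default degenerate word set for DC5-like composite-site scanning.
#
# SYNTHETIC RECONSTRUCTION: the word set used in the original genome search
# was assembled manually from binding data and was never published; the
# words below are this package's own reconstruction anchored on the DC5
# element architecture (sox half-site CATTGT immediately followed by the
# degenerate pax half-site) and are labelled as such.  Replace with your own
# words for any real genomic analysis.
motifs:
  - id: dc5_like_strict
    sox_word: CATTGT
    pax_word: TGTTGC
    gap: 0
    pax_orientation: forward
    note: exact DC5 half-site juxtaposition (synthetic reconstruction)
  - id: dc5_like_degenerate
    sox_word: CWTTGT
    pax_word: TRTTGY
    gap: 0
    pax_orientation: forward
    note: degenerate DC5-like word admitting close variants (synthetic reconstruction)
  - id: sox_consensus
    sox_word: CWTTGTT
    pax_word: "N"
    gap: 0
    pax_orientation: forward
    note: sox consensus core alone, for sox-motif region fractions
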