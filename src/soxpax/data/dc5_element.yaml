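# Annotation of the 31-bp DC5 duplex (forward strand).
#
# The half-site boundary between the sox and pax words is figure-derived:
# it was read off published element diagrams, not stated as text, and is
# recorded here with that caveat.  Coordinates are 0-based half-open on the
# forward oligo.
element: DC5
forward: TTCATTGTTGTTGCTCACCTACCATGGATCC
reverse: GGATCCATGGTAGGTGAGCAACAACAATGAA
length: 31
sox_span: [2, 8]     # CATTGT
pax_span: [8, 14]    # TGTTGC (degenerate pax half-site start; figure-derived)
gap: 0
provenance: half-site spans are figure-derived annotations, not printed coordinates
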