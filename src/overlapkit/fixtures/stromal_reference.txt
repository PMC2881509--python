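# Collagen genes flagged as members of the knockout-stroma upregulated set
# (union of the flagged rows across the three collagen panels).
COL11A1
COL5A1
COL1A2
COL3A1
COL4A5
COL6A3
COL6A1
COL9A1
COL4A6
COL1A1
COL5A3
COL16A1
COL24A1
COL4A2
COL18A1
COL9A2
COL14A1
COL23A1
COL11A2
COL2A1
COL27A1
COL4A3
COL19A1
COL4A1
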