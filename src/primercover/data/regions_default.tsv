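# Default 16S rRNA region boundaries, E. coli numbering (positions 1-1542).
# 10 conserved (C1-C10) and 9 hypervariable (V1-V9) regions tiling the gene.
# Editable configuration: boundaries follow the coordinates in common use for
# the E. coli reference; reports always cite the active table.
# label	start	end
C1	1	68
V1	69	99
C2	100	136
V2	137	242
C3	243	432
V3	433	497
C4	498	575
V4	576	682
C5	683	821
V5	822	879
C6	880	985
V6	986	1043
C7	1044	1116
V7	1117	1173
C8	1174	1242
V8	1243	1294
C9	1295	1434
V9	1435	1465
C10	1466	1542
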