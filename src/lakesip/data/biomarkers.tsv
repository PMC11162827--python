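# PLFA biomarker map: which taxon group a fatty acid is characteristic of.
# ambiguous = True marks biomarkers shared between groups (interpret with care).
fame	group	ambiguous
i15:0	gram-positive / Verrucomicrobia	False
a15:0	gram-positive / Verrucomicrobia	False
16:1w7	gram-negative Proteobacteria / Acidobacteria	False
18:1w7	gram-negative Proteobacteria / Acidobacteria	False
18:2w6	fungi	False
18:3w3	fungi	False
18:1w9	fungi / Planctomycetes	True
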