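# Pairwise duplication-evidence grid for the seven dopamine receptor families,
# transcribed cell-for-cell in printed column order. Columns: microsynteny at the
# 2 Mb and 12 Mb panel widths, per-gene syntenic lookup (SynFind-style), genome-wide
# synteny under the colinear and density algorithms, and human-paralogon overlap.
pair	micro_2Mb	micro_12Mb	synfind	synmap_colinear	synmap_density	paralogy
DRD1A/DRD1B	Y	Y	Y	Y	Y	Y
DRD1A/DRD1C	Y	Y	Y	Y	Y	N
DRD1A/DRD1E	Y	Y	Y	Y	N	N
DRD1B/DRD1C	Y	Y	N	Y	Y	N
DRD1B/DRD1E	Y	Y	N	Y	N	N
DRD1C/DRD1E	Y	Y	N	N	N	N
DRD2/DRD3	N	Y	N	Y	N	Y
DRD2/DRD4	N	N	N	N	N	N
DRD3/DRD4	N	N	N	N	N	N
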