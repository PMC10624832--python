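# Per-methyl-type chemical-shift standard deviations used to scale methyl
# CSPs into SD units: alpha_h = 1H SD (ppm), beta_c = 13C SD (ppm).
# Representative values derived from BMRB chemical-shift statistics
# (www.bmrb.wisc.edu); editable configuration, not ground truth.
methyl_type	alpha_h	beta_c
ALA-CB	0.27	1.90
ILE-CD1	0.29	1.70
ILE-CG2	0.25	1.40
LEU-CD	0.28	1.60
LEU-CD1	0.28	1.60
LEU-CD2	0.29	1.70
VAL-CG	0.26	1.40
VAL-CG1	0.26	1.40
VAL-CG2	0.27	1.50
THR-CG2	0.22	1.10
MET-CE	0.41	1.60
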