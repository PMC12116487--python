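label	theta_deg	phi_deg	r_mm
F1	109.348	47.737	85.0
Fz	90.000	54.000	85.0
F2	70.652	47.737	85.0
FC1	129.967	63.914	85.0
FC2	50.033	63.914	85.0
C1	180.000	72.000	85.0
Cz	0.000	90.000	85.0
C2	0.000	72.000	85.0
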