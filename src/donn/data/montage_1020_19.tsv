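label	theta_deg	phi_deg	r_mm
Fp1	108.000	18.000	85.0
Fp2	72.000	18.000	85.0
F7	144.000	18.000	85.0
F3	123.859	38.993	85.0
Fz	90.000	54.000	85.0
F4	56.141	38.993	85.0
F8	36.000	18.000	85.0
T7	180.000	18.000	85.0
C3	180.000	54.000	85.0
Cz	0.000	90.000	85.0
C4	0.000	54.000	85.0
T8	0.000	18.000	85.0
P7	-144.000	18.000	85.0
P3	-123.859	38.993	85.0
Pz	-90.000	54.000	85.0
P4	-56.141	38.993	85.0
P8	-36.000	18.000	85.0
O1	-108.000	18.000	85.0
O2	-72.000	18.000	85.0
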