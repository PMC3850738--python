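#name SYNQC
# Synthetic quasi-chemical-style residue contact energies (arbitrary units).
# Values are derived from the Kyte-Doolittle hydropathy scale as
# e_ij = -0.60 - 0.12*(h_i + h_j), giving favourable (negative) energies
# for hydrophobic-hydrophobic contacts and mildly unfavourable ones for
# polar pairs. This is generated stand-in data, not a published matrix.
#representative min_heavy_atom
#bins 0:5
ALA ALA 0 -1.0320
ALA ARG 0 -0.2760
ALA ASN 0 -0.3960
ALA ASP 0 -0.3960
ALA CYS 0 -1.1160
ALA GLN 0 -0.3960
ALA GLU 0 -0.3960
ALA GLY 0 -0.7680
ALA HIS 0 -0.4320
ALA ILE 0 -1.3560
ALA LEU 0 -1.2720
ALA LYS 0 -0.3480
ALA MET 0 -1.0440
ALA PHE 0 -1.1520
ALA PRO 0 -0.6240
ALA SER 0 -0.7200
ALA THR 0 -0.7320
ALA TRP 0 -0.7080
ALA TYR 0 -0.6600
ALA VAL 0 -1.3200
ARG ARG 0 0.4800
ARG ASN 0 0.3600
ARG ASP 0 0.3600
ARG CYS 0 -0.3600
ARG GLN 0 0.3600
ARG GLU 0 0.3600
ARG GLY 0 -0.0120
ARG HIS 0 0.3240
ARG ILE 0 -0.6000
ARG LEU 0 -0.5160
ARG LYS 0 0.4080
ARG MET 0 -0.2880
ARG PHE 0 -0.3960
ARG PRO 0 0.1320
ARG SER 0 0.0360
ARG THR 0 0.0240
ARG TRP 0 0.0480
ARG TYR 0 0.0960
ARG VAL 0 -0.5640
ASN ASN 0 0.2400
ASN ASP 0 0.2400
ASN CYS 0 -0.4800
ASN GLN 0 0.2400
ASN GLU 0 0.2400
ASN GLY 0 -0.1320
ASN HIS 0 0.2040
ASN ILE 0 -0.7200
ASN LEU 0 -0.6360
ASN LYS 0 0.2880
ASN MET 0 -0.4080
ASN PHE 0 -0.5160
ASN PRO 0 0.0120
ASN SER 0 -0.0840
ASN THR 0 -0.0960
ASN TRP 0 -0.0720
ASN TYR 0 -0.0240
ASN VAL 0 -0.6840
ASP ASP 0 0.2400
ASP CYS 0 -0.4800
ASP GLN 0 0.2400
ASP GLU 0 0.2400
ASP GLY 0 -0.1320
ASP HIS 0 0.2040
ASP ILE 0 -0.7200
ASP LEU 0 -0.6360
ASP LYS 0 0.2880
ASP MET 0 -0.4080
ASP PHE 0 -0.5160
ASP PRO 0 0.0120
ASP SER 0 -0.0840
ASP THR 0 -0.0960
ASP TRP 0 -0.0720
ASP TYR 0 -0.0240
ASP VAL 0 -0.6840
CYS CYS 0 -1.2000
CYS GLN 0 -0.4800
CYS GLU 0 -0.4800
CYS GLY 0 -0.8520
CYS HIS 0 -0.5160
CYS ILE 0 -1.4400
CYS LEU 0 -1.3560
CYS LYS 0 -0.4320
CYS MET 0 -1.1280
CYS PHE 0 -1.2360
CYS PRO 0 -0.7080
CYS SER 0 -0.8040
CYS THR 0 -0.8160
CYS TRP 0 -0.7920
CYS TYR 0 -0.7440
CYS VAL 0 -1.4040
GLN GLN 0 0.2400
GLN GLU 0 0.2400
GLN GLY 0 -0.1320
GLN HIS 0 0.2040
GLN ILE 0 -0.7200
GLN LEU 0 -0.6360
GLN LYS 0 0.2880
GLN MET 0 -0.4080
GLN PHE 0 -0.5160
GLN PRO 0 0.0120
GLN SER 0 -0.0840
GLN THR 0 -0.0960
GLN TRP 0 -0.0720
GLN TYR 0 -0.0240
GLN VAL 0 -0.6840
GLU GLU 0 0.2400
GLU GLY 0 -0.1320
GLU HIS 0 0.2040
GLU ILE 0 -0.7200
GLU LEU 0 -0.6360
GLU LYS 0 0.2880
GLU MET 0 -0.4080
GLU PHE 0 -0.5160
GLU PRO 0 0.0120
GLU SER 0 -0.0840
GLU THR 0 -0.0960
GLU TRP 0 -0.0720
GLU TYR 0 -0.0240
GLU VAL 0 -0.6840
GLY GLY 0 -0.5040
GLY HIS 0 -0.1680
GLY ILE 0 -1.0920
GLY LEU 0 -1.0080
GLY LYS 0 -0.0840
GLY MET 0 -0.7800
GLY PHE 0 -0.8880
GLY PRO 0 -0.3600
GLY SER 0 -0.4560
GLY THR 0 -0.4680
GLY TRP 0 -0.4440
GLY TYR 0 -0.3960
GLY VAL 0 -1.0560
HIS HIS 0 0.1680
HIS ILE 0 -0.7560
HIS LEU 0 -0.6720
HIS LYS 0 0.2520
HIS MET 0 -0.4440
HIS PHE 0 -0.5520
HIS PRO 0 -0.0240
HIS SER 0 -0.1200
HIS THR 0 -0.1320
HIS TRP 0 -0.1080
HIS TYR 0 -0.0600
HIS VAL 0 -0.7200
ILE ILE 0 -1.6800
ILE LEU 0 -1.5960
ILE LYS 0 -0.6720
ILE MET 0 -1.3680
ILE PHE 0 -1.4760
ILE PRO 0 -0.9480
ILE SER 0 -1.0440
ILE THR 0 -1.0560
ILE TRP 0 -1.0320
ILE TYR 0 -0.9840
ILE VAL 0 -1.6440
LEU LEU 0 -1.5120
LEU LYS 0 -0.5880
LEU MET 0 -1.2840
LEU PHE 0 -1.3920
LEU PRO 0 -0.8640
LEU SER 0 -0.9600
LEU THR 0 -0.9720
LEU TRP 0 -0.9480
LEU TYR 0 -0.9000
LEU VAL 0 -1.5600
LYS LYS 0 0.3360
LYS MET 0 -0.3600
LYS PHE 0 -0.4680
LYS PRO 0 0.0600
LYS SER 0 -0.0360
LYS THR 0 -0.0480
LYS TRP 0 -0.0240
LYS TYR 0 0.0240
LYS VAL 0 -0.6360
MET MET 0 -1.0560
MET PHE 0 -1.1640
MET PRO 0 -0.6360
MET SER 0 -0.7320
MET THR 0 -0.7440
MET TRP 0 -0.7200
MET TYR 0 -0.6720
MET VAL 0 -1.3320
PHE PHE 0 -1.2720
PHE PRO 0 -0.7440
PHE SER 0 -0.8400
PHE THR 0 -0.8520
PHE TRP 0 -0.8280
PHE TYR 0 -0.7800
PHE VAL 0 -1.4400
PRO PRO 0 -0.2160
PRO SER 0 -0.3120
PRO THR 0 -0.3240
PRO TRP 0 -0.3000
PRO TYR 0 -0.2520
PRO VAL 0 -0.9120
SER SER 0 -0.4080
SER THR 0 -0.4200
SER TRP 0 -0.3960
SER TYR 0 -0.3480
SER VAL 0 -1.0080
THR THR 0 -0.4320
THR TRP 0 -0.4080
THR TYR 0 -0.3600
THR VAL 0 -1.0200
TRP TRP 0 -0.3840
TRP TYR 0 -0.3360
TRP VAL 0 -0.9960
TYR TYR 0 -0.2880
TYR VAL 0 -0.9480
VAL VAL 0 -1.6080
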