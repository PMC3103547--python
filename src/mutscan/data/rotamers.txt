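# mutscan backbone-independent rotamer library
# <residue> <chi1> <chi2> <chi3> <chi4>   ('-' = not applicable)
ALA - - - -
ARG -60.0 180.0 180.0 180.0
ARG -60.0 180.0 180.0 -60.0
ARG -60.0 180.0 180.0 60.0
ARG 180.0 180.0 180.0 180.0
ARG 180.0 180.0 180.0 -60.0
ARG 180.0 180.0 180.0 60.0
ARG 60.0 180.0 180.0 180.0
ARG 60.0 180.0 180.0 -60.0
ARG 60.0 180.0 180.0 60.0
ASN -60.0 180.0 - -
ASN -60.0 60.0 - -
ASN -60.0 -60.0 - -
ASN 180.0 180.0 - -
ASN 180.0 60.0 - -
ASN 180.0 -60.0 - -
ASN 60.0 180.0 - -
ASN 60.0 60.0 - -
ASN 60.0 -60.0 - -
ASP -60.0 180.0 - -
ASP -60.0 60.0 - -
ASP -60.0 -60.0 - -
ASP 180.0 180.0 - -
ASP 180.0 60.0 - -
ASP 180.0 -60.0 - -
ASP 60.0 180.0 - -
ASP 60.0 60.0 - -
ASP 60.0 -60.0 - -
CYS -60.0 - - -
CYS 180.0 - - -
CYS 60.0 - - -
GLN -60.0 180.0 180.0 -
GLN -60.0 -60.0 180.0 -
GLN -60.0 180.0 -60.0 -
GLN 180.0 180.0 180.0 -
GLN 180.0 -60.0 180.0 -
GLN 180.0 180.0 -60.0 -
GLN 60.0 180.0 180.0 -
GLN 60.0 -60.0 180.0 -
GLN 60.0 180.0 -60.0 -
GLU -60.0 180.0 180.0 -
GLU -60.0 -60.0 180.0 -
GLU -60.0 180.0 -60.0 -
GLU 180.0 180.0 180.0 -
GLU 180.0 -60.0 180.0 -
GLU 180.0 180.0 -60.0 -
GLU 60.0 180.0 180.0 -
GLU 60.0 -60.0 180.0 -
GLU 60.0 180.0 -60.0 -
HIS -60.0 180.0 - -
HIS -60.0 60.0 - -
HIS -60.0 -60.0 - -
HIS 180.0 180.0 - -
HIS 180.0 60.0 - -
HIS 180.0 -60.0 - -
HIS 60.0 180.0 - -
HIS 60.0 60.0 - -
HIS 60.0 -60.0 - -
ILE -60.0 180.0 - -
ILE -60.0 60.0 - -
ILE -60.0 -60.0 - -
ILE 180.0 180.0 - -
ILE 180.0 60.0 - -
ILE 180.0 -60.0 - -
ILE 60.0 180.0 - -
ILE 60.0 60.0 - -
ILE 60.0 -60.0 - -
LEU -60.0 180.0 - -
LEU -60.0 60.0 - -
LEU -60.0 -60.0 - -
LEU 180.0 180.0 - -
LEU 180.0 60.0 - -
LEU 180.0 -60.0 - -
LEU 60.0 180.0 - -
LEU 60.0 60.0 - -
LEU 60.0 -60.0 - -
LYS -60.0 180.0 180.0 180.0
LYS -60.0 180.0 180.0 -60.0
LYS -60.0 180.0 180.0 60.0
LYS 180.0 180.0 180.0 180.0
LYS 180.0 180.0 180.0 -60.0
LYS 180.0 180.0 180.0 60.0
LYS 60.0 180.0 180.0 180.0
LYS 60.0 180.0 180.0 -60.0
LYS 60.0 180.0 180.0 60.0
MET -60.0 180.0 180.0 -
MET -60.0 -60.0 180.0 -
MET -60.0 180.0 -60.0 -
MET 180.0 180.0 180.0 -
MET 180.0 -60.0 180.0 -
MET 180.0 180.0 -60.0 -
MET 60.0 180.0 180.0 -
MET 60.0 -60.0 180.0 -
MET 60.0 180.0 -60.0 -
PHE -60.0 180.0 - -
PHE -60.0 60.0 - -
PHE -60.0 -60.0 - -
PHE 180.0 180.0 - -
PHE 180.0 60.0 - -
PHE 180.0 -60.0 - -
PHE 60.0 180.0 - -
PHE 60.0 60.0 - -
PHE 60.0 -60.0 - -
PRO - - - -
SER -60.0 - - -
SER 180.0 - - -
SER 60.0 - - -
THR -60.0 - - -
THR 180.0 - - -
THR 60.0 - - -
TRP -60.0 180.0 - -
TRP -60.0 60.0 - -
TRP -60.0 -60.0 - -
TRP 180.0 180.0 - -
TRP 180.0 60.0 - -
TRP 180.0 -60.0 - -
TRP 60.0 180.0 - -
TRP 60.0 60.0 - -
TRP 60.0 -60.0 - -
TYR -60.0 180.0 - -
TYR -60.0 60.0 - -
TYR -60.0 -60.0 - -
TYR 180.0 180.0 - -
TYR 180.0 60.0 - -
TYR 180.0 -60.0 - -
TYR 60.0 180.0 - -
TYR 60.0 60.0 - -
TYR 60.0 -60.0 - -
VAL -60.0 - - -
VAL 180.0 - - -
VAL 60.0 - - -
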