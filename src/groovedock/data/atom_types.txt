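# Heavy-atom interaction typing for the 20 standard residues.
# Columns: residue atom type-code. "*" matches any residue (backbone atoms).
# Codes: ALC aliphatic-C, ARC aromatic-C, ND N-donor, NA N-acceptor,
#        NDA N-donor-acceptor, OA O-acceptor, ODA O-donor-acceptor, S sulfur.
*   N    ND
*   CA   ALC
*   C    ALC
*   O    OA
*   OXT  OA
PRO N    NA
ALA CB   ALC
ARG CB   ALC
ARG CG   ALC
ARG CD   ALC
ARG NE   ND
ARG CZ   ALC
ARG NH1  ND
ARG NH2  ND
ASN CB   ALC
ASN CG   ALC
ASN OD1  OA
ASN ND2  ND
ASP CB   ALC
ASP CG   ALC
ASP OD1  OA
ASP OD2  OA
CYS CB   ALC
CYS SG   S
GLN CB   ALC
GLN CG   ALC
GLN CD   ALC
GLN OE1  OA
GLN NE2  ND
GLU CB   ALC
GLU CG   ALC
GLU CD   ALC
GLU OE1  OA
GLU OE2  OA
HIS CB   ALC
HIS CG   ARC
HIS ND1  NDA
HIS CD2  ARC
HIS CE1  ARC
HIS NE2  NDA
ILE CB   ALC
ILE CG1  ALC
ILE CG2  ALC
ILE CD1  ALC
LEU CB   ALC
LEU CG   ALC
LEU CD1  ALC
LEU CD2  ALC
LYS CB   ALC
LYS CG   ALC
LYS CD   ALC
LYS CE   ALC
LYS NZ   ND
MET CB   ALC
MET CG   ALC
MET SD   S
MET CE   ALC
PHE CB   ALC
PHE CG   ARC
PHE CD1  ARC
PHE CD2  ARC
PHE CE1  ARC
PHE CE2  ARC
PHE CZ   ARC
PRO CB   ALC
PRO CG   ALC
PRO CD   ALC
SER CB   ALC
SER OG   ODA
THR CB   ALC
THR OG1  ODA
THR CG2  ALC
TRP CB   ALC
TRP CG   ARC
TRP CD1  ARC
TRP CD2  ARC
TRP NE1  ND
TRP CE2  ARC
TRP CE3  ARC
TRP CZ2  ARC
TRP CZ3  ARC
TRP CH2  ARC
TYR CB   ALC
TYR CG   ARC
TYR CD1  ARC
TYR CD2  ARC
TYR CE1  ARC
TYR CE2  ARC
TYR CZ   ARC
TYR OH   ODA
VAL CB   ALC
VAL CG1  ALC
VAL CG2  ALC
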