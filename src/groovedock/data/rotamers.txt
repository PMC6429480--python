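# Backbone-independent coarse rotamer library.
# Columns: residue chi1 chi2 chi3 chi4 weight  ("-" = no such chi angle).
# Canonical gauche-/trans/gauche+ combinations; weights sum to 1 per residue.
ALA -    -    -    -    1.00
GLY -    -    -    -    1.00
PRO -    -    -    -    1.00
SER -65  -    -    -    0.48
SER 180  -    -    -    0.30
SER 62   -    -    -    0.22
CYS -65  -    -    -    0.50
CYS 180  -    -    -    0.30
CYS 62   -    -    -    0.20
THR -60  -    -    -    0.45
THR 60   -    -    -    0.45
THR 180  -    -    -    0.10
VAL 175  -    -    -    0.55
VAL -60  -    -    -    0.30
VAL 62   -    -    -    0.15
LEU -65  175  -    -    0.60
LEU 180  60   -    -    0.30
LEU -90  60   -    -    0.10
ILE -65  170  -    -    0.60
ILE 180  165  -    -    0.20
ILE 62   170  -    -    0.20
PHE -65  90   -    -    0.50
PHE 180  80   -    -    0.40
PHE 62   90   -    -    0.10
TYR -65  90   -    -    0.50
TYR 180  80   -    -    0.40
TYR 62   90   -    -    0.10
TRP -65  95   -    -    0.35
TRP -65  -90  -    -    0.25
TRP 180  -105 -    -    0.20
TRP 62   -90  -    -    0.20
HIS -65  -70  -    -    0.40
HIS -65  80   -    -    0.25
HIS 180  60   -    -    0.20
HIS 62   -75  -    -    0.15
ASP -70  -15  -    -    0.55
ASP 180  10   -    -    0.30
ASP 62   10   -    -    0.15
ASN -65  -20  -    -    0.50
ASN 180  30   -    -    0.30
ASN 62   -75  -    -    0.20
GLU -67  180  -10  -    0.40
GLU -65  -65  -40  -    0.25
GLU 180  180  0    -    0.25
GLU 62   180  0    -    0.10
GLN -67  180  -25  -    0.40
GLN -65  -65  -40  -    0.30
GLN 180  180  20   -    0.30
MET -65  -65  -70  -    0.30
MET -65  180  75   -    0.30
MET 180  180  75   -    0.25
MET 62   180  75   -    0.15
LYS -67  180  180  180  0.40
LYS 180  180  180  180  0.30
LYS -65  -65  180  180  0.20
LYS 62   180  180  180  0.10
ARG -67  180  180  85   0.30
ARG -67  180  180  180  0.30
ARG 180  180  180  180  0.25
ARG -65  -65  180  180  0.15
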