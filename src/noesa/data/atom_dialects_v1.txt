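# Atom-name dialect table v1: RESIDUE  PDB3_NAME  CHARMM_NAME
# '*' applies to any residue. Bijective per residue context.
*    H    HN
*    OXT  OT2
GLY  HA2  HA1
GLY  HA3  HA2
ILE  CD1  CD
ILE  HD11 HD1
ILE  HD12 HD2
ILE  HD13 HD3
ILE  HG12 HG11
ILE  HG13 HG12
SER  HG   HG1
CYS  HG   HG1
ARG  HB2  HB1
ARG  HB3  HB2
ARG  HD2  HD1
ARG  HD3  HD2
ARG  HG2  HG1
ARG  HG3  HG2
ASN  HB2  HB1
ASN  HB3  HB2
ASP  HB2  HB1
ASP  HB3  HB2
CYS  HB2  HB1
CYS  HB3  HB2
GLN  HB2  HB1
GLN  HB3  HB2
GLN  HG2  HG1
GLN  HG3  HG2
GLU  HB2  HB1
GLU  HB3  HB2
GLU  HG2  HG1
GLU  HG3  HG2
HIS  HB2  HB1
HIS  HB3  HB2
LEU  HB2  HB1
LEU  HB3  HB2
LYS  HB2  HB1
LYS  HB3  HB2
LYS  HD2  HD1
LYS  HD3  HD2
LYS  HE2  HE1
LYS  HE3  HE2
LYS  HG2  HG1
LYS  HG3  HG2
MET  HB2  HB1
MET  HB3  HB2
MET  HG2  HG1
MET  HG3  HG2
PHE  HB2  HB1
PHE  HB3  HB2
PRO  HB2  HB1
PRO  HB3  HB2
PRO  HD2  HD1
PRO  HD3  HD2
PRO  HG2  HG1
PRO  HG3  HG2
SER  HB2  HB1
SER  HB3  HB2
TRP  HB2  HB1
TRP  HB3  HB2
TYR  HB2  HB1
TYR  HB3  HB2
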