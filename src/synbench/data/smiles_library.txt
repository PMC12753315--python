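CC(=O)OC1=CC=CC=C1C(=O)O
CC(=O)NC1=CC=C(O)C=C1
CC(C)CC1=CC=C(C=C1)C(C)C(=O)O
CN1C=NC2=C1C(=O)N(C)C(=O)N2C
CN(C)CCC=C1C2=CC=CC=C2CCC2=CC=CC=C12
C1=CC=C(C=C1)C(=O)O
OC(=O)C1=CC=CC=C1O
NC1=CC=C(C=C1)S(N)(=O)=O
CC1=CC=C(C=C1)S(=O)(=O)NC(=O)NN1CCCCCC1
CCN(CC)CCNC(=O)C1=CC=C(N)C=C1
COC1=CC2=C(C=C1OC)C(=O)C(CC1CCN(CC3=CC=C(F)C=C3)CC1)C2
CC(CS)C(=O)N1CCCC1C(=O)O
NC(=O)C1=CN=CC=C1
OCC1OC(O)C(O)C(O)C1O
NC(CC1=CNC2=CC=CC=C12)C(=O)O
NC(CC1=CC=C(O)C=C1)C(=O)O
NC(CO)C(=O)O
CC(N)C(=O)O
NCCCCC(N)C(=O)O
OC(=O)CC(O)(CC(=O)O)C(=O)O
CC(O)C(=O)O
OC(=O)C=CC(=O)O
OC(=O)CCC(=O)O
OCC(O)CO
CCO
CC(C)O
OCCO
C1CCNCC1
C1CCOC1
C1=CC=NC=C1
C1=CC=CC=C1
CC1=CC=CC=C1
COC1=CC=CC=C1
CC(=O)C1=CC=CC=C1
CC1=CC(=O)C=CC1=O
OC1=CC=C(C=C1)C=O
COC1=CC(=CC(OC)=C1O)C=O
CC(C)=CCCC(C)=CC=O
CC1=CC=C(C=C1)C(C)C
CC(C)C1=CC=C(C)C=C1O
OC1=CC=CC=C1
OC1=CC=C(Cl)C=C1
NC1=CC=CC=C1
ClC1=CC=CC=C1
BrC1=CC=CC=C1
FC1=CC=CC=C1
IC1=CC=CC=C1
CC#N
CCOC(=O)C
CCOCC
CCCCCC
C1CCCCC1
C1CC1
CC(C)(C)O
CC(C)(C)C1=CC=C(O)C=C1
CN1CCC[C@H]1C1=CN=CC=C1
CN1C2=C(C=C(C=C2)N(=O)=O)C(=O)N(C)C1=O
CC(CN1C=NC2=C1C(=O)N(C)C(=O)N2C)O
CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2=O
CC12CCC3C(CCC4=CC(O)=CC=C34)C1CCC2O
CC(=O)OC1CC2CCC3C(CCC4(C)C3CCC4(O)C#C)C2(C)CC1
CN(C)C1=CC=C(C=C1)C(C2=CC=C(C=C2)N(C)C)=C3C=CC(C=C3)=[N+](C)C
CC1=C(C=C(C=C1)O)C(C)C
CC1=CC=C(O)C=C1
COC(=O)C1=CC=CC=C1O
COC(=O)C1=CC=CC=C1N
CCOC(=O)C1=CC=C(N)C=C1
CN1CCN(CC1)C1=CC=CC=C1
O=C1NC(=O)NC(=O)C1(CC)CC
O=C1NC(=O)NC(=O)C1(CC)C1=CC=CC=C1
CCC1(CCC(=O)NC1=O)C1=CC=CC=C1
NC(=O)N1C2=CC=CC=C2C=CC2=CC=CC=C12
OC(=O)C1=CC=CN=C1
OC(=O)C1=CC=NC=C1
CC1=NC=C(N1CCO)N(=O)=O
OCC1=CC=C(C=C1)O
OC(CNC(C)(C)C)C1=CC(CO)=C(O)C=C1
CNCC(O)C1=CC(O)=C(O)C=C1
NCC(O)C1=CC(O)=C(O)C=C1
CNC(C)C(O)C1=CC=CC=C1
CC(N)CC1=CC=CC=C1
CC(C)NCC(O)COC1=CC=C(CC(N)=O)C=C1
CC(C)NCC(O)COC1=CC=CC2=CC=CC=C12
OC(=O)CCCCCCC(=O)O
OC(=O)CCCCC(=O)O
CCCCCCCCCCCCCCCC(=O)O
CCCCCCCCC=CCCCCCCCC(=O)O
OC(=O)C1CCCCC1
NC1CCCCC1
OC1CCCCC1
O=C1CCCCC1
CC(=O)CC(C1=CC=CC=C1)C1=C(O)C2=CC=CC=C2OC1=O
COC1=CC2=C(C=C1)C1=CC=CC=C1N2
CN1CCC2=CC=CC=C2C1
C1=CC2=CC=CC=C2C=C1
C1=CC2=CC=CC=C2N1
C1=CC=C2OC=CC2=C1
C1=CC=C2SC=CC2=C1
C1=CSC=C1
C1=COC=C1
C1=CNC=C1
CN1C=CC=C1
CC1=CC=C(S1)C
O=S1(=O)CCCC1
CC(C)S
CCS
CCN
CCCN
CCCCN
NCCO
NCCCO
OCCCO
CC(=O)N
CC(=O)NC
CNC(=O)N
NC(=O)N
NC(N)=N
CC(=O)C(C)=O
OCC(=O)CO
CC1CCCCC1
CC1CCCC1
CC1=CC=CC=C1C
CC1=CC=CC(C)=C1
CC1=CC(C)=CC(C)=C1
COC1=CC=C(C=C1)CCN
COC1=CC=C(C=C1)CC(N)C
OC(=O)C(Cl)Cl
OC(=O)C(F)(F)F
ClCCl
ClC(Cl)Cl
CCOC(=O)CC(=O)OCC
CCOC(=O)C(C)C
CC(C)CC(=O)O
CC(C)(C)CC(=O)O
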