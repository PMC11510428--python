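OC1CC1=CO pagerank|BigBird
CCNC1CC1=C pagerank|GPT-NeoX
C1C2C=CC=CC12 pagerank|GPT-NeoX
NC1CCCC=C1 pagerank|GPT-NeoX
OC1CCOC1=C pagerank|GPT-NeoX
OC1CC1C pagerank|GPT-NeoX
CCC1CC=C1C pagerank|Gemma
OCC1=NCCN1 pagerank|GPT-NeoX
OCC1=NCCN1 pagerank|Gemma
N=CN1CCCN1 pagerank|GPT-NeoX
C1C=CC2NC12 pagerank|GPT-NeoX
OC12CC1=CS2 pagerank|Gemma
OC1CNC=NC1 pagerank|GPT-NeoX
C1C2CC=CC=CC12 pagerank|GPT-NeoX
OC1=CCN=C1 pagerank|Gemma
CC1C(O)C1C pagerank|GPT-NeoX
NC1CCC=C1 pagerank|GPT-NeoX
CC1NCC1O pagerank|Gemma
CC1=CCC2CC12 pagerank|GPT-NeoX
CC1C(O)C1O pagerank|BigBird
CCC1=COCC=CC(=CC(C)CCC1=CN) qed|BigBird
CN1CNC=C1CC1CC1C qed|BigBird
CNCC1COCN1CC1C=CC1 qed|BigBird
CNCCC1CCCC1C qed|BigBird
CC1CC1CC(C)CC1CC1=O qed|BigBird
CCC(C)CC(C)(N)CN qed|Gemma
C1CC1CC1CC1CN qed|BigBird
CCC1=NC=NC=C1Cl qed|Gemma
CCCC(C)C(C)O qed|Gemma
CC1CNCC1CC(C) qed|BigBird
C1C2C3OC1CN23 sa|GPT-NeoX
C1C2NC1C1NC21 sa|GPT-NeoX
CC1=C=CC1C=NN=C sa|BigBird
NC1CN2CC1N2 sa|GPT-NeoX
NC1=CSN=C=C1 sa|GPT-NeoX
C1NC2CCC1O2 sa|GPT-NeoX
C1CC=CC=C=C=CC=CCC1N sa|BigBird
NC1C2NC=CN12 sa|GPT-NeoX
OC1C2NC1C=C2 sa|GPT-NeoX
CC1C=CON=N1 sa|GPT-NeoX
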