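# Residue-name -> cofactor-class table (wwPDB chemical component ids).
# Chlorophyll counts include both Chl a (CLA) and the P700 epimer Chl a' (CL0).
CLA: chlorophyll
CL0: chlorophyll
BCR: carotenoid
ECH: carotenoid
ECN: carotenoid
CAN: carotenoid
ZEX: carotenoid
PQN: phylloquinone
SF4: iron_sulfur
FES: iron_sulfur
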