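# Synthetic stand-in Qy transition-charge set for chlorophyll a.
# Constructed in-package: NOT a literature gas-phase TrESP charge set.
# Properties: zero net monopole; transition dipole along the NB->ND axis
# of the macrocycle (the Qy polarization direction); charges confined to
# macrocycle heavy atoms. Intended for use after rescaling every pigment
# to the standard effective Qy dipole strength (4.3 D), which removes the
# arbitrary overall magnitude.
# provenance: synthetic (psispec package)
atom_name,charge_e
MG,0.0
NA,0.0
NB,0.30
NC,0.0
ND,-0.30
CHA,0.0
CHB,0.02
CHC,0.02
CHD,-0.04
C1A,0.0
C2A,0.0
C3A,0.0
C4A,0.0
C1B,0.08
C2B,0.05
C3B,0.05
C4B,0.08
C1C,0.0
C2C,0.0
C3C,0.0
C4C,0.0
C1D,-0.08
C2D,-0.05
C3D,-0.05
C4D,-0.08
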