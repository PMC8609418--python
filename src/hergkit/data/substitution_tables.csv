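# Per-residue substitution tables used by the structural impact score.
# volume_A3: residue volume (Zamyatnin); charge: +, - or 0; polarity:
# polar/nonpolar; hydropathy class from the Kyte-Doolittle index
# (hydrophobic > 1, hydrophilic < -2, neutral otherwise).
residue,volume_A3,charge,polarity,hydropathy
A,88.6,0,nonpolar,hydrophobic
R,173.4,+,polar,hydrophilic
N,114.1,0,polar,hydrophilic
D,111.1,-,polar,hydrophilic
C,108.5,0,nonpolar,hydrophobic
Q,143.8,0,polar,hydrophilic
E,138.4,-,polar,hydrophilic
G,60.1,0,nonpolar,neutral
H,153.2,+,polar,hydrophilic
I,166.7,0,nonpolar,hydrophobic
L,166.7,0,nonpolar,hydrophobic
K,168.6,+,polar,hydrophilic
M,162.9,0,nonpolar,hydrophobic
F,189.9,0,nonpolar,hydrophobic
P,112.7,0,nonpolar,neutral
S,89.0,0,polar,neutral
T,116.1,0,polar,neutral
W,227.8,0,nonpolar,neutral
Y,193.6,0,polar,neutral
V,140.0,0,nonpolar,hydrophobic
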