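# Coarse formal-charge defaults for standard amino acids and common solvent
# species, keyed by (residue_name, atom_name).  The charge is placed on the
# sidechain charged-group carbon/nitrogen conventionally used as the group
# proxy (guanidinium CZ for Arg, carboxyl carbon for Asp/Glu, amine NZ for
# Lys, imidazole NE2 for doubly protonated His).  A residue_name of * is a
# wildcard matched after exact rows.  Radii are van der Waals radii in A.
residue_name,atom_name,charge,radius
ARG,CZ,1.0,1.70
LYS,NZ,1.0,1.55
ASP,CG,-1.0,1.70
GLU,CD,-1.0,1.70
HSP,NE2,1.0,1.55
POT,POT,1.0,2.75
K,K,1.0,2.75
CLA,CLA,-1.0,1.75
CL,CL,-1.0,1.75
SOD,SOD,1.0,2.27
TIP3,OH2,0.0,1.52
HOH,O,0.0,1.52
SOL,OW,0.0,1.52
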