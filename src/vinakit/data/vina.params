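# Vina scoring function: term weights, term parameters, atomic radii.
# Distances in angstrom; weights dimensionless.
name vina
weight gauss1 -0.035579
weight gauss2 -0.005156
weight repulsion 0.840245
weight hydrophobic -0.035069
weight hbond -0.587439
gauss1_offset 0.0
gauss1_width 0.5
gauss2_enabled true
gauss2_offset 3.0
gauss2_width 2.0
hydrophobic_onset 0.5
hydrophobic_offset 1.5
hbond_onset -0.7
cutoff 8.0
torsion_coeff 0.05846
# Heavy-atom radii by AutoDock type. A = aromatic carbon.
radius C 1.9
radius A 1.9
radius N 1.8
radius O 1.7
# Elements not retuned by either parameterization (Vina-heritage values).
radius S 2.0
radius P 2.1
radius F 1.5
radius Cl 1.8
radius Br 2.0
radius I 2.2
radius metal 1.2
# Fluorine hydrophobicity follows the Vina convention (halogens hydrophobic).
fluorine_hydrophobic true
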