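# Vinardo scoring function: single-Gaussian steric term, retuned radii,
# hydrophobic onset fixed at contact (p1 = 0).
name vinardo
weight gauss1 -0.045
weight gauss2 0.000
weight repulsion 0.800
weight hydrophobic -0.035
weight hbond -0.600
gauss1_offset 0.0
gauss1_width 0.8
gauss2_enabled false
hydrophobic_onset 0.0
hydrophobic_offset 2.5
hbond_onset -0.6
cutoff 8.0
torsion_coeff 0.05846
radius C 2.0
radius A 1.9
radius N 1.7
radius O 1.6
radius S 2.0
radius P 2.1
radius F 1.5
radius Cl 1.8
radius Br 2.0
radius I 2.2
radius metal 1.2
fluorine_hydrophobic true
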