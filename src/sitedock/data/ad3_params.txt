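# Pair-potential parameter table, version 1.
#
# United-atom 12-6 van der Waals parameters (Rii in A, eps_ii in kcal/mol),
# 12-10 hydrogen-bond parameters for donor/acceptor heteroatom pairs,
# empirical free-energy coefficients, and carbon desolvation parameters
# (fragmental volume V in A^3, solvation parameter S in kcal/mol/A^3).
# Electrostatics use q_i q_j * 332.06 / (eps(r) * r) with the
# Mehler-Solmajer sigmoidal distance-dependent dielectric.
#
# coeff <term> <value>
coeff vdw    0.1485
coeff hbond  0.0656
coeff estat  0.1146
coeff desolv 0.1711
# cap (kcal/mol) applied to the summed energy of each interacting pair
coeff cap    1.0
#
# vdw <type> <Rii> <eps_ii>
vdw C  4.00 0.150
vdw A  4.00 0.150
vdw N  3.50 0.160
vdw O  3.20 0.200
vdw S  4.00 0.200
vdw H  2.00 0.020
vdw P  4.20 0.200
vdw F  3.09 0.080
vdw Cl 4.09 0.276
vdw Br 4.33 0.389
vdw I  4.72 0.550
#
# hbond <type_i> <type_j> <Rij> <eps_ij>   (unordered pair)
hbond O O 1.90 5.0
hbond N O 1.90 5.0
hbond O S 2.50 1.0
hbond N S 2.50 1.0
#
# solv <type> <S> <V>
solv C 0.00110 12.77
solv A 0.00110 10.80
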