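# Reduced self-contained polar-hydrogen parameter set.
# One atom class per line:
#   class  charge(e)  rmin_half(A)  epsilon(kcal/mol)  gamma_sa(kcal/mol/A^2)
# rmin_half is half the Lennard-Jones minimum-energy distance; pair minima
# use rmin_ij = rmin_half_i + rmin_half_j.  gamma_sa is the surface-tension
# coefficient of the nonpolar solvation term.  United-atom carbons carry
# enlarged radii to absorb their implicit hydrogens.
H      0.25  0.80  0.046  0.000
HC     0.35  0.60  0.046  0.000
HO     0.40  0.60  0.046  0.000
HS     0.20  0.60  0.046  0.000
NH1   -0.35  1.85  0.200 -0.006
NH2   -0.50  1.85  0.200 -0.006
NH3   -0.30  1.85  0.200 -0.009
NC2   -0.45  1.85  0.200 -0.009
NR    -0.40  1.85  0.200 -0.006
NP    -0.10  1.85  0.200 -0.006
O     -0.55  1.70  0.120 -0.006
OC    -0.55  1.70  0.120 -0.009
OH1   -0.65  1.77  0.150 -0.006
C      0.55  2.00  0.070  0.012
CCARB  0.10  2.00  0.070  0.012
CR     0.35  2.00  0.070  0.012
CRP    0.30  2.04  0.070  0.012
CT1    0.10  2.27  0.020  0.012
CT1P   0.25  2.27  0.020  0.012
CT1S   0.00  2.27  0.020  0.012
CT2    0.00  2.17  0.055  0.012
CT2P   0.25  2.17  0.055  0.012
CT3    0.00  2.06  0.078  0.012
CAH    0.00  2.04  0.070  0.012
CAN    0.00  2.04  0.070  0.012
CAP    0.25  2.04  0.070  0.012
S     -0.20  2.00  0.450  0.012
S1    -0.45  2.00  0.450  0.012
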