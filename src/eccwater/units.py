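"""Unit conventions and conversion constants.

Internal unit system: lengths in nm, energies in kJ/mol, charges in
elementary charges (e), angles in degrees.  Electrostatic moments are
reported in the units customary for water models: the dipole in debye (D)
and the quadrupole in debye-angstrom (D Å).

The single conversion constant below is derived from the CODATA elementary
charge (1.602176634e-19 C) and the definition of the debye
(1 D = 1e-21/c C m = 3.33564095e-30 C m).
"""

#: 1 e nm expressed in debye.
E_NM_TO_DEBYE = 48.03204712570264

#: 1 e nm^2 expressed in debye angstrom (one extra nm -> Å factor of 10).
E_NM2_TO_DEBYE_ANGSTROM = E_NM_TO_DEBYE * 10.0

#: Boltzmann constant, J/K (used by the finite-size diffusion correction).
BOLTZMANN_J_PER_K = 1.380649e-23
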