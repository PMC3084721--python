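"""Physical constants and unit helpers.

Canonical units throughout the package are nm (length), nN (force) and
nN/nm (stiffness).  With these, energy comes out in nN*nm = 1e-18 J and a
modulus in nN/nm^2 = 1 GPa, which keeps force-curve arithmetic near unity.
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K

#: 1 J expressed in nN*nm
JOULE_TO_NN_NM = 1e18

#: 1 nN/nm^2 expressed in Pa
NN_PER_NM2_TO_PA = 1e9


def thermal_energy(T: float) -> float:
    """k_B*T in nN*nm (4.116e-3 at 298.15 K)."""
    return BOLTZMANN * T * JOULE_TO_NN_NM
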