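"""Physical constants and unit conversions used across the package.

Internal conventions: lengths in Angstrom (A), charges in units of the
elementary charge e, free energies tagged as kcal/mol or eV, membrane
voltages in volts, times in ns unless stated otherwise.
"""

#: elementary charge in coulomb (exact, SI 2019)
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: kcal/mol -> eV per particle; the inverse is derived so that the
#: round-trip kcal/mol -> eV -> kcal/mol is exact in floating point.
EV_PER_KCAL_MOL = 0.0433641
KCAL_MOL_PER_EV = 1.0 / EV_PER_KCAL_MOL

#: Coulomb constant in (volt * Angstrom / e): phi[V] = 14.39964 * q[e] / r[A]
COULOMB_V_A_PER_E = 14.39964

#: gas constant in kcal/(mol K)
R_KCAL_MOL_K = 1.9872041e-3


def kcal_to_ev(x):
    """Convert a free energy from kcal/mol to eV per particle."""
    return x * EV_PER_KCAL_MOL


def ev_to_kcal(x):
    """Convert a free energy from eV per particle to kcal/mol."""
    return x * KCAL_MOL_PER_EV
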