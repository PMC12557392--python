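"""Per-residue parameters of the coarse-grained HPS model.

One bead per residue, centred on the C-alpha.  Bead diameters ``sigma``
(Angstrom) and hydrophobicity weights ``lambda`` (dimensionless, [0, 1],
Kapcha–Rossky-derived scale) transcribed from Dignon, Zheng, Kim, Best &
Mittal, PLoS Comput. Biol. 2018, 14, e1005941 (Table S1 of that work).
Charges follow the simulation convention Arg/Lys +1, Asp/Glu -1, His +0.5.

A hook for temperature-dependent refinement of the hydrophobicity scale
(per-residue linear coefficients d lambda / dT) is provided; coefficients
default to zero and can be overridden with any published parameterisation.
"""

from __future__ import annotations

# residue -> (sigma [A], lambda)
HPS_SIGMA_LAMBDA: dict[str, tuple[float, float]] = {
    "A": (5.04, 0.730),
    "R": (6.56, 0.000),
    "N": (5.68, 0.432),
    "D": (5.58, 0.378),
    "C": (5.48, 0.595),
    "Q": (6.02, 0.514),
    "E": (5.92, 0.459),
    "G": (4.50, 0.649),
    "H": (6.08, 0.514),
    "I": (6.18, 0.973),
    "L": (6.18, 0.973),
    "K": (6.36, 0.514),
    "M": (6.18, 0.838),
    "F": (6.36, 1.000),
    "P": (5.56, 1.000),
    "S": (5.18, 0.595),
    "T": (5.62, 0.676),
    "W": (6.78, 0.946),
    "Y": (6.46, 0.865),
    "V": (5.86, 0.892),
}

#: HPS charge convention (e), as used by the simulations.
HPS_CHARGE: dict[str, float] = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0, "H": 0.5}

#: Pair interaction strength, kcal/mol (0.8368 kJ/mol).
HPS_EPSILON = 0.2

#: Harmonic bond: k in kcal/(mol A^2) (10 kJ/(mol A^2)), r0 in A.
HPS_BOND_K = 2.39006
HPS_BOND_R0 = 3.8

#: Interaction truncation radii (A); shifted to zero at the cutoff.
DEFAULT_LJ_CUTOFF = 25.0
DEFAULT_ELEC_CUTOFF = 35.0

#: d lambda / dT per residue (1/K); zero by default (see module docstring).
LAMBDA_DT_DEFAULT: dict[str, float] = {aa: 0.0 for aa in HPS_SIGMA_LAMBDA}
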