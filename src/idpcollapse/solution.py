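"""Solution electrostatics and thermodynamics.

Everything the rest of the pipeline needs to know about the solvent lives
here: the Bjerrum length l_B = e^2 / (4 pi eps0 eps_r k_B T), the Debye
screening length lambda_D = (8 pi l_B N_A I)^(-1/2), ionic strengths of
mixed salt/buffer solutions, mean ionic activities (Davies equation by
default, user-supplied gamma tables optionally), the Kd -> deltaG0
conversion at 1 M standard state, and screened/unscreened Coulomb pair
energies used to put fitted binding free energies on the salt-bridge scale.

Unit conventions: temperatures in K, concentrations in mol/L, lengths in
Angstrom, energies in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

#: Gas constant in kcal/(mol K).
R_KCAL = constants.R / constants.calorie / 1000.0  # 0.0019872 kcal/(mol K)

_EPS0 = constants.epsilon_0
_E = constants.e
_KB = constants.k
_NA = constants.N_A


def water_permittivity(T: float) -> float:
    """Static relative permittivity of water at temperature ``T`` (K).

    Empirical polynomial (CRC-style fit, valid ~273-373 K); gives 78.4 at
    25 C.  Use an explicit ``eps_r`` everywhere if another solvent model is
    wanted.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    t = T - 273.15
    return 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


def bjerrum_length(T: float, eps_r: float) -> float:
    """Bjerrum length in Angstrom.

    l_B = e^2 / (4 pi eps0 eps_r k_B T); the distance at which two unit
    charges interact with thermal energy k_B T.  7.14 A in water at 25 C.
    """
    if T <= 0 or eps_r <= 0:
        raise ValueError("T and eps_r must be positive")
    lb_m = _E**2 / (4.0 * math.pi * _EPS0 * eps_r * _KB * T)
    return lb_m * 1e10


def debye_length(I: float, l_B: float) -> float:
    """Debye screening length in Angstrom.

    lambda_D = (8 pi l_B N_A I)^(-1/2) with ``I`` in mol/L and ``l_B`` in
    Angstrom.  Diverges as I -> 0; an error is raised for I <= 0 because the
    screening theory consuming this quantity is not defined there.
    """
    if I <= 0:
        raise ValueError("ionic strength must be positive (theory diverges at I=0)")
    if l_B <= 0:
        raise ValueError("Bjerrum length must be positive")
    number_density = I * _NA * 1e-27  # ions per A^3 per unit valence-square
    return 1.0 / math.sqrt(8.0 * math.pi * l_B * number_density)


@dataclass(frozen=True)
class SaltSpec:
    """A strong salt: stoichiometry and ion valences.

    Electroneutrality ``n_cat * z_cat == n_an * |z_an|`` is enforced.
    """

    name: str
    cation_valence: int
    anion_valence: int
    stoichiometry: tuple[int, int]

    def __post_init__(self):
        n_cat, n_an = self.stoichiometry
        if n_cat * self.cation_valence != n_an * abs(self.anion_valence):
            raise ValueError(
                f"{self.name}: electroneutrality violated "
                f"({n_cat}x{self.cation_valence:+d} vs {n_an}x{self.anion_valence:+d})"
            )


#: The four salts titrated in the compaction experiments.
NACL = SaltSpec("NaCl", 1, -1, (1, 1))
KCL = SaltSpec("KCl", 1, -1, (1, 1))
MGCL2 = SaltSpec("MgCl2", 2, -1, (1, 2))
CACL2 = SaltSpec("CaCl2", 2, -1, (1, 2))

SALTS = {s.name: s for s in (NACL, KCL, MGCL2, CACL2)}


def ionic_strength(c: float, salt: SaltSpec, buffer_I: float = 0.0) -> float:
    """Ionic strength I = 1/2 sum c_i z_i^2 in mol/L.

    ``buffer_I`` adds a pre-computed buffer contribution (e.g. ~5 mM for
    half-ionized 10 mM Tris).  For a 2:1 salt I = 3c; for 1:1, I = c.
    """
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    n_cat, n_an = salt.stoichiometry
    I_salt = 0.5 * c * (n_cat * salt.cation_valence**2 + n_an * salt.anion_valence**2)
    return I_salt + buffer_I


def davies_log10_gamma(I: float, z_plus: int, z_minus: int, T: float = 298.15) -> float:
    """log10 of the Davies mean ionic activity coefficient.

    log10 gamma = -A z+|z-| ( sqrt(I)/(1+sqrt(I)) - 0.3 I ), with the
    Debye-Hueckel constant A computed from temperature through the Bjerrum
    length (A ~ 0.509 at 25 C in water).
    """
    if I < 0:
        raise ValueError("ionic strength must be nonnegative")
    l_B = bjerrum_length(T, water_permittivity(T))  # A
    # A = l_B^(3/2) sqrt(2 pi N_A * 1000) / ln(10), with l_B in cm-compatible
    # units; evaluate directly in A and mol/L.
    A = (
        math.sqrt(2.0 * math.pi * _NA * 1e-27)
        * l_B**1.5
        / math.log(10.0)
    )
    sq = math.sqrt(I)
    return -A * z_plus * abs(z_minus) * (sq / (1.0 + sq) - 0.3 * I)


@dataclass(frozen=True)
class Activity:
    """Mean ionic activity of a salt at one concentration."""

    concentration: float  # mol/L
    gamma: float
    activity: float  # gamma * c, mol/L
    beyond_validity: bool = False  # Davies used outside I <~ 0.5 M


def mean_activity(
    c: float,
    salt: SaltSpec,
    T: float = 298.15,
    buffer_I: float = 0.0,
    gamma_table: "tuple[np.ndarray, np.ndarray] | None" = None,
) -> Activity:
    """Mean ionic activity a = gamma_pm * c of a salt solution.

    By default gamma_pm comes from the Davies equation at the total ionic
    strength (salt + buffer).  A user-supplied ``gamma_table`` of
    (concentrations, gamma values) overrides the model by interpolation, so
    experimental activity conventions can be plugged in.

    The Davies equation is trusted to I ~ 0.5 M; beyond that the result is
    returned with ``beyond_validity=True`` rather than refused.
    """
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    if gamma_table is not None:
        cs, gs = (np.asarray(a, dtype=float) for a in gamma_table)
        gamma = float(np.interp(c, cs, gs))
        return Activity(c, gamma, gamma * c)
    I = ionic_strength(c, salt, buffer_I=buffer_I)
    if I == 0.0:
        return Activity(c, 1.0, 0.0)
    gamma = 10.0 ** davies_log10_gamma(I, salt.cation_valence, salt.anion_valence, T)
    return Activity(c, gamma, gamma * c, beyond_validity=I > 0.5)


def kd_to_dg(Kd: float, T: float) -> float:
    """Standard binding free energy deltaG0 = R T ln(Kd / 1 M) in kcal/mol.

    Negative for sub-molar Kd; 0 at the 1 M standard state.
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if T <= 0:
        raise ValueError("T must be positive")
    return R_KCAL * T * math.log(Kd)


def coulomb_pair_energy(r: float, eps_r: float, T: float = 298.15) -> float:
    """Coulomb energy of a +1/-1 charge pair at separation ``r`` (Angstrom).

    U = -(l_B / r) R T in kcal/mol (attractive, hence negative).  At 3 A in
    water (eps_r = 80) this is about -1.4 kcal/mol — the canonical solvent-
    exposed salt-bridge scale; ~10x larger inside a low-permittivity core.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    l_B = bjerrum_length(T, eps_r)
    return -(l_B / r) * R_KCAL * T


def screened_pair_energy(
    r: float, q1: float, q2: float, l_B: float, lambda_D: float, T: float
) -> float:
    """Debye-Hueckel screened Coulomb energy in kcal/mol.

    U = q1 q2 (l_B / r) exp(-r / lambda_D) R T.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    return q1 * q2 * (l_B / r) * math.exp(-r / lambda_D) * R_KCAL * T


@dataclass(frozen=True)
class SolutionConditions:
    """Solvent state consumed by theory and simulation.

    ``l_B`` and ``lambda_D`` are derived on construction from (T, eps_r, I)
    unless given explicitly; viscosity is in mPa s.
    """

    temperature: float  # K
    ionic_strength: float  # mol/L
    relative_permittivity: float | None = None
    viscosity: float = 0.89  # mPa s, water-like default at 25 C
    bjerrum: float = field(default=0.0)
    debye: float = field(default=0.0)

    def __post_init__(self):
        if self.temperature <= 0 or self.ionic_strength <= 0:
            raise ValueError("temperature and ionic strength must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        eps = self.relative_permittivity
        if eps is None:
            eps = water_permittivity(self.temperature)
            object.__setattr__(self, "relative_permittivity", eps)
        if self.bjerrum == 0.0:
            object.__setattr__(self, "bjerrum", bjerrum_length(self.temperature, eps))
        if self.debye == 0.0:
            object.__setattr__(
                self, "debye", debye_length(self.ionic_strength, self.bjerrum)
            )

    @property
    def kT_kcal(self) -> float:
        return R_KCAL * self.temperature
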