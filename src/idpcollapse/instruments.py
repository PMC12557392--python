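"""Observation models: FCS autocorrelation and SEC calibration.

Fluorescence correlation spectroscopy measures the intensity
autocorrelation of labelled molecules diffusing through a confocal volume.
The model used throughout is two-component 3D diffusion (labelled protein
plus residual free dye) with a triplet-state correction::

    G(tau) = (1/n) [1 + T/(1-T) exp(-tau/tau_T)]
             * sum_i f_i (1 + tau/tau_i)^-1 (1 + tau/(s^2 tau_i))^-1/2

where ``n`` is the mean particle number in the focus, ``T`` the triplet
fraction, ``tau_T`` the triplet relaxation time (fixed, 2.4 us for the
dye-protein conjugate), ``tau_i`` the diffusion times, ``s`` the axial
structure parameter and ``f_i`` the component fractions (sum to 1).
Diffusion times convert to hydrodynamic radii through
D = w^2/(4 tau_D) and the Stokes–Einstein relation.

A droplet-titration ledger tracks evaporation (solvent only) and stock
aliquot additions so the actual salt concentration at each measurement is
known.  SEC is calibrated by a log-linear fit of standard Rh against
elution volume, with prediction uncertainty propagated to unknowns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy import constants, stats

TRIPLET_TIME_DEFAULT = 2.4  # us, dye-protein conjugate average


@dataclass(frozen=True)
class FCSModelParams:
    """Parameters of the triplet + multi-component 3D diffusion model."""

    n_particles: float
    triplet_fraction: float  # [0, 1)
    triplet_time: float = TRIPLET_TIME_DEFAULT  # us
    fractions: tuple[float, ...] = (1.0,)
    diffusion_times: tuple[float, ...] = (100.0,)  # us
    structure_parameter: float = 5.0
    beam_waist: float = 250.0  # nm

    def __post_init__(self):
        if not 0 <= self.triplet_fraction < 1:
            raise ValueError("triplet fraction must be in [0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        if len(self.fractions) != len(self.diffusion_times):
            raise ValueError("fractions and diffusion times must align")
        if self.n_particles <= 0 or self.triplet_time <= 0:
            raise ValueError("n and triplet time must be positive")
        if any(t <= 0 for t in self.diffusion_times):
            raise ValueError("diffusion times must be positive")


def fcs_model(tau: "float | np.ndarray", p: FCSModelParams) -> "float | np.ndarray":
    """Autocorrelation G(tau); ``tau`` in the same time unit as the model's
    diffusion/triplet times (us by convention)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag times must be nonnegative")
    T = p.triplet_fraction
    triplet = 1.0 + (T / (1.0 - T)) * np.exp(-tau / p.triplet_time) if T > 0 else 1.0
    s2 = p.structure_parameter**2
    diff = sum(
        f / ((1.0 + tau / td) * np.sqrt(1.0 + tau / (s2 * td)))
        for f, td in zip(p.fractions, p.diffusion_times)
    )
    out = triplet * diff / p.n_particles
    return float(out) if np.ndim(out) == 0 else out


def taud_to_rh(tau_D: float, w: float, T: float, eta: float) -> float:
    """Diffusion time (us) -> hydrodynamic radius (Angstrom).

    ``w`` is the lateral beam waist in nm, ``eta`` the viscosity in mPa s.
    D = w^2 / (4 tau_D); Rh = k_B T / (6 pi eta D).
    """
    if min(tau_D, w, T, eta) <= 0:
        raise ValueError("all inputs must be positive")
    D = (w * 1e-9) ** 2 / (4.0 * tau_D * 1e-6)  # m^2/s
    rh_m = constants.k * T / (6.0 * math.pi * eta * 1e-3 * D)
    return rh_m * 1e10


def rh_to_taud(Rh: float, w: float, T: float, eta: float) -> float:
    """Inverse of :func:`taud_to_rh` (Rh in Angstrom -> tau_D in us)."""
    if min(Rh, w, T, eta) <= 0:
        raise ValueError("all inputs must be positive")
    D = constants.k * T / (6.0 * math.pi * eta * 1e-3 * Rh * 1e-10)
    return (w * 1e-9) ** 2 / (4.0 * D) * 1e6


@dataclass(frozen=True)
class FCSFitResult:
    """Per-curve estimates from the (global) FCS fit."""

    n_particles: np.ndarray
    triplet_fraction: np.ndarray
    protein_tau_D: np.ndarray  # us
    protein_tau_D_stderr: np.ndarray
    protein_fraction: np.ndarray
    structure_parameter: float
    redchi: float
    success: bool
    at_bound: bool


def fit_fcs_global(
    curves: Sequence[tuple[np.ndarray, np.ndarray]],
    weights: Sequence[np.ndarray] | None = None,
    triplet_time: float = TRIPLET_TIME_DEFAULT,
    structure_parameter: float = 5.0,
    fit_structure: bool = False,
    dye_tau_D: float | None = None,
) -> FCSFitResult:
    """Global weighted fit of the triplet + diffusion model to FCS curves.

    The triplet relaxation time is fixed (2.4 us default); the structure
    parameter is shared across curves (fixed unless ``fit_structure``).
    Per-curve free parameters: amplitude 1/n, triplet fraction, protein
    diffusion time, and — when ``dye_tau_D`` is given — the free-dye
    fraction with the dye diffusion time fixed from calibration.
    """
    if not curves:
        raise ValueError("need at least one curve")
    params = lmfit.Parameters()
    params.add("s", value=structure_parameter, min=1.0, vary=fit_structure)
    two_component = dye_tau_D is not None
    for i, (lag, g) in enumerate(curves):
        lag = np.asarray(lag, dtype=float)
        if np.log10(lag[lag > 0].max() / lag[lag > 0].min()) < 3:
            raise ValueError("lag grid must span at least 3 decades")
        params.add(f"n_{i}", value=1.0 / max(g.max(), 1e-12), min=1e-6)
        params.add(f"T_{i}", value=0.1, min=0.0, max=0.8)
        params.add(f"taud_{i}", value=float(np.median(lag)), min=1e-3)
        if two_component:
            params.add(f"fdye_{i}", value=0.1, min=0.0, max=1.0)

    def one(p, i, lag):
        fractions: tuple[float, ...]
        times: tuple[float, ...]
        if two_component:
            fd = p[f"fdye_{i}"].value
            fractions = (1.0 - fd, fd)
            times = (p[f"taud_{i}"].value, dye_tau_D)
        else:
            fractions = (1.0,)
            times = (p[f"taud_{i}"].value,)
        mp = FCSModelParams(
            n_particles=p[f"n_{i}"].value,
            triplet_fraction=p[f"T_{i}"].value,
            triplet_time=triplet_time,
            fractions=fractions,
            diffusion_times=times,
            structure_parameter=p["s"].value,
        )
        return fcs_model(lag, mp)

    def residual(p):
        res = []
        for i, (lag, g) in enumerate(curves):
            r = one(p, i, np.asarray(lag, dtype=float)) - np.asarray(g, dtype=float)
            if weights is not None:
                r = r / np.asarray(weights[i], dtype=float)
            res.append(r)
        return np.concatenate(res)

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    ncurves = len(curves)
    at_bound = False
    for i in range(ncurves):
        for name in (f"T_{i}", f"fdye_{i}") if two_component else (f"T_{i}",):
            par = p[name]
            if par.max is not None and (
                abs(par.value - par.max) < 1e-9 or abs(par.value - par.min) < 1e-9
            ):
                at_bound = True
    return FCSFitResult(
        n_particles=np.array([p[f"n_{i}"].value for i in range(ncurves)]),
        triplet_fraction=np.array([p[f"T_{i}"].value for i in range(ncurves)]),
        protein_tau_D=np.array([p[f"taud_{i}"].value for i in range(ncurves)]),
        protein_tau_D_stderr=np.array(
            [p[f"taud_{i}"].stderr or np.nan for i in range(ncurves)]
        ),
        protein_fraction=np.array(
            [1.0 - p[f"fdye_{i}"].value if two_component else 1.0
             for i in range(ncurves)]
        ),
        structure_parameter=float(p["s"].value),
        redchi=float(out.redchi),
        success=bool(out.success),
        at_bound=at_bound,
    )


# --------------------------------------------------------------------------
# Droplet titration bookkeeping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Aliquot:
    """One stock addition: time (min), volume added (uL), stock conc (M)."""

    time: float
    volume: float
    stock_concentration: float


@dataclass
class TitrationLedger:
    """Evaporating-droplet bookkeeping for sequential salt titration.

    Volume decreases linearly with time at ``evaporation_rate`` (solvent
    only: solute amount is conserved between additions) and jumps up at
    each aliquot.  Concentrations are amount/volume at each queried time.
    """

    initial_volume: float  # uL
    evaporation_rate: float = 0.0  # uL/min
    aliquots: list[Aliquot] = field(default_factory=list)

    def add(self, time: float, volume: float, stock_concentration: float) -> None:
        if self.aliquots and time < self.aliquots[-1].time:
            raise ValueError("aliquot log must be chronological")
        self.aliquots.append(Aliquot(time, volume, stock_concentration))

    def state_at(self, time: float) -> tuple[float, float]:
        """(volume uL, salt concentration M) at ``time`` minutes."""
        volume = self.initial_volume
        amount = 0.0  # umol... (uL * M = nmol x 1e-3; units cancel in c)
        t_prev = 0.0
        for al in self.aliquots:
            if al.time > time:
                break
            volume -= self.evaporation_rate * (al.time - t_prev)
            if volume <= 0:
                raise ValueError("droplet evaporated to nothing")
            volume += al.volume
            amount += al.volume * al.stock_concentration
            t_prev = al.time
        volume -= self.evaporation_rate * (time - t_prev)
        if volume <= 0:
            raise ValueError("droplet evaporated to nothing")
        return volume, amount / volume

    def concentrations(
        self, times: Sequence[float]
    ) -> list[tuple[float, float, float]]:
        """Per-measurement (time, volume, concentration) rows."""
        return [(t, *self.state_at(t)) for t in times]


# --------------------------------------------------------------------------
# SEC calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SECCalibration:
    """Log-linear SEC calibration log(Rh) = intercept + slope * Ve.

    Prediction uncertainty follows the standard regression prediction
    interval, propagated through the exponential.
    """

    slope: float
    intercept: float
    residual_std: float
    n: int
    ve_mean: float
    ve_ssx: float
    ve_range: tuple[float, float]

    def rh(self, Ve: float) -> tuple[float, float, bool]:
        """Predict (Rh, stderr, extrapolated_flag) at elution volume ``Ve``."""
        log_rh = self.intercept + self.slope * Ve
        se_log = self.residual_std * math.sqrt(
            1.0 + 1.0 / self.n + (Ve - self.ve_mean) ** 2 / self.ve_ssx
        )
        rh = math.exp(log_rh)
        extrapolated = not (self.ve_range[0] <= Ve <= self.ve_range[1])
        return rh, rh * se_log, extrapolated


def sec_calibrate(standards: Sequence[tuple[float, float]]) -> SECCalibration:
    """Fit the calibration from (Rh Angstrom, Ve mL) standards (>= 3)."""
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    rh = np.array([s[0] for s in standards], dtype=float)
    ve = np.array([s[1] for s in standards], dtype=float)
    if np.any(rh <= 0):
        raise ValueError("standard radii must be positive")
    y = np.log(rh)
    res = stats.linregress(ve, y)
    resid = y - (res.intercept + res.slope * ve)
    dof = max(1, len(standards) - 2)
    s = math.sqrt(float(np.sum(resid**2)) / dof)
    return SECCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_std=s,
        n=len(standards),
        ve_mean=float(ve.mean()),
        ve_ssx=float(np.sum((ve - ve.mean()) ** 2)),
        ve_range=(float(ve.min()), float(ve.max())),
    )


def viscosity_lookup(
    c: float,
    table: "tuple[np.ndarray, np.ndarray] | None",
    buffer_viscosity: float = 0.89,
) -> tuple[float, bool]:
    """Viscosity (mPa s) of a salt solution at concentration ``c`` (M).

    Linear interpolation in a user-supplied (concentration, viscosity)
    table; with no table the buffer value is returned together with a
    ``defaulted=True`` flag so callers can warn loudly.
    """
    if table is None:
        return buffer_viscosity, True
    cs, etas = (np.asarray(a, dtype=float) for a in table)
    return float(np.interp(c, cs, etas)), False
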