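"""Two-state apparent-binding analysis of Rh vs salt activity.

Titration of a polyanionic disordered protein with salt shrinks its
hydrodynamic radius along a sigmoid in salt activity ``a``.  Assuming
identical, non-interacting, entropically independent ion-binding sites in
large ion excess, the observable follows::

    Rh(a) = R0 ( 1 + rho * a / (Kd + a) )

with ``R0`` the salt-free radius, ``rho`` the relative size change at
saturation (negative for compaction) and ``Kd`` the apparent per-site
dissociation constant.  The saturation limit is Rmin = R0 (1 + rho), and
Kd converts to a standard binding free energy via the solution module.

Fit adequacy is judged by a Wald–Wolfowitz runs test on the signs of the
residuals in activity order (exact combinatorial null for small samples,
normal approximation beyond n = 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm

from .solution import SaltSpec, kd_to_dg


@dataclass(frozen=True)
class TitrationCurve:
    """One salt/method titration: Rh (with errors) vs concentration/activity."""

    salt: SaltSpec | None
    method: str  # "FCS" | "SEC" | "synthetic"
    concentration: np.ndarray  # mol/L
    activity: np.ndarray  # mol/L
    Rh: np.ndarray  # Angstrom
    sigma_Rh: np.ndarray | None  # Angstrom
    temperature: float = 298.15  # K

    def __post_init__(self):
        c = np.asarray(self.concentration, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        r = np.asarray(self.Rh, dtype=float)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "activity", a)
        object.__setattr__(self, "Rh", r)
        if self.sigma_Rh is not None:
            s = np.asarray(self.sigma_Rh, dtype=float)
            if np.any(s <= 0):
                raise ValueError("sigma_Rh must be positive")
            object.__setattr__(self, "sigma_Rh", s)
        if a.shape != r.shape or c.shape != r.shape:
            raise ValueError("concentration, activity and Rh must align")
        if np.any(a < 0):
            raise ValueError("activities must be nonnegative")
        order = np.argsort(c, kind="stable")
        if np.any(np.diff(a[order]) < 0):
            raise ValueError("activity must be nondecreasing with concentration")

    @property
    def n(self) -> int:
        return int(self.Rh.size)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, method: str = "synthetic", **kw
    ) -> "TitrationCurve":
        """Build from a DataFrame with columns concentration, activity, Rh
        and optionally sigma_Rh."""
        sigma = df["sigma_Rh"].to_numpy() if "sigma_Rh" in df else None
        return cls(
            salt=kw.pop("salt", None),
            method=method,
            concentration=df["concentration"].to_numpy(),
            activity=df["activity"].to_numpy(),
            Rh=df["Rh"].to_numpy(),
            sigma_Rh=sigma,
            **kw,
        )


def rh_binding_model(
    a: "float | np.ndarray", Kd: float, rho: float, R0: float
) -> "float | np.ndarray":
    """Two-state binding sigmoid Rh = R0 (1 + rho a / (Kd + a))."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("activity must be nonnegative")
    out = R0 * (1.0 + rho * a / (Kd + a))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BindingFit:
    """Fitted two-state binding parameters and diagnostics."""

    Kd: float  # mol/L
    Kd_stderr: float
    rho: float
    rho_stderr: float
    R0: float  # Angstrom
    R0_stderr: float
    Rmin: float  # Angstrom
    Rmin_stderr: float
    dG0: float  # kcal/mol
    dG0_stderr: float
    covariance: np.ndarray  # 3x3 over (log10 Kd, rho, R0)
    runs_test_p: float
    rmse: float  # Angstrom
    residuals: np.ndarray  # Rh_obs - Rh_fit in activity order
    spans_inflection: bool
    method: str = "synthetic"
    salt_name: str = ""
    temperature: float = 298.15


def rmin_from_fit(R0: float, rho: float) -> float:
    """Saturation radius Rmin = R0 (1 + rho) — the infinite-activity limit."""
    return R0 * (1.0 + rho)


def runs_test(signs: Sequence[int]) -> float:
    """Two-sided Wald–Wolfowitz runs test on a +/- sign sequence.

    The null distribution of the number of runs R given n+ positives and n-
    negatives is enumerated exactly for n <= 30::

        P(R = 2k)   = 2 C(n+-1, k-1) C(n--1, k-1) / C(n, n+)
        P(R = 2k+1) = [C(n+-1, k) C(n--1, k-1)
                       + C(n+-1, k-1) C(n--1, k)] / C(n, n+)

    and approximated by a normal beyond.  The two-sided p doubles the
    smaller tail (capped at 1).  Zeros must be removed by the caller;
    sequences with only one sign present are not testable and raise.
    """
    s = [int(np.sign(x)) for x in signs if x != 0]
    if any(x == 0 for x in s):
        raise ValueError("signs must be +/-1")
    n_pos = sum(1 for x in s if x > 0)
    n_neg = len(s) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("runs test undefined: only one sign present")
    r_obs = 1 + sum(1 for a, b in zip(s, s[1:]) if a != b)
    n = n_pos + n_neg
    if n <= 30:
        pmf = runs_null_pmf(n_pos, n_neg)
        lower = sum(p for r, p in pmf.items() if r <= r_obs)
        upper = sum(p for r, p in pmf.items() if r >= r_obs)
        return float(min(1.0, 2.0 * min(lower, upper)))
    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    z = (r_obs - mu) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def runs_null_pmf(n_pos: int, n_neg: int) -> dict[int, float]:
    """Exact null pmf of the run count for n_pos +'s and n_neg -'s."""
    total = comb(n_pos + n_neg, n_pos, exact=True)
    pmf: dict[int, float] = {}
    for k in range(1, min(n_pos, n_neg) + 1):
        pmf[2 * k] = (
            2
            * comb(n_pos - 1, k - 1, exact=True)
            * comb(n_neg - 1, k - 1, exact=True)
            / total
        )
    for k in range(1, max(n_pos, n_neg)):
        odd = comb(n_pos - 1, k, exact=True) * comb(n_neg - 1, k - 1, exact=True)
        odd += comb(n_pos - 1, k - 1, exact=True) * comb(n_neg - 1, k, exact=True)
        if odd:
            pmf[2 * k + 1] = odd / total
    return pmf


def _initial_guesses(a: np.ndarray, Rh: np.ndarray) -> tuple[float, float, float]:
    """Data-driven starting point: R0 from the large-Rh plateau, Rmin from
    the small one, Kd from the activity where Rh crosses the midpoint."""
    R0 = float(Rh.max())
    Rmin = float(Rh.min())
    rho = (Rmin - R0) / R0 if R0 > 0 else -0.3
    mid = 0.5 * (R0 + Rmin)
    below = a[Rh <= mid]
    positive = a[a > 0]
    if below.size and below.min() > 0:
        Kd = float(below.min())
    elif positive.size:
        Kd = float(np.exp(np.mean(np.log(positive))))
    else:
        Kd = 1e-3
    return Kd, rho if rho != 0 else -0.1, R0


def fit_binding(curve: TitrationCurve) -> BindingFit:
    """Weighted nonlinear least-squares fit of the two-state sigmoid.

    Kd is fitted as log10(Kd) internally (positivity and conditioning) and
    reported on the linear scale with a delta-method standard error.
    Residual-sign randomness in activity order is summarised by the exact
    runs-test p value (NaN when all residuals share one sign — itself a red
    flag reported via ``spans_inflection`` and the residual vector).
    """
    if curve.n < 5:
        raise ValueError("need at least 5 titration points")
    order = np.argsort(curve.activity, kind="stable")
    a = curve.activity[order]
    Rh = curve.Rh[order]
    sigma = curve.sigma_Rh[order] if curve.sigma_Rh is not None else np.ones_like(Rh)

    Kd0, rho0, R00 = _initial_guesses(a, Rh)
    params = lmfit.Parameters()
    params.add("log10_Kd", value=math.log10(Kd0), min=-9, max=2)
    params.add("rho", value=rho0, min=-0.999, max=2.0)
    params.add("R0", value=R00, min=1e-6)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = rh_binding_model(a, 10.0 ** p["log10_Kd"].value, p["rho"].value,
                                 p["R0"].value)
        return (model - Rh) / sigma

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-12, ftol=1e-12)
    if not result.success:
        raise RuntimeError(f"binding fit did not converge: {result.message}")
    p = result.params
    log10_Kd = p["log10_Kd"].value
    Kd = 10.0**log10_Kd
    rho = p["rho"].value
    R0 = p["R0"].value
    if result.covar is not None:
        cov = np.asarray(result.covar)
        se_log10_Kd, se_rho, se_R0 = np.sqrt(np.diag(cov))
        cov_rho_R0 = cov[1, 2]
    else:  # singular fit; propagate NaNs rather than fail
        cov = np.full((3, 3), np.nan)
        se_log10_Kd = se_rho = se_R0 = cov_rho_R0 = np.nan
    Kd_stderr = Kd * math.log(10.0) * se_log10_Kd
    Rmin = rmin_from_fit(R0, rho)
    # var(R0(1+rho)) by the delta method
    Rmin_var = (
        (1.0 + rho) ** 2 * se_R0**2
        + R0**2 * se_rho**2
        + 2.0 * (1.0 + rho) * R0 * cov_rho_R0
    )
    Rmin_stderr = math.sqrt(Rmin_var) if Rmin_var >= 0 else np.nan
    dG0 = kd_to_dg(Kd, curve.temperature)
    from .solution import R_KCAL

    dG0_stderr = R_KCAL * curve.temperature * (Kd_stderr / Kd)

    fitted = rh_binding_model(a, Kd, rho, R0)
    resid = Rh - fitted
    signs = np.sign(resid[resid != 0])
    if signs.size and np.any(signs > 0) and np.any(signs < 0):
        p_runs = runs_test(signs)
    else:
        p_runs = float("nan")
    spans = bool(a.min() < Kd < a.max())
    return BindingFit(
        Kd=Kd,
        Kd_stderr=float(Kd_stderr),
        rho=float(rho),
        rho_stderr=float(se_rho),
        R0=float(R0),
        R0_stderr=float(se_R0),
        Rmin=float(Rmin),
        Rmin_stderr=float(Rmin_stderr),
        dG0=float(dG0),
        dG0_stderr=float(dG0_stderr),
        covariance=cov,
        runs_test_p=p_runs,
        rmse=float(np.sqrt(np.mean(resid**2))),
        residuals=resid,
        spans_inflection=spans,
        method=curve.method,
        salt_name=curve.salt.name if curve.salt is not None else "",
        temperature=curve.temperature,
    )


def table_summary(fits: Sequence[BindingFit]) -> pd.DataFrame:
    """Binding-parameter table, one row per salt/method.

    Columns mirror the standard titration report: Kd [mM], rho, R0 [A],
    Rmin [A], dG0 [kcal/mol], each with its standard error, plus the
    runs-test p value and RMSE.
    """
    rows = []
    for f in fits:
        rows.append(
            {
                "method": f.method,
                "salt": f.salt_name,
                "Kd_mM": f.Kd * 1e3,
                "Kd_stderr_mM": f.Kd_stderr * 1e3,
                "rho": f.rho,
                "rho_stderr": f.rho_stderr,
                "R0_A": f.R0,
                "R0_stderr_A": f.R0_stderr,
                "Rmin_A": f.Rmin,
                "Rmin_stderr_A": f.Rmin_stderr,
                "dG0_kcal_mol": f.dG0,
                "dG0_stderr_kcal_mol": f.dG0_stderr,
                "runs_test_p": f.runs_test_p,
                "rmse_A": f.rmse,
            }
        )
    columns = [
        "method", "salt", "Kd_mM", "Kd_stderr_mM", "rho", "rho_stderr",
        "R0_A", "R0_stderr_A", "Rmin_A", "Rmin_stderr_A",
        "dG0_kcal_mol", "dG0_stderr_kcal_mol", "runs_test_p", "rmse_A",
    ]
    return pd.DataFrame(rows, columns=columns)
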