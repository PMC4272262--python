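"""Fluorescence polarization and lifetime analysis.

Steady-state polarization of a dye rigidly bound to a macromolecule obeys
the Perrin relation

    1/P - 1/3 = (1/P0 - 1/3) * (1 + 3 * tau / rho),

with P0 the intrinsic (frozen) polarization, tau the excited-state
lifetime and rho = 3 eta V / RT the rotational relaxation time.  Since
rho is proportional to eta/T, plotting (1/P - 1/3) against T/eta is
linear; the slope and intercept give P0 and rho at any stated reference
condition (water at 20 C by default).

Frequency-domain lifetimes: for a sum of exponentials with fractional
intensities f_i and lifetimes tau_i, at angular frequency w,

    S(w) = sum f_i * w*tau_i / (1 + w^2 tau_i^2)
    C(w) = sum f_i / (1 + w^2 tau_i^2)
    phase = atan(S/C),  modulation = sqrt(S^2 + C^2),

fit by weighted nonlinear least squares over phase (sigma = 0.2 deg) and
modulation (sigma = 0.004).
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .hydrocalc import WATER_20C_ETA_POISE

__all__ = [
    "PolarizationSeries",
    "PerrinFit",
    "LifetimeFit",
    "polarization",
    "grating_factor",
    "perrin_fit",
    "phase_modulation",
    "lifetime_fit",
    "correlation_time",
    "sucrose_viscosity",
]

REF_T_K = 293.15


class UndefinedPolarizationError(ValueError):
    pass


def polarization(I_par: float, I_perp: float, G: float = 1.0) -> float:
    """Steady-state polarization P = (I_par - G*I_perp)/(I_par + G*I_perp).

    ``G`` is the instrument grating correction.  Values above the
    one-photon limit of 0.5 (or below -1/3) are returned but flagged with
    a warning as unphysical.
    """
    if I_par < 0 or I_perp < 0 or G <= 0:
        raise ValueError("intensities must be >= 0 and G > 0")
    denom = I_par + G * I_perp
    if denom == 0:
        raise UndefinedPolarizationError("zero total intensity")
    P = (I_par - G * I_perp) / denom
    if P > 0.5 + 1e-12 or P < -1.0 / 3.0 - 1e-12:
        warnings.warn(f"P = {P:.3f} outside the one-photon range "
                      "[-1/3, 0.5]; check inputs")
    return P


def grating_factor(i_perp: float, i_par: float) -> float:
    """G = i_perp / i_par from the horizontal-excitation control pair."""
    if i_par <= 0 or i_perp <= 0:
        raise ValueError("control intensities must be positive")
    return i_perp / i_par


@dataclass
class PolarizationSeries:
    """(T, eta, P) triples with the dye lifetime used for Perrin analysis."""

    T_K: np.ndarray
    eta_poise: np.ndarray
    P: np.ndarray
    tau_ns: float
    meta: dict | None = None

    def __post_init__(self):
        self.T_K = np.asarray(self.T_K, dtype=float)
        self.eta_poise = np.asarray(self.eta_poise, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (len(self.T_K) == len(self.eta_poise) == len(self.P)):
            raise ValueError("T, eta, P must have equal lengths")
        if np.any(self.eta_poise <= 0) or np.any(self.T_K <= 0):
            raise ValueError("T and eta must be positive")
        if self.tau_ns <= 0:
            raise ValueError("lifetime must be positive")

    @classmethod
    def from_csv(cls, path, tau_ns: float) -> "PolarizationSeries":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   df.iloc[:, 2].to_numpy(), tau_ns)


@dataclass
class PerrinFit:
    slope: float            # per (K/poise)
    intercept: float
    slope_se: float
    intercept_se: float
    P0: float
    rho_ns: float           # at the reference condition
    rho_se_ns: float
    eta_ref: float
    T_ref: float
    r_squared: float


def perrin_fit(series: PolarizationSeries,
               eta_ref: float = WATER_20C_ETA_POISE,
               T_ref: float = REF_T_K) -> PerrinFit:
    """Ordinary least squares of (1/P - 1/3) on T/eta.

    Returns P0 = 1/(intercept + 1/3) and the rotational relaxation time
    referred to (``eta_ref``, ``T_ref``):

        rho_ref = 3 * tau * (intercept / slope) * (eta_ref / T_ref).

    A non-positive slope means no resolvable rotation on the lifetime
    timescale (rho -> infinity); reported with a warning.
    """
    x = series.T_K / series.eta_poise
    y = 1.0 / series.P - 1.0 / 3.0
    if len(x) < 3:
        raise ValueError("need at least 3 points for a Perrin fit")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate abscissa: no T/eta spread")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    P0 = 1.0 / (intercept + 1.0 / 3.0)
    if slope <= 0:
        warnings.warn("non-positive Perrin slope: molecule effectively "
                      "rigid on the lifetime timescale (rho -> inf)")
        rho = math.inf
        rho_se = math.nan
    else:
        rho = 3.0 * series.tau_ns * (intercept / slope) * (eta_ref / T_ref)
        # first-order propagation through the ratio
        rel = math.sqrt((res.stderr / slope) ** 2
                        + ((res.intercept_stderr or 0.0) / intercept) ** 2
                        if intercept != 0 else (res.stderr / slope) ** 2)
        rho_se = abs(rho) * rel
    return PerrinFit(slope=slope, intercept=intercept, slope_se=res.stderr,
                     intercept_se=res.intercept_stderr, P0=P0, rho_ns=rho,
                     rho_se_ns=rho_se, eta_ref=eta_ref, T_ref=T_ref,
                     r_squared=res.rvalue ** 2)


def correlation_time(rho_ns: float, convention: str = "debye") -> float:
    """Rotational correlation time phi from the relaxation time rho.

    ``"debye"`` (default): phi = rho / 3, the standard relation between
    the 1-radian correlation time and the 1/e relaxation time.  The
    inverted convention ``"phi=3rho"`` found in parts of the polarization
    literature is exposed for comparison only.
    """
    if rho_ns <= 0:
        raise ValueError("rho must be positive")
    if convention == "debye":
        return rho_ns / 3.0
    if convention == "phi=3rho":
        return 3.0 * rho_ns
    raise ValueError("convention must be 'debye' or 'phi=3rho'")


# ---------------------------------------------------------------------------
# frequency-domain lifetimes

def phase_modulation(freq_mhz, taus_ns, fracs) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form phase (deg) and modulation for a multi-exponential decay."""
    f = np.asarray(freq_mhz, dtype=float)
    taus = np.atleast_1d(np.asarray(taus_ns, dtype=float))
    fr = np.atleast_1d(np.asarray(fracs, dtype=float))
    if np.any(taus <= 0) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("lifetimes must be positive and fractions sum to 1")
    wt = 2.0e-3 * math.pi * f[:, None] * taus[None, :]  # omega*tau, unitless
    S = (fr * wt / (1.0 + wt ** 2)).sum(axis=1)
    C = (fr / (1.0 + wt ** 2)).sum(axis=1)
    phase = np.degrees(np.arctan2(S, C))
    modulation = np.hypot(S, C)
    return phase, modulation


@dataclass
class LifetimeFit:
    taus_ns: tuple
    fractions: tuple
    chi2: float
    n_components: int
    success: bool
    residual_phase_deg: np.ndarray
    residual_modulation: np.ndarray


def lifetime_fit(freq_mhz, phase_deg, modulation, n_components: int = 2,
                 sigma_phase: float = 0.2,
                 sigma_mod: float = 0.004) -> LifetimeFit:
    """Weighted nonlinear least squares of a 1- or 2-exponential model to
    frequency-domain phase/modulation data."""
    f = np.asarray(freq_mhz, dtype=float)
    ph = np.asarray(phase_deg, dtype=float)
    mod = np.asarray(modulation, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(f) < 2 * n_components:
        raise ValueError("need at least 2 frequencies per component")
    if np.any(mod <= 0) or np.any(mod > 1.0 + 1e-9):
        raise ValueError("modulation must lie in (0, 1]")
    if np.any(ph < 0) or np.any(ph >= 90):
        raise ValueError("phase must lie in [0, 90) degrees")

    # apparent single-exponential phase lifetime at the median frequency
    i_mid = len(f) // 2
    w_mid = 2.0e-3 * math.pi * f[i_mid]
    tau_app = max(math.tan(math.radians(ph[i_mid])) / w_mid, 0.05)

    def unpack(theta):
        if n_components == 1:
            return np.array([theta[0]]), np.array([1.0])
        t1, t2, logit = theta
        f1 = 1.0 / (1.0 + math.exp(-logit))
        return np.array([t1, t2]), np.array([f1, 1.0 - f1])

    def resid(theta):
        taus, fr = unpack(theta)
        p, m = phase_modulation(f, np.abs(taus), fr)
        return np.concatenate([(p - ph) / sigma_phase,
                               (m - mod) / sigma_mod])

    if n_components == 1:
        x0 = [tau_app]
    else:
        x0 = [0.5 * tau_app, 2.0 * tau_app, 0.0]
    fit = least_squares(resid, x0, method="lm", max_nfev=5000)
    taus, fr = unpack(fit.x)
    taus = np.abs(taus)
    order = np.argsort(taus)
    taus, fr = taus[order], fr[order]
    if n_components == 2 and abs(taus[1] - taus[0]) < 0.05 * taus[1]:
        warnings.warn("lifetime components collapsed (tau1 ~ tau2): "
                      "two-component model not identifiable from these data")
    chi2 = float(fit.cost * 2.0)
    nres = len(f)
    if not fit.success:
        raise RuntimeError(f"lifetime fit did not converge: {fit.message}")
    return LifetimeFit(taus_ns=tuple(float(t) for t in taus),
                       fractions=tuple(float(x) for x in fr),
                       chi2=chi2, n_components=n_components,
                       success=bool(fit.success),
                       residual_phase_deg=fit.fun[:nres] * sigma_phase,
                       residual_modulation=fit.fun[nres:] * sigma_mod)


# ---------------------------------------------------------------------------
# sucrose viscosity table

_SUCROSE_INTERP = None


def _sucrose_table():
    global _SUCROSE_INTERP
    if _SUCROSE_INTERP is None:
        ref = importlib.resources.files("g4shape.data") / "sucrose_viscosity.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, comment="#")
        T = df["T_C"].to_numpy(dtype=float)
        W = np.array([float(c[1:]) for c in df.columns[1:]])
        vals = df.iloc[:, 1:].to_numpy(dtype=float)
        _SUCROSE_INTERP = (RegularGridInterpolator((T, W), vals), T, W)
    return _SUCROSE_INTERP


def sucrose_viscosity(T_C: float, w_percent: float) -> float:
    """Viscosity (poise) of aqueous sucrose at ``T_C`` Celsius and
    ``w_percent`` % sucrose, by bilinear interpolation on the bundled
    standard table.  Valid 0-60 C and 0-40 %."""
    interp, T, W = _sucrose_table()
    if not (T[0] <= T_C <= T[-1]) or not (W[0] <= w_percent <= W[-1]):
        raise ValueError(
            f"({T_C} C, {w_percent}%) outside the bundled table range "
            f"[{T[0]}-{T[-1]} C] x [{W[0]}-{W[-1]}%]")
    cp = float(interp([[T_C, w_percent]])[0])
    return cp / 100.0  # cP -> poise
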