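"""Rigid-body bead-shell hydrodynamics for atomic structure models.

The calculator follows the shell-model strategy used for rigid
biomolecules: every heavy atom is inflated to a hydrated atomic element
radius (AER), the surface of the resulting union of spheres is tiled with
mini-beads of radius sigma, the grand mobility supermatrix with
Rotne-Prager-Yamakawa (RPY) pair interactions is assembled and solved for
the rigid-body resistance, and the transport properties are extrapolated
linearly in sigma to the zero-bead-size limit.  From the translational
friction, the Svedberg relation gives the sedimentation coefficient

    s = M (1 - vbar * rho) / (N_A * f_t),

and the rotational diffusion tensor gives the rotational relaxation time
rho = 1/(2 * Dr_mean), the time for the orientation correlation of the
particle to decay to 1/e.

Internally everything is CGS (poise, cm, erg); the public API uses
Svedberg, nanoseconds, Angstrom, and Dalton.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigvalsh
from scipy.spatial import cKDTree

__all__ = [
    "HydroParams",
    "HydroResult",
    "WATER_20C_ETA_POISE",
    "WATER_20C_RHO",
    "shell_model",
    "bead_cluster_rigid_body",
    "kirkwood_dt",
    "sedimentation_coefficient",
    "s20w_standardize",
    "frictional_ratio",
    "equivalent_sphere_rho0",
    "rotational_relaxation",
    "asymmetry_ratio",
    "ensemble_average",
    "max_sphere_s",
    "calibrate_aer",
]

KB = 1.380649e-16          # erg/K
NA = 6.02214076e23         # 1/mol
R_GAS = 8.314462618e7      # erg/(mol K)
A_TO_CM = 1.0e-8
WATER_20C_ETA_POISE = 0.01002
WATER_20C_RHO = 0.99823    # g/cm^3


class ConditioningError(RuntimeError):
    pass


class ResolutionError(RuntimeError):
    pass


@dataclass(frozen=True)
class HydroParams:
    """Solvent and solute parameters for transport-property predictions.

    vbar : partial specific volume, cm^3/g (0.55 for quadruplex DNA)
    hydration : bound water, g water per g DNA (0.3 assumed)
    eta : solvent viscosity, poise (water, 20 C default)
    rho_solvent : solvent density, g/cm^3
    T : absolute temperature, K
    aer : hydrated atomic element radius for shell generation, A
    """

    vbar: float = 0.55
    hydration: float = 0.3
    eta: float = WATER_20C_ETA_POISE
    rho_solvent: float = WATER_20C_RHO
    T: float = 293.15
    aer: float = 2.8

    def __post_init__(self):
        if self.vbar <= 0 or self.eta <= 0 or self.T <= 0:
            raise ValueError("vbar, eta and T must be positive")
        if not (1.5 <= self.aer <= 4.5):
            raise ValueError("AER outside the physically sensible 1.5-4.5 A")


@dataclass
class HydroResult:
    """Transport properties of one rigid structure at stated conditions."""

    f_trans: float               # translational friction, g/s
    Dt: float                    # translational diffusion, cm^2/s
    Dr: tuple                    # rotational diffusion eigenvalues, 1/s
    s: float                     # sedimentation coefficient, S
    s20w: float                  # standardized to water, 20 C, S
    f_ratio: float               # f/f0, anhydrous-sphere reference
    f_ratio_hydrated: float      # f/f0, hydrated-sphere reference
    f_ratio_convention: str
    rho_rot_ns: float            # rotational relaxation time, ns
    mass_da: float
    params: HydroParams = field(repr=False, default=None)
    detail: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# bead-level machinery

def _rpy_supermatrix(pos_cm: np.ndarray, sigma_cm: float,
                     eta: float) -> np.ndarray:
    """Grand 3Nx3N RPY mobility matrix for equal beads (overlap-corrected)."""
    n = len(pos_cm)
    d = pos_cm[:, None, :] - pos_cm[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, 1.0)
    rhat = d / r[..., None]
    outer = rhat[..., :, None] * rhat[..., None, :]
    eye = np.eye(3)

    c0 = 1.0 / (8.0 * math.pi * eta * r)
    a2r2 = (sigma_cm / r) ** 2
    far_i = c0 * (1.0 + (2.0 / 3.0) * a2r2)
    far_o = c0 * (1.0 - 2.0 * a2r2)

    c1 = 1.0 / (6.0 * math.pi * eta * sigma_cm)
    near_i = c1 * (1.0 - 9.0 * r / (32.0 * sigma_cm))
    near_o = c1 * (3.0 * r / (32.0 * sigma_cm))

    overlap = r < 2.0 * sigma_cm
    iso = np.where(overlap, near_i, far_i)
    aniso = np.where(overlap, near_o, far_o)
    blocks = iso[..., None, None] * eye + aniso[..., None, None] * outer

    self_block = c1 * eye
    idx = np.arange(n)
    blocks[idx, idx] = self_block

    return blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def bead_cluster_rigid_body(positions_a: np.ndarray, sigma_a: float,
                            eta: float, T: float) -> dict:
    """Rigid-body transport properties of a cluster of equal beads.

    ``positions_a`` in Angstrom, ``sigma_a`` bead radius in Angstrom.
    Returns the orientation-averaged translational friction (g/s) and
    diffusion (cm^2/s), evaluated at the center of diffusion, and the
    rotational diffusion eigenvalues (1/s).
    """
    pos = np.asarray(positions_a, dtype=float) * A_TO_CM
    pos = pos - pos.mean(axis=0)
    n = len(pos)
    kT_1 = KB * T
    if n == 1:
        # closed form: a lone bead is a Stokes sphere of radius sigma
        sig = sigma_a * A_TO_CM
        f1 = 6.0 * math.pi * eta * sig
        dr1 = kT_1 / (8.0 * math.pi * eta * sig ** 3)
        return {"f_trans": f1, "Dt": kT_1 / f1, "Dr": (dr1, dr1, dr1),
                "n_beads": 1}
    M = _rpy_supermatrix(pos, sigma_a * A_TO_CM, eta)
    try:
        cf = cho_factor(M, lower=False, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("singular mobility supermatrix") from exc

    B = np.zeros((3 * n, 6))
    for i in range(n):
        B[3 * i: 3 * i + 3, :3] = np.eye(3)
        B[3 * i: 3 * i + 3, 3:] = -_skew(pos[i])
    X = cho_solve(cf, B, check_finite=False)
    Xi = B.T @ X                     # 6x6 resistance at the centroid
    Xi = 0.5 * (Xi + Xi.T)
    mu = np.linalg.inv(Xi)
    a, b, c = mu[:3, :3], mu[:3, 3:], mu[3:, 3:]

    # translate to the center of diffusion (where the coupling is symmetric)
    rhs = np.array([b[2, 1] - b[1, 2], b[0, 2] - b[2, 0], b[1, 0] - b[0, 1]])
    lhs = np.trace(c) * np.eye(3) - c
    dvec = np.linalg.solve(lhs, rhs)
    Ad = _skew(dvec)
    mu_tt = a - Ad @ b.T + b @ Ad - Ad @ c @ Ad
    kT = KB * T
    Dt = kT * np.trace(mu_tt) / 3.0
    f_trans = kT / Dt
    Dr = np.sort(eigvalsh(kT * c))
    return {"f_trans": float(f_trans), "Dt": float(Dt),
            "Dr": tuple(float(x) for x in Dr), "n_beads": n}


def kirkwood_dt(positions_a: np.ndarray, sigma_a: float, eta: float,
                T: float) -> float:
    """Kirkwood double-sum estimate of the translational diffusion
    coefficient (cm^2/s) of a rigid cluster of equal beads; the classic
    pre-supermatrix approximation used here as an independent cross-check."""
    pos = np.asarray(positions_a, dtype=float) * A_TO_CM
    n = len(pos)
    sigma = sigma_a * A_TO_CM
    if n == 1:
        return KB * T / (6.0 * math.pi * eta * sigma)
    d = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    inv = 1.0 / np.where(r > 0, r, np.inf)
    double_sum = inv.sum()
    return (KB * T / (6.0 * math.pi * eta * sigma * n)) * (
        1.0 + sigma * double_sum / n)


# ---------------------------------------------------------------------------
# shell generation

def _shell_beads(coords_a: np.ndarray, aer: float, sigma: float) -> np.ndarray:
    """Mini-bead centers tiling the exposed surface of AER-inflated atoms."""
    coords = np.asarray(coords_a, dtype=float)
    # dense candidates (spacing ~0.7 sigma), later thinned to ~1.7 sigma:
    # a maximal independent set over the union surface leaves no gaps wider than the
    # bead diameter, which a sparse per-atom grid cannot guarantee
    n_pts = max(12, int(math.ceil(4.0 * math.pi * aer ** 2
                                  / (0.866 * (0.7 * sigma) ** 2))))
    i = np.arange(n_pts)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_pts
    rr = np.sqrt(1.0 - z ** 2)
    sphere = np.column_stack([rr * np.cos(golden * i),
                              rr * np.sin(golden * i), z]) * aer

    tree = cKDTree(coords)
    beads: list[np.ndarray] = []
    for k, center in enumerate(coords):
        cand = center + sphere
        neighbors = [j for j in tree.query_ball_point(center, 2.0 * aer)
                     if j != k]
        if neighbors:
            dist = np.linalg.norm(
                cand[:, None, :] - coords[neighbors][None, :, :], axis=-1)
            exposed = (dist > aer * 0.999).all(axis=1)
            cand = cand[exposed]
        if len(cand):
            beads.append(cand)
    if not beads:
        raise ResolutionError("no exposed surface found")
    pts = np.vstack(beads)
    # greedy maximal-independent-set thinning to ~1.7 sigma spacing
    keep_tree = cKDTree(pts)
    pairs = keep_tree.query_pairs(1.7 * sigma)
    neighbor: dict[int, list[int]] = {}
    for i, j in pairs:
        neighbor.setdefault(i, []).append(j)
        neighbor.setdefault(j, []).append(i)
    dropped = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        if not dropped[i]:
            for j in neighbor.get(i, ()):
                if j > i:
                    dropped[j] = True
    return pts[~dropped]


def shell_model(structure, params: HydroParams | None = None,
                sigma_list=(2.5, 2.0, 1.6), mass_da: float | None = None,
                max_beads: int = 2500) -> HydroResult:
    """Bead-shell transport properties of a structure model.

    ``structure`` is a :class:`~g4shape.qmodel_builder.StructureModel` or a
    plain (N, 3) coordinate array in Angstrom.  For each mini-bead radius
    in ``sigma_list`` (>= 3 values, decreasing) the exposed surface of the
    AER-inflated atoms is tiled and solved as a rigid bead cluster; the
    transport properties are then extrapolated linearly in sigma to the
    sigma -> 0 shell limit.  ``mass_da`` is needed for s and f/f0 (taken
    from provenance when absent).
    """
    params = params or HydroParams()
    coords = structure if isinstance(structure, np.ndarray) else structure.coords()
    if len(coords) < 10:
        raise ValueError("need at least 10 atoms for a shell model")
    sigmas = [float(s) for s in sigma_list]
    if len(sigmas) < 3 or any(b >= a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("sigma_list must hold >= 3 decreasing radii")

    per_sigma = []
    for sigma in sigmas:
        beads = _shell_beads(coords, params.aer, sigma)
        if len(beads) > max_beads:
            raise ResolutionError(
                f"{len(beads)} mini-beads at sigma={sigma} exceeds the "
                f"{max_beads} cap; use a larger sigma")
        rb = bead_cluster_rigid_body(beads, sigma, params.eta, params.T)
        rb["sigma"] = sigma
        per_sigma.append(rb)

    x = np.array(sigmas)
    Dt0 = float(np.polynomial.polynomial.polyfit(
        x, [r["Dt"] for r in per_sigma], 1)[0])
    Dr0 = tuple(
        float(np.polynomial.polynomial.polyfit(
            x, [r["Dr"][k] for r in per_sigma], 1)[0])
        for k in range(3))
    if Dt0 <= 0 or any(d <= 0 for d in Dr0):
        raise ConditioningError("sigma->0 extrapolation left the physical range")
    kT = KB * params.T
    f_trans = kT / Dt0

    mass = mass_da
    if mass is None and hasattr(structure, "provenance"):
        mass = structure.provenance.get("mass_da")
    s = s20w = f_ratio = f_ratio_h = float("nan")
    if mass is not None:
        s = sedimentation_coefficient(f_trans, mass, params)
        s20w = s20w_standardize(s, params.eta, params.rho_solvent, params)
        f_ratio = frictional_ratio(s, mass, params, convention="anhydrous")
        f_ratio_h = frictional_ratio(s, mass, params, convention="hydrated")
    rho_ns = rotational_relaxation(Dr0)
    return HydroResult(
        f_trans=f_trans, Dt=Dt0, Dr=Dr0, s=s, s20w=s20w,
        f_ratio=f_ratio, f_ratio_hydrated=f_ratio_h,
        f_ratio_convention="anhydrous",
        rho_rot_ns=rho_ns, mass_da=mass if mass is not None else float("nan"),
        params=params,
        detail={"per_sigma": per_sigma, "sigma_list": sigmas},
    )


# ---------------------------------------------------------------------------
# scalar relations

def sedimentation_coefficient(f_trans: float, mass_da: float,
                              params: HydroParams) -> float:
    """Svedberg relation: s in S from friction (g/s) and molar mass (Da)."""
    if f_trans <= 0 or mass_da <= 0:
        raise ValueError("friction and mass must be positive")
    buoyancy = 1.0 - params.vbar * params.rho_solvent
    if buoyancy <= 0:
        raise ValueError("neutral or negative buoyancy: vbar*rho >= 1")
    s_seconds = mass_da * buoyancy / (NA * f_trans)
    return s_seconds / 1.0e-13


def s20w_standardize(s_obs: float, eta_buffer: float, rho_buffer: float,
                     params: HydroParams) -> float:
    """Standardize an observed s to water at 20 C.

    s20,w = s_obs * (eta_b / eta_20,w) * (1 - vbar*rho_20,w)/(1 - vbar*rho_b).
    """
    if eta_buffer <= 0 or rho_buffer <= 0:
        raise ValueError("buffer viscosity and density must be positive")
    num = 1.0 - params.vbar * WATER_20C_RHO
    den = 1.0 - params.vbar * rho_buffer
    if num * den <= 0:
        raise ValueError("buoyancy term changes sign between conditions")
    return s_obs * (eta_buffer / WATER_20C_ETA_POISE) * (num / den)


def _sphere_radius_cm(mass_da: float, params: HydroParams,
                      hydrated: bool) -> float:
    vol_per_g = params.vbar + (params.hydration if hydrated else 0.0)
    vol = mass_da * vol_per_g / NA
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)


def frictional_ratio(s: float, mass_da: float, params: HydroParams,
                     convention: str = "anhydrous") -> float:
    """f/f0 from an s value; the reference sphere holds the particle's mass
    at vbar alone (``anhydrous``) or vbar + bound water (``hydrated``)."""
    if s <= 0:
        raise ValueError("s must be positive")
    buoyancy = 1.0 - params.vbar * params.rho_solvent
    if buoyancy <= 0:
        raise ValueError("neutral or negative buoyancy")
    f = mass_da * buoyancy / (NA * s * 1.0e-13)
    r0 = _sphere_radius_cm(mass_da, params, hydrated=(convention == "hydrated"))
    f0 = 6.0 * math.pi * params.eta * r0
    return f / f0


def max_sphere_s(mass_da: float, params: HydroParams) -> float:
    """s of the equivalent hydrated sphere — the maximum s the mass can have."""
    r = _sphere_radius_cm(mass_da, params, hydrated=True)
    f0 = 6.0 * math.pi * params.eta * r
    return sedimentation_coefficient(f0, mass_da, params)


def equivalent_sphere_rho0(mass_da: float, params: HydroParams) -> float:
    """Rotational relaxation time rho0 (ns) of the equivalent anhydrous
    sphere: rho0 = 3 * eta * M * vbar / (R * T)."""
    if mass_da < 0:
        raise ValueError("mass must be non-negative")
    rho0_s = 3.0 * params.eta * mass_da * params.vbar / (R_GAS * params.T)
    return rho0_s * 1.0e9


def rotational_relaxation(dr_eigenvalues) -> float:
    """Isotropic-average rotational relaxation time in ns: 1/(2 * mean Dr)."""
    dr = np.asarray(dr_eigenvalues, dtype=float)
    if dr.size != 3 or np.any(dr <= 0):
        raise ValueError("need three positive rotational eigenvalues")
    return float(1.0e9 / (2.0 * dr.mean()))


def asymmetry_ratio(rho_measured_ns: float, rho0_ns: float) -> float:
    """rho/rho0: unity for an anhydrous sphere, > 1 for asymmetric or
    hydrated particles."""
    if rho_measured_ns <= 0 or rho0_ns <= 0:
        raise ValueError("relaxation times must be positive")
    return rho_measured_ns / rho0_ns


def ensemble_average(results: list[HydroResult]) -> dict:
    """Mean and min-max range of each transport property over snapshots."""
    if not results:
        raise ValueError("empty ensemble")
    out = {}
    for prop in ("s20w", "s", "rho_rot_ns", "Dt", "f_trans"):
        vals = np.array([getattr(r, prop) for r in results], dtype=float)
        out[prop] = {"mean": float(vals.mean()),
                     "min": float(vals.min()), "max": float(vals.max()),
                     "range": float(vals.max() - vals.min())}
    out["n"] = len(results)
    return out


def calibrate_aer(structure, mass_da: float, target_s20w: float,
                  params: HydroParams | None = None,
                  bounds: tuple[float, float] = (2.0, 4.0),
                  sigma_list=(2.5, 2.0, 1.6), tol: float = 5e-3) -> float:
    """Tune the atomic element radius so a reference structure reproduces a
    target s20,w (the shell-model calibration step for quadruplex DNA)."""
    from scipy.optimize import brentq

    params = params or HydroParams()

    def gap(aer):
        res = shell_model(structure, replace(params, aer=aer),
                          sigma_list=sigma_list, mass_da=mass_da)
        return res.s20w - target_s20w

    lo, hi = bounds
    glo, ghi = gap(lo), gap(hi)
    if glo * ghi > 0:
        warnings.warn("target s outside the AER bracket; returning the "
                      "closer endpoint")
        return lo if abs(glo) < abs(ghi) else hi
    return float(brentq(gap, lo, hi, xtol=tol))
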