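"""Idealized atomic models of multimeric G-quadruplex architectures.

Builds coordinate models of the candidate folds of a long G-rich promoter
strand — a coaxial stack of parallel quadruplex units, an unstacked
"beads-on-a-string" arrangement, and a duplex-quadruplex hybrid — for
downstream bead-shell hydrodynamic evaluation.

Geometry conventions (all lengths in Angstrom, right-handed frame, helix
axis = z):

* G-quartets are planar; within a unit consecutive quartets are separated
  by a helical rise of 3.3 A with a 30 degree twist per step (standard
  parallel-quadruplex values).
* Tetrad guanines are placed so the four O6 carbonyls ring the axis at
  ~2.55 A (the K+ coordination cage) and the C1'-C1' diagonal is ~15 A.
* Propeller loops, inter-unit linkers and flanking nucleotides are built
  as smooth Bezier arcs of residue centers outside the grooves, each
  center dressed with the residue's full heavy-atom complement packed
  into a compact 2.5 A sphere (an idealized, conformation-agnostic
  nucleotide; only the excluded envelope matters downstream).
* B-form duplex: 3.4 A rise, 36 degree twist, ~20 A diameter.

All builders are deterministic given their parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Residue",
    "StructureModel",
    "GeometryError",
    "build_parallel_unit",
    "stack_units",
    "build_beads_on_string",
    "build_duplex_quadruplex_hybrid",
    "build_hairpin_duplex",
    "build_htert_model",
    "write_pdb",
    "read_pdb",
]

RISE = 3.3            # A per quartet step
TWIST = 30.0          # deg per quartet step
INTERFACE_GAP = 3.4   # A between terminal quartets of stacked units
DUPLEX_RISE = 3.4
DUPLEX_TWIST = 36.0
LINKER_RISE = 5.9     # A per nt, extended single strand
R_O6 = 2.55           # O6 carbonyl ring radius
R_GLY = 6.1           # glycosidic N radius in a quartet
GLY_BOND = 1.47       # N-C1' bond length
BALL_RADIUS = 2.5     # compact dressed-residue radius
CLASH_CUTOFF = 1.5

# Planar base heavy-atom templates (x, y in A, base standard frames).
_BASE_2D = {
    "DG": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "DA": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "DC": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "DT": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
        "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
    },
}
_GLY_N = {"DG": "N9", "DA": "N9", "DC": "N1", "DT": "N1"}

# Sugar-phosphate heavy atoms as offsets from C1' in the residue's local
# (radial u, tangential t, axial z) frame.
_BACKBONE_LOCAL = {
    "C2'": (0.9, 1.0, -0.5),
    "C3'": (1.9, 0.7, 0.3),
    "O3'": (2.2, 1.2, 1.6),
    "O4'": (0.5, -1.2, 0.4),
    "C4'": (1.8, -0.6, 0.6),
    "C5'": (2.2, -1.5, 1.4),
    "O5'": (2.0, -0.9, -1.4),
    "P": (2.8, -0.2, -2.2),
    "OP1": (3.9, -0.6, -2.4),
    "OP2": (2.6, 1.0, -3.0),
}


def _atom_names(resname: str) -> list[str]:
    return list(_BASE_2D[resname]) + ["C1'"] + list(_BACKBONE_LOCAL)


class GeometryError(ValueError):
    """Raised for impossible builder inputs or steric clashes."""


@dataclass
class Residue:
    """One nucleotide: name (DG/DA/DC/DT), structural role, and heavy atoms."""

    name: str
    role: str  # quartet | loop | linker | duplex | hairpin_loop | flank
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    quartet: tuple | None = None  # (unit_index, layer_index, tract_index)

    @property
    def elements(self) -> list[str]:
        return [n[0] for n in self.atom_names]

    def copy(self) -> "Residue":
        return Residue(self.name, self.role, list(self.atom_names),
                       self.coords.copy(), self.quartet)


@dataclass
class StructureModel:
    """An atomic model: ordered residues plus builder provenance."""

    residues: list[Residue]
    provenance: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.coords) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])

    def elements(self) -> list[str]:
        return [e for r in self.residues for e in r.elements]

    def copy(self) -> "StructureModel":
        return StructureModel([r.copy() for r in self.residues],
                              dict(self.provenance))

    def transform(self, rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None) -> "StructureModel":
        out = self.copy()
        for r in out.residues:
            if rotation is not None:
                r.coords = r.coords @ rotation.T
            if translation is not None:
                r.coords = r.coords + np.asarray(translation, dtype=float)
        return out

    def radius_of_gyration(self) -> float:
        xyz = self.coords()
        c = xyz.mean(axis=0)
        return float(np.sqrt(((xyz - c) ** 2).sum(axis=1).mean()))

    def axial_extent(self) -> float:
        z = self.coords()[:, 2]
        return float(z.max() - z.min())

    def quartet_layers(self) -> list[dict]:
        """Quartet layers sorted by mean z; each entry lists its residues."""
        groups: dict[tuple, list[Residue]] = {}
        for r in self.residues:
            if r.role == "quartet":
                groups.setdefault(r.quartet[:2], []).append(r)
        layers = []
        for key, members in groups.items():
            base = np.vstack([m.coords[: len(_BASE_2D[m.name])] for m in members])
            layers.append({"unit": key[0], "layer": key[1],
                           "z": float(base[:, 2].mean()),
                           "residues": members,
                           "rms_out_of_plane": float(base[:, 2].std())})
        layers.sort(key=lambda d: d["z"])
        return layers

    def check_clashes(self, cutoff: float = CLASH_CUTOFF) -> list[tuple]:
        """Pairs of atoms from non-bonded residues closer than ``cutoff``.

        Atoms within one residue, and in chain-adjacent residues, are
        exempt (those distances are set by covalent geometry).
        """
        from scipy.spatial import cKDTree

        xyz = self.coords()
        owner = np.concatenate(
            [np.full(len(r.coords), i) for i, r in enumerate(self.residues)]
        )
        tree = cKDTree(xyz)
        clashes = []
        for i, j in tree.query_pairs(cutoff):
            if abs(int(owner[i]) - int(owner[j])) > 1:
                clashes.append((int(i), int(j),
                                float(np.linalg.norm(xyz[i] - xyz[j]))))
        return clashes

    def validate(self, rise: float = RISE, rise_tol: float = 0.1) -> None:
        """Assert the structural invariants (quartet geometry, clashes)."""
        layers = self.quartet_layers()
        for lay in layers:
            if len(lay["residues"]) != 4:
                raise GeometryError(
                    f"quartet layer {lay['layer']} has {len(lay['residues'])} "
                    "guanines (expected 4)")
            if any(r.name != "DG" for r in lay["residues"]):
                raise GeometryError("quartet layer contains non-guanine residue")
            if lay["rms_out_of_plane"] > 0.5:
                raise GeometryError("quartet layer is not planar")
        by_unit: dict[int, list[dict]] = {}
        for lay in layers:
            by_unit.setdefault(lay["unit"], []).append(lay)
        for unit_layers in by_unit.values():
            unit_layers.sort(key=lambda d: d["layer"])
            for a, b in zip(unit_layers, unit_layers[1:]):
                dz = abs(b["z"] - a["z"])
                if abs(dz - rise) > rise_tol:
                    raise GeometryError(
                        f"inter-quartet rise {dz:.2f} A deviates from "
                        f"{rise} +/- {rise_tol} A")
        clashes = self.check_clashes()
        if clashes:
            i, j, d = min(clashes, key=lambda c: c[2])
            raise GeometryError(
                f"{len(clashes)} steric clash(es); worst pair atoms "
                f"{i},{j} at {d:.2f} A")


# ---------------------------------------------------------------------------
# low-level geometry helpers

def _rot2(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def _rotz(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rigid_map_2d(src1, src2, dst1, dst2):
    """Rotation+translation (no reflection) sending src1->dst1, src2->dst2."""
    src1, src2 = np.asarray(src1), np.asarray(src2)
    dst1, dst2 = np.asarray(dst1), np.asarray(dst2)
    vs, vd = src2 - src1, dst2 - dst1
    ang = math.degrees(math.atan2(vd[1], vd[0]) - math.atan2(vs[1], vs[0]))
    R = _rot2(ang)
    t = dst1 - R @ src1
    return R, t


_QUARTET_POSE_CACHE: dict = {}


def _quartet_pose(r_gly: float = R_GLY) -> tuple[np.ndarray, np.ndarray]:
    """In-plane pose (R, t) of the tetrad guanine template such that four
    90-degree copies form a Hoogsteen-bonded G-quartet.

    Constraints: N1(k)...O6(k+1) = 2.91 A, N2(k)...N7(k+1) = 2.86 A,
    glycosidic N9 at radius ``r_gly``.
    """
    if r_gly in _QUARTET_POSE_CACHE:
        return _QUARTET_POSE_CACHE[r_gly]
    from scipy.optimize import least_squares

    tmpl = _BASE_2D["DG"]
    pts = {k: np.array(v) for k, v in tmpl.items()}
    r90 = _rot2(90.0)

    def place(params, name):
        theta, tx, ty = params
        return _rot2(theta) @ pts[name] + np.array([tx, ty])

    def residuals(params):
        n1, n2, n9 = (place(params, n) for n in ("N1", "N2", "N9"))
        o6n, n7n = (r90 @ place(params, n) for n in ("O6", "N7"))
        # two Hoogsteen H-bonds plus a soft glycosidic-radius target
        return [np.linalg.norm(n1 - o6n) - 2.91,
                np.linalg.norm(n2 - n7n) - 2.86,
                0.3 * (np.linalg.norm(n9) - r_gly)]

    best = None
    for th0 in range(-180, 180, 45):
        fit = least_squares(residuals, [float(th0), 3.0, 0.0])
        if best is None or fit.cost < best.cost:
            best = fit
    if best.cost > 0.05:
        raise GeometryError("quartet pose solve failed")
    theta, tx, ty = best.x
    R, t = _rot2(theta), np.array([tx, ty])
    _QUARTET_POSE_CACHE[r_gly] = (R, t)
    return R, t


def _base_plane_targets(resname: str, r_inner: float, r_gly: float,
                        phi_deg: float):
    """In-plane targets placing a base with its glycosidic N at radius
    ``r_gly`` and its inner (H-bonding) reference atom near the axis."""
    tmpl = _BASE_2D[resname]
    gly = np.array(tmpl[_GLY_N[resname]])
    inner_name = {"DG": "O6", "DA": "C6", "DC": "C4", "DT": "C4"}[resname]
    inner = np.array(tmpl[inner_name])
    d = float(np.linalg.norm(gly - inner))
    phi = math.radians(phi_deg)
    p_in = r_inner * np.array([math.cos(phi), math.sin(phi)])
    # glycosidic N on the circle of radius r_gly at distance d from p_in,
    # counterclockwise of the inner anchor (sets the handedness)
    dot = (r_gly ** 2 + r_inner ** 2 - d ** 2) / 2.0
    # solve p . p_in = dot with |p| = r_gly
    u = p_in / r_inner
    v = np.array([-u[1], u[0]])
    along = dot / r_inner
    perp_sq = r_gly ** 2 - along ** 2
    if perp_sq <= 0:
        raise GeometryError("base placement radii are inconsistent")
    p_gly = along * u + math.sqrt(perp_sq) * v
    return inner, gly, p_in, p_gly


def _quartet_residue(phi_deg: float, z: float, quartet,
                     r_gly: float = R_GLY) -> Residue:
    """Tetrad guanine: solved quartet pose rotated to ``phi_deg``, with the
    helical backbone cluster radially outside the glycosidic nitrogen."""
    R, t = _quartet_pose(r_gly)
    names, xy = [], []
    for name, p in _BASE_2D["DG"].items():
        names.append(name)
        xy.append(R @ np.array(p) + t)
    n9 = xy[names.index("N9")]
    u = n9 / np.linalg.norm(n9)
    c1 = n9 + GLY_BOND * u
    names.append("C1'")
    xy.append(c1)
    tvec = np.array([-u[1], u[0]])
    zoff = [0.0] * len(xy)
    for name, (du, dt, dz) in _BACKBONE_LOCAL.items():
        names.append(name)
        xy.append(c1 + du * u + dt * tvec)
        zoff.append(dz)
    rot = _rot2(phi_deg)
    coords = np.array([[*(rot @ p), z + dz] for p, dz in zip(xy, zoff)])
    return Residue("DG", "quartet", names, coords, quartet)


def _planar_residue(resname: str, phi_deg: float, z: float, r_inner: float,
                    r_gly: float, role: str, quartet=None,
                    backbone_sign: float = 1.0) -> Residue:
    """A residue with its base in the z-plane and a helical backbone cluster."""
    inner_t, gly_t, p_in, p_gly = _base_plane_targets(
        resname, r_inner, r_gly, phi_deg)
    R, t = _rigid_map_2d(inner_t, gly_t, p_in, p_gly)
    names, coords = [], []
    tmpl = _BASE_2D[resname]
    for name, xy in tmpl.items():
        p = R @ np.array(xy) + t
        names.append(name)
        coords.append((p[0], p[1], z))
    # C1' radially outward of the glycosidic N
    u = p_gly / np.linalg.norm(p_gly)
    c1 = p_gly + GLY_BOND * u
    names.append("C1'")
    coords.append((c1[0], c1[1], z))
    tvec = np.array([-u[1], u[0]])
    for name, (du, dt, dz) in _BACKBONE_LOCAL.items():
        p = c1 + du * u + dt * tvec
        names.append(name)
        coords.append((p[0], p[1], z + backbone_sign * dz))
    return Residue(resname, role, names, np.array(coords, dtype=float), quartet)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    zval = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - zval ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), zval])


def _ball_residue(resname: str, center: np.ndarray, role: str,
                  orient_index: int = 0,
                  radius: float = BALL_RADIUS) -> Residue:
    """Full heavy-atom complement packed on a sphere shell around ``center``.

    An idealized single-nucleotide envelope for loops/linkers/flanks where
    the actual conformation is unresolved; deterministic orientation varies
    with ``orient_index`` so stacked balls do not align artificially.
    """
    names = _atom_names(resname)
    pts = _fibonacci_sphere(len(names)) * radius
    pts = pts @ _rotz(37.0 * orient_index).T
    return Residue(resname, role, names,
                   pts + np.asarray(center, dtype=float))


def _bezier_path(p0, c1, c2, p3, n: int) -> np.ndarray:
    """``n`` arclength-uniform interior points on a cubic Bezier curve."""
    t = np.linspace(0.0, 1.0, 400)[:, None]
    pts = ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * c1
           + 3 * (1 - t) * t ** 2 * c2 + t ** 3 * p3)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = s[-1] * (np.arange(1, n + 1) / (n + 1))
    idx = np.searchsorted(s, targets)
    return pts[np.clip(idx, 0, len(pts) - 1)]


def _radial(p: np.ndarray) -> np.ndarray:
    u = np.array([p[0], p[1], 0.0])
    nrm = np.linalg.norm(u)
    return u / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])


def _arc_residues(seq: str, start: np.ndarray, end: np.ndarray, role: str,
                  bulge: float = 4.5, lift: float = 0.0,
                  orient_offset: int = 0,
                  r_min: float | None = None) -> list[Residue]:
    """Dressed-residue arc from ``start`` to ``end`` bulging radially outward.

    ``r_min`` pushes interior centers out to at least that cylinder radius
    (clearance from the helical core for linkers crossing an interface).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    c1 = start + bulge * _radial(start) + np.array([0.0, 0.0, lift])
    c2 = end + bulge * _radial(end) + np.array([0.0, 0.0, lift])
    centers = _bezier_path(start, c1, c2, end, len(seq))
    if r_min is not None:
        for c in centers:
            r = math.hypot(c[0], c[1])
            if 1e-9 < r < r_min:
                c[:2] *= r_min / r
    return [
        _ball_residue("D" + b, c, role, orient_index=orient_offset + i)
        for i, (b, c) in enumerate(zip(seq.upper(), centers))
    ]


_BALL_ROLES = frozenset({"loop", "linker", "flank", "hairpin_loop"})


def _resolve_ball_clashes(model: StructureModel, max_iter: int = 300,
                          step_pad: float = 0.25) -> StructureModel:
    """Deterministic steric relaxation of dressed-residue placements.

    Arc-placed residues (loops, linkers, flanks) are rigid balls whose
    ideal path may graze the helical core or each other; each offending
    ball is translated directly away from its closest clash partner until
    the model satisfies the 1.5 A non-bonded cutoff.  Quartet and duplex
    residues never move.
    """
    out = model.copy()
    for _ in range(max_iter):
        clashes = out.check_clashes()
        if not clashes:
            return out
        owner = np.concatenate(
            [np.full(len(r.coords), i) for i, r in enumerate(out.residues)])
        xyz = out.coords()
        moved = False
        # worst clash first; one move per iteration keeps this deterministic
        i, j, d = min(clashes, key=lambda c: c[2])
        ri, rj = int(owner[i]), int(owner[j])
        for mover, anchor_atom in ((ri, j), (rj, i)):
            if out.residues[mover].role in _BALL_ROLES:
                center = out.residues[mover].coords.mean(axis=0)
                away = center - xyz[anchor_atom]
                nrm = np.linalg.norm(away)
                away = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
                shift = (CLASH_CUTOFF - d + step_pad) * away
                out.residues[mover].coords = out.residues[mover].coords + shift
                moved = True
                break
        if not moved:  # clash between two rigid residues: cannot repair
            break
    remaining = out.check_clashes()
    if remaining:
        raise GeometryError(
            f"clash relaxation failed; {len(remaining)} contacts remain")
    return out


def _tract_anchor(unit: "StructureModel", unit_index: int, tract: int,
                  layer: int, push: float = 2.4) -> np.ndarray:
    """Backbone-side anchor point of a tract residue, pushed radially out."""
    for r in unit.residues:
        if r.role == "quartet" and r.quartet == (unit_index, layer, tract):
            c1 = r.coords[r.atom_names.index("C1'")]
            return c1 + push * _radial(c1)
    raise GeometryError(f"no quartet residue for tract {tract} layer {layer}")


# ---------------------------------------------------------------------------
# builders

def build_parallel_unit(n_quartets: int = 3,
                        loop_lengths: tuple[int, int, int] = (1, 2, 1),
                        loop_seqs: tuple[str, str, str] | None = None,
                        rise: float = RISE, twist: float = TWIST,
                        unit_index: int = 0, antiparallel: bool = False,
                        validate: bool = True) -> StructureModel:
    """An all-parallel G-quadruplex unit with propeller loops.

    Four G-tracts of ``n_quartets`` guanines run 5'->3' along +z at 90
    degree intervals; each of the three connecting loops (lengths >= 1 nt)
    double-chain-reverses down the outside of a groove.  With
    ``antiparallel=True`` the same tetrad core is kept but the loops are
    laid edgewise over the top/bottom faces and the unit is labelled as the
    antiparallel topology (an envelope-level idealization).
    """
    if n_quartets < 2:
        raise GeometryError("a quadruplex unit needs at least 2 stacked quartets")
    if len(loop_lengths) != 3 or any(n < 1 for n in loop_lengths):
        raise GeometryError("need three propeller loops of >= 1 nt each")
    if loop_seqs is None:
        loop_seqs = tuple("T" * n for n in loop_lengths)
    if tuple(len(s) for s in loop_seqs) != tuple(loop_lengths):
        raise GeometryError("loop sequences do not match loop lengths")

    tracts: list[list[Residue]] = []
    for k in range(4):
        tract = []
        for j in range(n_quartets):
            phi = 90.0 * k + twist * j
            res = _quartet_residue(phi, rise * j, quartet=(unit_index, j, k))
            tract.append(res)
        tracts.append(tract)

    residues: list[Residue] = []
    model = StructureModel([r for t in tracts for r in t])  # anchor lookup
    z_top = rise * (n_quartets - 1)
    for k in range(4):
        residues.extend(tracts[k])
        if k == 3:
            break
        seq = loop_seqs[k]
        if not antiparallel:
            a0 = _tract_anchor(model, unit_index, k, n_quartets - 1)
            a1 = _tract_anchor(model, unit_index, k + 1, 0)
            residues.extend(_arc_residues(seq, a0, a1, "loop", bulge=5.5,
                                          orient_offset=7 * k))
        else:
            layer = n_quartets - 1 if k % 2 == 0 else 0
            zoff = 5.6 if k % 2 == 0 else -5.6
            a0 = _tract_anchor(model, unit_index, k, layer)
            a1 = _tract_anchor(model, unit_index, k + 1, layer)
            mid = np.array([0.0, 0.0, (a0 + a1)[2] / 2 + zoff])
            c1 = a0 * 0.55 + mid * 0.45 + np.array([0, 0, zoff])
            c2 = a1 * 0.55 + mid * 0.45 + np.array([0, 0, zoff])
            centers = _bezier_path(a0, c1, c2, a1, len(seq))
            residues.extend(
                _ball_residue("D" + b, c, "loop", orient_index=7 * k + i)
                for i, (b, c) in enumerate(zip(seq, centers)))

    out = StructureModel(residues, provenance={
        "builder": "parallel_unit", "n_quartets": n_quartets,
        "loop_lengths": tuple(loop_lengths), "rise": rise, "twist": twist,
        "topology": "antiparallel" if antiparallel else "parallel",
        "unit_index": unit_index, "z_top": z_top,
    })
    out = _resolve_ball_clashes(out)
    if validate:
        out.validate(rise=rise)
    return out


def _unit_span(unit: StructureModel) -> tuple[float, float]:
    zs = [lay["z"] for lay in unit.quartet_layers()]
    return min(zs), max(zs)


def stack_units(units: list[StructureModel],
                interface_gap: float = INTERFACE_GAP,
                linker_seqs: list[str] | None = None,
                twist: float = TWIST,
                validate: bool = True) -> StructureModel:
    """Coaxial 5'->3' stack of quadruplex units.

    Terminal quartet planes of adjacent units are separated by
    ``interface_gap`` along the shared axis and the helical twist continues
    across the interface.  ``linker_seqs`` (one per junction, may be empty
    strings) are inserted as outside arcs.
    """
    if not units:
        raise GeometryError("nothing to stack")
    if len(units) == 1:
        return units[0].copy()
    if interface_gap <= 0:
        raise GeometryError("interface gap must be positive")
    n_junction = len(units) - 1
    if linker_seqs is None:
        linker_seqs = [""] * n_junction
    if len(linker_seqs) != n_junction:
        raise GeometryError("need one linker sequence per junction")

    placed: list[StructureModel] = []
    z_shift, twist_shift = 0.0, 0.0
    for i, unit in enumerate(units):
        lo, hi = _unit_span(unit)
        u = unit.transform(rotation=_rotz(twist_shift),
                           translation=np.array([0.0, 0.0, z_shift - lo]))
        # re-key quartet unit indices so layers stay distinguishable
        for r in u.residues:
            if r.quartet is not None:
                r.quartet = (i, r.quartet[1], r.quartet[2])
        placed.append(u)
        z_shift += (hi - lo) + interface_gap
        twist_shift += twist * ((hi - lo) / RISE + 1.0)

    residues: list[Residue] = []
    for i, u in enumerate(placed):
        residues.extend(u.residues)
        if i < n_junction and linker_seqs[i]:
            nq_i = max(r.quartet[1] for r in u.residues if r.quartet)
            a0 = _tract_anchor(u, i, 3, nq_i)
            nxt = placed[i + 1]
            a1 = _tract_anchor(nxt, i + 1, 0, 0)
            residues.extend(_arc_residues(linker_seqs[i], a0, a1, "linker",
                                          bulge=8.0, orient_offset=11 * i,
                                          r_min=14.5))
    out = StructureModel(residues, provenance={
        "builder": "stacked", "n_units": len(units),
        "interface_gap": interface_gap,
        "topology": "stacked-" + "/".join(u.provenance.get("topology", "?")
                                          for u in units),
    })
    out = _resolve_ball_clashes(out)
    if validate:
        out.validate()
    return out


def build_beads_on_string(units: list[StructureModel],
                          linker_nt: int = 3,
                          linker_rise: float = LINKER_RISE,
                          validate: bool = True) -> StructureModel:
    """Unstacked multi-quadruplex chain: the same units joined by extended
    single-strand linkers (5.9 A/nt) with no inter-unit quartet stacking
    (terminal-quartet plane separation > 10 A requires linker_nt >= 2)."""
    if not units:
        raise GeometryError("no units")
    if len(units) == 1:
        return units[0].copy()
    if linker_nt < 1:
        raise GeometryError("beads-on-a-string needs >= 1 linker nt")
    span = linker_nt * linker_rise

    placed: list[StructureModel] = []
    z_shift = 0.0
    for i, unit in enumerate(units):
        lo, hi = _unit_span(unit)
        u = unit.transform(rotation=_rotz(60.0 * i),
                           translation=np.array([0.0, 0.0, z_shift - lo]))
        for r in u.residues:
            if r.quartet is not None:
                r.quartet = (i, r.quartet[1], r.quartet[2])
        placed.append(u)
        z_shift += (hi - lo) + span

    residues: list[Residue] = []
    for i, u in enumerate(placed):
        residues.extend(u.residues)
        if i < len(placed) - 1:
            nq_i = max(r.quartet[1] for r in u.residues if r.quartet)
            a0 = _tract_anchor(u, i, 3, nq_i)
            a1 = _tract_anchor(placed[i + 1], i + 1, 0, 0)
            # extended path: gentle outward arc spanning the full gap
            residues.extend(_arc_residues("T" * linker_nt, a0, a1, "linker",
                                          bulge=3.0, orient_offset=13 * i))
    out = StructureModel(residues, provenance={
        "builder": "beads_on_string", "n_units": len(units),
        "linker_nt": linker_nt, "linker_rise": linker_rise,
        "topology": "beads-on-a-string",
    })
    out = _resolve_ball_clashes(out)
    if validate:
        out.validate()
    return out


def build_hairpin_duplex(n_bp: int = 8, loop_nt: int = 4,
                         rise: float = DUPLEX_RISE, twist: float = DUPLEX_TWIST,
                         validate: bool = True) -> StructureModel:
    """A B-form DNA hairpin: ``n_bp`` G-C steps capped by a ``loop_nt`` loop.

    Standard B geometry (3.4 A rise, 36 deg twist, ~20 A diameter); the
    terminal loop is a dressed-residue arc over the top of the stem.
    """
    if n_bp < 1:
        raise GeometryError("hairpin stem needs >= 1 bp")
    strand_a, strand_b = [], []
    for j in range(n_bp):
        phi = twist * j
        z = rise * j
        ra = _planar_residue("DG", phi, z, 3.4, 5.9, "duplex")
        rb = _planar_residue("DC", phi + 152.0, z, 4.4, 5.9, "duplex",
                             backbone_sign=-1.0)
        strand_a.append(ra)
        strand_b.append(rb)
    residues = list(strand_a)
    if loop_nt:
        top = strand_a[-1]
        a0 = top.coords[top.atom_names.index("C1'")]
        a0 = a0 + 2.0 * _radial(a0)
        bot = strand_b[-1]
        a1 = bot.coords[bot.atom_names.index("C1'")]
        a1 = a1 + 2.0 * _radial(a1)
        lift = 6.0 + 1.2 * loop_nt
        c1 = a0 + 2.5 * _radial(a0) + np.array([0, 0, lift])
        c2 = a1 + 2.5 * _radial(a1) + np.array([0, 0, lift])
        centers = _bezier_path(a0, c1, c2, a1, loop_nt)
        residues.extend(_ball_residue("DT", c, "hairpin_loop", orient_index=i)
                        for i, c in enumerate(centers))
    residues.extend(reversed(strand_b))
    out = StructureModel(residues, provenance={
        "builder": "hairpin_duplex", "n_bp": n_bp, "loop_nt": loop_nt,
        "rise": rise, "twist": twist, "topology": "hairpin-duplex",
    })
    out = _resolve_ball_clashes(out)
    if validate:
        out.validate()
    return out


def build_duplex_quadruplex_hybrid(
        quartets_per_unit: int = 3,
        unit_loops: tuple[int, int, int] = (2, 3, 2),
        hairpin_bp: int = 8, hairpin_loop_nt: int = 4,
        connector_nt: int = 3, gap: float = 3.5,
        flank_nt: int = 4,
        validate: bool = True) -> StructureModel:
    """The earlier-proposed mixed architecture: one parallel quadruplex, an
    8-bp B-form hairpin, and one antiparallel quadruplex threaded on a
    common axis with flexible connectors (no coaxial quartet stacking)."""
    if hairpin_bp < 1:
        raise GeometryError("hybrid model requires a hairpin stem of >= 1 bp")
    par = build_parallel_unit(quartets_per_unit, unit_loops, unit_index=0,
                              validate=False)
    hp = build_hairpin_duplex(hairpin_bp, hairpin_loop_nt, validate=False)
    anti = build_parallel_unit(quartets_per_unit, unit_loops, unit_index=1,
                               antiparallel=True, validate=False)

    # axial placement with flexible gaps (no stacking interfaces)
    def _zspan(m):
        z = m.coords()[:, 2]
        return float(z.min()), float(z.max())

    residues: list[Residue] = []
    z_cursor = 0.0
    parts = [par, hp, anti]
    placed = []
    for i, part in enumerate(parts):
        lo, hi = _zspan(part)
        p = part.transform(rotation=_rotz(45.0 * i),
                           translation=np.array([0.0, 0.0, z_cursor - lo]))
        placed.append(p)
        z_cursor += (hi - lo) + gap
    for i, p in enumerate(placed):
        residues.extend(p.residues)
        if i < 2 and connector_nt:
            a0 = p.coords()[p.coords()[:, 2].argmax()]
            a0 = a0 + 4.0 * _radial(a0) if np.linalg.norm(a0[:2]) > 1 else \
                a0 + np.array([4.0, 0, 0])
            nxt = placed[i + 1]
            a1 = nxt.coords()[nxt.coords()[:, 2].argmin()]
            a1 = a1 + 4.0 * _radial(a1) if np.linalg.norm(a1[:2]) > 1 else \
                a1 + np.array([4.0, 0, 0])
            residues.extend(_arc_residues("T" * connector_nt, a0, a1,
                                          "linker", bulge=4.0,
                                          orient_offset=17 * i))
    if flank_nt:
        lo_atom = residues[0].coords[0]
        a0 = lo_atom + 3.0 * _radial(lo_atom)
        a1 = a0 + np.array([4.0, 2.0, -5.0 - 4.5 * flank_nt])
        residues = _arc_residues("T" * flank_nt, a1, a0, "flank",
                                 bulge=2.0) + residues
    out = StructureModel(residues, provenance={
        "builder": "duplex_quadruplex_hybrid",
        "quartets_per_unit": quartets_per_unit, "hairpin_bp": hairpin_bp,
        "topology": "duplex-quadruplex-hybrid",
    })
    out = _resolve_ball_clashes(out)
    if validate:
        out.validate()
    return out


def _flank_arcs(model: StructureModel, n5: int, n3: int) -> StructureModel:
    """Add 5'/3' flanking dressed residues below/above the assembly."""
    out = model.copy()
    xyz = out.coords()
    if n5:
        first = out.residues[0].coords.mean(axis=0)
        a0 = first + 3.0 * _radial(first) + np.array([0, 0, -3.0])
        a1 = a0 + np.array([5.0, 3.0, -4.0 - 3.5 * n5])
        out.residues = _arc_residues("T" * n5, a1, a0, "flank", bulge=2.0,
                                     orient_offset=23) + out.residues
    if n3:
        last = out.residues[-1].coords.mean(axis=0)
        a0 = last + 3.0 * _radial(last) + np.array([0, 0, 3.0])
        a1 = a0 + np.array([5.0, -3.0, 4.0 + 3.5 * n3])
        out.residues = out.residues + _arc_residues("T" * n3, a0, a1, "flank",
                                                    bulge=2.0,
                                                    orient_offset=29)
    out.provenance = dict(model.provenance, flank_5p=n5, flank_3p=n3)
    return out


def build_htert_model(kind: str = "stacked",
                      validate: bool = True) -> StructureModel:
    """The three candidate folds of the 68-nt hTERT core promoter strand.

    All three carry the full 68-residue complement (36 tetrad guanines in
    three 3-quartet units for the quadruplex-only models, the rest as
    loops, linkers and flanks), so they differ in shape, not in material:

    * ``"stacked"``  — three parallel units coaxially stacked (3.4 A
      interfaces, 3-nt outside linkers, 2-nt/3-nt flanks);
    * ``"beads"``    — the same three units with extended 3-nt linkers and
      no inter-quadruplex stacking;
    * ``"hybrid"``   — parallel unit + 8-bp hairpin + antiparallel unit.
    """
    loops = (2, 3, 2)
    if kind == "stacked":
        units = [build_parallel_unit(3, loops, unit_index=i, validate=False)
                 for i in range(3)]
        model = stack_units(units, linker_seqs=["TCG", "ACG"],
                            validate=False)
        model = _flank_arcs(model, 2, 3)
    elif kind == "beads":
        units = [build_parallel_unit(3, loops, unit_index=i, validate=False)
                 for i in range(3)]
        model = build_beads_on_string(units, linker_nt=3, validate=False)
        model = _flank_arcs(model, 2, 3)
    elif kind == "hybrid":
        model = build_duplex_quadruplex_hybrid(validate=False)
    else:
        raise ValueError("kind must be 'stacked', 'beads' or 'hybrid'")
    model = _resolve_ball_clashes(model)
    from .oligo_props import HTERT_SEQ, molecular_weight

    model.provenance["model"] = kind
    model.provenance["sequence_nt"] = len(model.residues)
    model.provenance["mass_da"] = molecular_weight(HTERT_SEQ)
    if validate:
        model.validate()
    return model


# ---------------------------------------------------------------------------
# PDB I/O

def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write standard ATOM records (single chain, sequential residues)."""
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("g4")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    serial = 1
    for i, res in enumerate(model.residues, start=1):
        sb.init_residue(res.name.rjust(3), " ", i, " ")
        for name, el, xyz in zip(res.atom_names, res.elements, res.coords):
            sb.init_atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                         name.ljust(4), serial, element=el)
            serial += 1
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def read_pdb(path: str | Path) -> StructureModel:
    """Read ATOM records back into a :class:`StructureModel` (roles are not
    stored in PDB; all residues come back with role 'unknown')."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("g4", str(path))
    residues = []
    for res in structure.get_residues():
        names = [a.get_name() for a in res]
        coords = np.array([a.get_coord() for a in res], dtype=float)
        residues.append(Residue(res.get_resname().strip(), "unknown",
                                names, coords))
    return StructureModel(residues, provenance={"source": str(path)})
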