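"""Rigid-body assembly of domain models under cross-link distance restraints.

Each domain model is placed by a rigid transform (rotation + translation)
chosen to minimize a loss combining squared restraint excesses, max(0, d −
d_max)², with a steric-clash penalty.  Distance-only restraints determine a
placement only up to reflection, so the optimizer can also search the
mirror-image branch; improper (chirality-inverting) solutions are returned
flagged, never applied silently.  Lipoprotein-particle geometry (sphere or
rounded discoid) is available for shell-containment checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import Structure, merge

#: default inter-body Cα–Cα clash cutoff, Å
CLASH_CUTOFF = 4.0
#: default loss penalty per clash, Å²
CLASH_WEIGHT = 100.0
#: default d_max slack for links with an endpoint in a flexible coil, Å
COIL_SLACK = 10.0


@dataclass(frozen=True)
class Pose:
    """A rigid (or reflecting) transform x' = Rx + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length-3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def improper(self) -> bool:
        """True iff the transform inverts chirality (det R = −1)."""
        return bool(np.linalg.det(self.rotation) < 0)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply ``other`` first."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Pose":
        Rinv = self.rotation.T
        return Pose(Rinv, -Rinv @ self.translation)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))


def transform(structure: Structure, pose: Pose) -> Structure:
    """Apply a pose to all atoms of a structure."""
    return structure.with_coords(pose.apply(structure.coords))


def mirror_pose(plane_point: np.ndarray, plane_normal: np.ndarray) -> Pose:
    """The reflection through the plane given by a point and a normal."""
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("plane normal must be non-zero")
    n = n / norm
    p = np.asarray(plane_point, dtype=float)
    R = np.eye(3) - 2.0 * np.outer(n, n)
    t = 2.0 * np.dot(p, n) * n
    return Pose(R, t)


def mirror(structure: Structure, plane_point, plane_normal) -> Structure:
    """Reflect a structure through a plane. The result is the mirror image:
    distances are preserved but chirality (e.g. helix handedness) inverts."""
    return transform(structure, mirror_pose(plane_point, plane_normal))


def ca_pseudo_dihedrals(structure: Structure) -> np.ndarray:
    """Cα(i)..Cα(i+3) pseudo-dihedral angles in radians, a chirality probe:
    reflection flips the sign of every torsion."""
    res = structure.residues()
    coords = np.array([structure.coord(r) for r in res])
    if len(coords) < 4:
        return np.empty(0)
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # sign such that an ideal right-handed helix has positive torsions
    return -np.arctan2(y, x)


def clash_count(
    structure_a: Structure | np.ndarray,
    structure_b: Structure | np.ndarray,
    cutoff: float = CLASH_CUTOFF,
) -> int:
    """Number of inter-body atom pairs strictly closer than ``cutoff``.

    Uses a KD-tree; identical to the brute-force all-pairs count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xa = structure_a.coords if isinstance(structure_a, Structure) else np.asarray(structure_a)
    xb = structure_b.coords if isinstance(structure_b, Structure) else np.asarray(structure_b)
    if len(xa) == 0 or len(xb) == 0:
        return 0
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    sdm = tree_a.sparse_distance_matrix(tree_b, max_distance=cutoff,
                                        output_type="coo_matrix")
    return int(np.count_nonzero(sdm.data < cutoff))


# ---------------------------------------------------------------------------
# restraint loss

Restraint = tuple[int, int, float]  # (res_a, res_b, d_max)


def restraint_loss(
    assembly: "AssemblyState | Structure",
    restraints: Sequence[Restraint],
    *,
    clash_weight: float = CLASH_WEIGHT,
    clash_cutoff: float = CLASH_CUTOFF,
) -> tuple[float, int, float]:
    """(sum of squared restraint excesses, clash count, combined loss).

    Restraints whose endpoints cannot both be located are excluded (and do
    not contribute).  The clash count for an :class:`AssemblyState` is summed
    over all placed-body pairs; a bare structure contributes no clash term.
    """
    if isinstance(assembly, AssemblyState):
        structure = assembly.merged()
        bodies = list(assembly.placed.values())
    else:
        structure = assembly
        bodies = []
    excess_sq = 0.0
    for res_a, res_b, d_max in restraints:
        pa = structure.coord(res_a)
        pb = structure.coord(res_b)
        if pa is None or pb is None:
            continue
        d = float(np.linalg.norm(pa - pb))
        excess_sq += max(0.0, d - d_max) ** 2
    clashes = 0
    for i in range(len(bodies)):
        for j in range(i + 1, len(bodies)):
            clashes += clash_count(bodies[i], bodies[j], clash_cutoff)
    return excess_sq, clashes, excess_sq + clash_weight * clashes


# ---------------------------------------------------------------------------
# pose fitting

@dataclass
class FitResult:
    pose: Pose
    loss: float
    restraint_excess: float
    clashes: int
    improper: bool
    diagnostics: dict = field(default_factory=dict)


def _axis_rotation(axis: int, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    R = np.eye(3)
    i, j = (axis + 1) % 3, (axis + 2) % 3
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation superposing P onto Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def _project_refine(A, B, d_max, R, t, iters=150):
    """Iterative projection: pull each violated anchor onto its restraint
    sphere and re-superpose.  Rapidly drives the restraint excess toward
    zero; the clash term is handled by the subsequent coordinate descent."""
    for _ in range(iters):
        X = A @ R.T + t
        d = np.linalg.norm(X - B, axis=1)
        u = (X - B) / np.where(d == 0.0, 1.0, d)[:, None]
        targets = np.where((d > d_max)[:, None], B + u * d_max[:, None], X)
        R, t = _kabsch(A, targets)
    return R, t


def _refine(R, t, loss_fn, max_iter, tol):
    """Coordinate descent over 6 pose parameters with step halving.

    Rotations are applied about the current centroid of the transformed
    restraint anchors so rotation and translation moves stay decoupled.
    """
    best = loss_fn(R, t)
    step_rot, step_trans = 0.3, 4.0
    n_iter = 0
    history = [best]
    while n_iter < max_iter and (step_rot > 1e-6 or step_trans > 1e-5):
        n_iter += 1
        improved = False
        c = loss_fn.anchor_centroid(R, t)
        for axis in range(3):
            for sign in (1.0, -1.0):
                dR = _axis_rotation(axis, sign * step_rot)
                cand_R = dR @ R
                cand_t = dR @ (t - c) + c
                val = loss_fn(cand_R, cand_t)
                if val < best - 1e-15:
                    best, R, t, improved = val, cand_R, cand_t, True
        for axis in range(3):
            for sign in (1.0, -1.0):
                dt = np.zeros(3)
                dt[axis] = sign * step_trans
                val = loss_fn(R, t + dt)
                if val < best - 1e-15:
                    best, t, improved = val, t + dt, True
        history.append(best)
        if best < 1e-14:
            break
        if not improved:
            step_rot *= 0.5
            step_trans *= 0.5
        elif len(history) > 2 and history[-2] - best < tol and step_rot < 1e-3:
            break
    return R, t, best, n_iter, history


class _PoseLoss:
    """Loss of a candidate pose: restraint excesses + clash penalty."""

    def __init__(self, mobile_anchors, fixed_anchors, d_max, mobile_coords,
                 fixed_tree, clash_cutoff, clash_weight):
        self.A = mobile_anchors
        self.B = fixed_anchors
        self.d_max = d_max
        self.X = mobile_coords
        self.tree = fixed_tree
        self.cutoff = clash_cutoff
        self.weight = clash_weight

    def restraint_part(self, R, t):
        placed = self.A @ R.T + t
        d = np.linalg.norm(placed - self.B, axis=1)
        excess = np.clip(d - self.d_max, 0.0, None)
        return float(np.dot(excess, excess))

    def clash_part(self, R, t):
        """Smooth soft-core overlap penalty: Σ (1 − d/cutoff)² over pairs
        closer than the cutoff.  Differentiable in the pose (unlike the raw
        clash count), equals zero exactly when the count does."""
        if self.tree is None or self.weight == 0.0:
            return 0.0
        placed = self.X @ R.T + t
        hits = self.tree.query_ball_point(placed, self.cutoff)
        total = 0.0
        fixed_pts = self.tree.data
        for i, h in enumerate(hits):
            if h:
                d = np.linalg.norm(fixed_pts[h] - placed[i], axis=1)
                total += float(((1.0 - d / self.cutoff) ** 2).sum())
        return total

    def __call__(self, R, t):
        return self.restraint_part(R, t) + self.weight * self.clash_part(R, t)

    def anchor_centroid(self, R, t):
        return (self.A @ R.T + t).mean(axis=0)


def fit_pose(
    mobile: Structure,
    fixed: Structure | Sequence[Structure],
    restraints: Sequence[Restraint],
    *,
    allow_mirror: bool = False,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    clash_cutoff: float = CLASH_CUTOFF,
    clash_weight: float = CLASH_WEIGHT,
) -> FitResult:
    """Fit a rigid pose placing ``mobile`` against an anchored assembly.

    Multi-start search: uniform random rotations, translation initialized so
    the restraint-anchor centroids coincide, followed by coordinate-descent
    refinement of the 6 pose parameters.  With ``allow_mirror`` the reflected
    mobile copy is optimized too and the improper solution is returned (and
    flagged) only when its combined loss is strictly lower.

    ``restraints`` are (mobile_residue, fixed_residue, d_max) triples, in
    either order — endpoints are matched to whichever body contains them.
    """
    fixed_structure = fixed if isinstance(fixed, Structure) else merge(fixed)
    mob_res = set(mobile.residues())
    fix_res = set(fixed_structure.residues())

    A, B, dmax = [], [], []
    for res_a, res_b, d in restraints:
        if res_a in mob_res and res_b in fix_res:
            m, f = res_a, res_b
        elif res_b in mob_res and res_a in fix_res:
            m, f = res_b, res_a
        else:
            continue
        pm, pf = mobile.coord(m), fixed_structure.coord(f)
        if pm is None or pf is None:
            continue
        A.append(pm)
        B.append(pf)
        dmax.append(d)
    if not A:
        raise ValueError("no restraints bridge the mobile and fixed bodies")
    A = np.array(A)
    B = np.array(B)
    dmax = np.array(dmax)

    diagnostics: dict = {"n_bridging": len(A)}
    centered = A - A.mean(axis=0)
    if len(A) >= 2:
        svals = np.linalg.svd(centered, compute_uv=False)
        if np.sum(svals > 1e-6) < 2:
            diagnostics["degenerate"] = (
                "restraint anchors are (near-)collinear; the optimal pose "
                "family is not unique"
            )

    rng = np.random.default_rng(seed)
    fixed_tree = cKDTree(fixed_structure.coords) if clash_weight else None

    def search(mobile_coords, anchors):
        loss_fn = _PoseLoss(anchors, B, dmax, mobile_coords, fixed_tree,
                            clash_cutoff, clash_weight)
        best = None
        rotations = Rotation.random(n_starts, rng=rng)
        for k in range(n_starts):
            R0 = rotations[k].as_matrix()
            t0 = B.mean(axis=0) - R0 @ anchors.mean(axis=0)
            R1, t1 = _project_refine(anchors, B, dmax, R0, t0)
            R, t, val, n_iter, history = _refine(R1, t1, loss_fn, max_iter, tol)
            if best is None or val < best[2]:
                best = (R, t, val, n_iter, history)
            if val < 1e-10:
                break
        return best

    best_proper = search(mobile.coords, A)
    diagnostics["proper_loss"] = best_proper[2]
    diagnostics["loss_history_nonincreasing"] = bool(
        all(b <= a + 1e-12 for a, b in zip(best_proper[4], best_proper[4][1:]))
    )

    result_R, result_t, result_loss = best_proper[:3]
    improper = False
    if allow_mirror:
        c = mobile.coords.mean(axis=0)
        M = mirror_pose(c, np.array([0.0, 0.0, 1.0]))
        mirrored_coords = M.apply(mobile.coords)
        mirrored_anchors = M.apply(A)
        best_mirror = search(mirrored_coords, mirrored_anchors)
        diagnostics["mirror_loss"] = best_mirror[2]
        if best_mirror[2] < best_proper[2] - 1e-9:
            R_m, t_m = best_mirror[:2]
            # overall transform of the *original* mobile: x -> R_m(Mx) + t_m
            combined = Pose(R_m, t_m).compose(M)
            result_R, result_t = combined.rotation, combined.translation
            result_loss = best_mirror[2]
            improper = True

    pose = Pose(result_R, result_t)
    placed_anchors = pose.apply(A)
    d = np.linalg.norm(placed_anchors - B, axis=1)
    excess = np.clip(d - dmax, 0.0, None)
    restraint_excess = float(np.dot(excess, excess))
    clashes = 0
    if fixed_tree is not None:
        placed = pose.apply(mobile.coords)
        hits = fixed_tree.query_ball_point(placed, clash_cutoff)
        clashes = sum(len(h) for h in hits)
    return FitResult(
        pose=pose,
        loss=result_loss,
        restraint_excess=restraint_excess,
        clashes=clashes,
        improper=improper,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# sequential assembly

@dataclass
class AssemblyState:
    """Placed segment models with their poses and loss components."""

    placed: dict[str, Structure] = field(default_factory=dict)
    poses: dict[str, Pose] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    restraint_excess: float = 0.0
    clashes: int = 0

    def merged(self) -> Structure:
        return merge(self.placed.values(), name="assembly")


def apply_coil_slack(
    restraints: Sequence[Restraint], scheme, slack: float = COIL_SLACK
) -> list[Restraint]:
    """Widen d_max for restraints with ≥1 endpoint in a coil-level segment.

    Coils are flexible; a rigid-body placement cannot reproduce their local
    torsion adjustments, so their restraints get extra slack.
    """
    out = []
    for res_a, res_b, d_max in restraints:
        in_coil = any(
            "coil" in scheme.locate(r) for r in (res_a, res_b)
            if "outside" not in scheme.locate(r)
        )
        out.append((res_a, res_b, d_max + slack if in_coil else d_max))
    return out


def sequential_assemble(
    segments: Mapping[str, Structure],
    restraints: Sequence[Restraint],
    order: Sequence[str],
    *,
    scheme=None,
    coil_slack: float = COIL_SLACK,
    allow_mirror: bool = False,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    clash_cutoff: float = CLASH_CUTOFF,
    clash_weight: float = CLASH_WEIGHT,
) -> AssemblyState:
    """Greedy sequential placement: the first segment in ``order`` anchors the
    assembly; each following segment is fitted against the union of already
    placed ones using all restraints bridging to them.  Segments with no
    bridging restraints are skipped with a warning."""
    if scheme is not None and coil_slack:
        restraints = apply_coil_slack(restraints, scheme, coil_slack)
    state = AssemblyState()
    anchor = order[0]
    state.placed[anchor] = segments[anchor]
    state.poses[anchor] = Pose.identity()
    for i, name in enumerate(order[1:], start=1):
        mobile = segments[name]
        fixed = state.merged()
        mob_res = set(mobile.residues())
        fix_res = set(fixed.residues())
        bridging = [
            r for r in restraints
            if (r[0] in mob_res and r[1] in fix_res)
            or (r[1] in mob_res and r[0] in fix_res)
        ]
        if not bridging:
            msg = f"segment {name!r} has no restraints bridging to the placed set; skipped"
            warnings.warn(msg, stacklevel=2)
            state.warnings.append(msg)
            state.skipped.append(name)
            continue
        fit = fit_pose(
            mobile, fixed, bridging,
            allow_mirror=allow_mirror, n_starts=n_starts,
            seed=seed + i, max_iter=max_iter,
            clash_cutoff=clash_cutoff, clash_weight=clash_weight,
        )
        state.placed[name] = transform(mobile, fit.pose)
        state.poses[name] = fit.pose
        if fit.improper:
            state.warnings.append(
                f"segment {name!r} placed with an improper (mirror) transform"
            )
    excess, clashes, _ = restraint_loss(
        state, restraints, clash_weight=clash_weight, clash_cutoff=clash_cutoff
    )
    state.restraint_excess = excess
    state.clashes = clashes
    return state


# ---------------------------------------------------------------------------
# lipoprotein particle geometry

@dataclass(frozen=True)
class ParticleModel:
    """Idealized lipoprotein particle: a sphere (diameter) or a discoid
    (bounding dx × dy × dz, modeled as an elliptical slab with a rounded rim
    of radius dz/2).  ``shell`` = (inner, outer) tolerances in Å around the
    surface."""

    kind: str
    dimensions: float | tuple[float, float, float]
    shell: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self):
        if self.kind == "sphere":
            if not isinstance(self.dimensions, (int, float)) or self.dimensions <= 0:
                raise ValueError("sphere needs a positive diameter")
        elif self.kind == "discoid":
            dims = tuple(self.dimensions)
            if len(dims) != 3 or any(d <= 0 for d in dims):
                raise ValueError("discoid needs positive (dx, dy, dz)")
            dx, dy, dz = dims
            if dz / 2 > min(dx, dy) / 2:
                raise ValueError("discoid rim radius dz/2 exceeds the footprint semi-axes")
            object.__setattr__(self, "dimensions", dims)
        else:
            raise ValueError(f"unknown particle kind {self.kind!r}")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the particle surface (negative inside)."""
        x = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "sphere":
            r = self.dimensions / 2.0
            return np.linalg.norm(x, axis=1) - r
        dx, dy, dz = self.dimensions
        h = dz / 2.0  # rim radius; the solid is (inner ellipse disk) ⊕ ball(h)
        a, b = dx / 2.0 - h, dy / 2.0 - h
        theta = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)
        ex, ey = a * np.cos(theta), b * np.sin(theta)
        out = np.empty(len(x))
        for i, p in enumerate(x):
            px, py, pz = p
            # inside the inner ellipse footprint: nearest disk point is (px,py,0)
            if a > 0 and b > 0 and (px / a) ** 2 + (py / b) ** 2 <= 1.0:
                dist = abs(pz)
            else:
                d2 = (px - ex) ** 2 + (py - ey) ** 2
                dist = math.sqrt(float(d2.min()) + pz * pz)
            out[i] = dist - h
        return out


#: LDL modeled as a 20 nm × 20 nm × 11 nm discoid
LDL_DISCOID = ParticleModel("discoid", (200.0, 200.0, 110.0))
#: VLDL modeled as a 30 nm diameter sphere
VLDL_SPHERE = ParticleModel("sphere", 300.0)


def shell_containment(
    assembly: AssemblyState | Structure, particle: ParticleModel
) -> float:
    """Fraction of Cα atoms within the particle's surface shell."""
    structure = assembly.merged() if isinstance(assembly, AssemblyState) else assembly
    ca = np.array([a.xyz for a in structure.atoms if a.atom_name == "CA"])
    if len(ca) == 0:
        return 0.0
    sd = particle.signed_distance(ca)
    inner, outer = particle.shell
    return float(np.mean((sd >= -inner) & (sd <= outer)))
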