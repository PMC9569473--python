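"""Solvent accessibility and protein-painting surface-exposure logic.

Two independent routes to surface exposure are implemented: a geometric one
(Shrake–Rupley sphere-point solvent-accessible surface area) and an
experimental one (protein painting: a covalent dye blocks trypsin access to
exposed regions, so peptides detected in every untreated replicate but in no
painted replicate mark exposed surface).  Hydrolyzed mono-link sites provide
a third, orthogonal marker whose concordance with painted regions can be
quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

#: van der Waals radii by element, Å
ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
#: enlarged pseudo-atom radius for Cα-only models, Å
PSEUDO_CA_RADIUS = 3.0
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: theoretical per-residue maximum accessible areas (Å², tripeptide standard,
#: Tien et al. 2013), used as the relative-accessibility reference; swappable.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class AccessibilityProfile:
    """Per-residue absolute accessible area (Å²) and relative accessibility."""

    area: dict[int, float]
    relative: dict[int, float] = field(default_factory=dict)
    over_reference: list[int] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return sum(self.area.values())


def sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    *,
    radii: dict[str, float] | None = None,
) -> AccessibilityProfile:
    """Shrake–Rupley accessible surface area, summed per residue.

    Atom radii come from an element table; atoms without an element (Cα-only
    trace models) use the enlarged pseudo-atom radius.  Deterministic for a
    given ``n_points`` (sphere points come from a fixed golden-spiral
    lattice).  Relative accessibilities divide by the tripeptide reference
    maxima and are clipped to [0, 1.2]; residues exceeding the reference are
    flagged in ``over_reference``.
    """
    table = dict(ATOM_RADII)
    if radii:
        table.update(radii)
    coords = structure.coords
    n = len(coords)
    if n == 0:
        return AccessibilityProfile(area={})
    r_atom = np.array([
        table.get((a.element or "").upper(), PSEUDO_CA_RADIUS)
        for a in structure.atoms
    ])
    r_ext = r_atom + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(n)
    for i in range(n):
        neighbors = [
            j for j in tree.query_ball_point(coords[i], r_ext[i] + r_ext.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < r_ext[i] + r_ext[j]
        ]
        pts = coords[i] + r_ext[i] * unit
        if neighbors:
            nb = coords[neighbors]
            nr = r_ext[np.array(neighbors)]
            d2 = ((pts[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * math.pi * r_ext[i] ** 2 * frac
    area: dict[int, float] = {}
    for a, v in zip(structure.atoms, per_atom):
        area[a.res_num] = area.get(a.res_num, 0.0) + float(v)
    relative: dict[int, float] = {}
    over: list[int] = []
    for res, v in area.items():
        name = structure.residue_name(res)
        ref = MAX_ASA.get((name or "").upper())
        if ref:
            rel = v / ref
            if rel > 1.0:
                over.append(res)
            relative[res] = min(rel, 1.2)
    return AccessibilityProfile(area=area, relative=relative,
                                over_reference=sorted(over))


# ---------------------------------------------------------------------------
# protein painting

@dataclass(frozen=True)
class PeptideObservation:
    """One peptide detected in one replicate of one condition."""

    peptide: str
    start: int  # 1-based inclusive
    end: int
    replicate: str
    condition: str  # "painted" | "unpainted"

    def __post_init__(self):
        if self.condition not in ("painted", "unpainted"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"peptide {self.peptide!r} length inconsistent with "
                f"[{self.start},{self.end}]"
            )


def merge_ranges(ranges: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of inclusive integer ranges (overlapping or adjacent merge)."""
    out: list[list[int]] = []
    for start, end in sorted(ranges):
        if out and start <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return [tuple(r) for r in out]


def paint_regions(
    observations: Sequence[PeptideObservation],
    sequence: str,
    n_replicates: int = 3,
) -> list[tuple[int, int]]:
    """Exposed (paint-positive) residue ranges from a painting experiment.

    A peptide is paint-positive iff it is present in ALL unpainted replicates
    and ABSENT from all painted replicates; the output is the merged residue
    ranges of paint-positive peptides.  Peptides must match the protein
    sequence at their coordinates, and each condition must contain exactly
    ``n_replicates`` distinct replicate ids.
    """
    reps: dict[str, set[str]] = {"painted": set(), "unpainted": set()}
    seen: dict[tuple[str, int, int], dict[str, set[str]]] = {}
    for obs in observations:
        if sequence[obs.start - 1: obs.end].upper() != obs.peptide.upper():
            raise ValueError(
                f"peptide {obs.peptide!r} does not match the sequence at "
                f"[{obs.start},{obs.end}]"
            )
        reps[obs.condition].add(obs.replicate)
        entry = seen.setdefault(
            (obs.peptide.upper(), obs.start, obs.end),
            {"painted": set(), "unpainted": set()},
        )
        entry[obs.condition].add(obs.replicate)
    for cond, ids in reps.items():
        if ids and len(ids) != n_replicates:
            raise ValueError(
                f"{cond} condition has {len(ids)} replicate ids "
                f"({sorted(ids)}), expected {n_replicates}"
            )
    positive = [
        (start, end)
        for (pep, start, end), entry in seen.items()
        if len(entry["unpainted"]) == n_replicates and not entry["painted"]
    ]
    return merge_ranges(positive)


def monolink_concordance(
    monolink_residues: Iterable[int],
    painted_ranges: Sequence[tuple[int, int]],
) -> float | None:
    """Fraction of hydrolyzed mono-link sites lying inside painted ranges.

    Returns None (undefined) when there are no sites.
    """
    sites = sorted(set(monolink_residues))
    if not sites:
        return None
    inside = sum(
        1 for s in sites if any(start <= s <= end for start, end in painted_ranges)
    )
    return inside / len(sites)
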