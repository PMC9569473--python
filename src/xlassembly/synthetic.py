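"""Synthetic fixture generator: idealized Cα traces, planted restraints,
scrambled poses and painting datasets.

Everything is reproducible: the same parameters and seed give the same
output.  Geometry uses standard idealizations so closed-form oracles exist:
helices with 2.3 Å radius, 1.5 Å rise and 100°/residue twist; strands as
3.8 Å steps with an alternating ±5° zigzag; coils as self-avoiding random
walks with 3.8 Å steps and 3.5 Å minimum separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .accessibility import PeptideObservation
from .assembly import Pose, mirror_pose, transform
from .restraints import (
    DSSO, CrossLink, LinkerChemistry, DEFAULT_GRACE,
)
from .segmentation import Segment, SegmentationScheme, digest
from .structure import AtomRecord, Structure, merge

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
STRAND_STEP = 3.8
STRAND_ZIGZAG_DEG = 10.0
COIL_STEP = 3.8
COIL_MIN_SEPARATION = 3.5


def helix_coord(i: int, radius=HELIX_RADIUS, rise=HELIX_RISE,
                twist_deg=HELIX_TWIST_DEG) -> np.ndarray:
    """Closed-form Cα position of residue ``i`` on the ideal helix."""
    theta = math.radians(twist_deg) * i
    return np.array([radius * math.cos(theta), radius * math.sin(theta),
                     rise * i])


def make_segment(
    kind: str,
    length: int,
    seed: int = 0,
    *,
    start_res: int = 1,
    chain: str = "A",
    res_name: str = "ALA",
) -> Structure:
    """Generate an idealized Cα-trace segment (helix, strand or coil)."""
    if length < 2:
        raise ValueError("segment length must be at least 2")
    if kind == "helix":
        coords = np.array([helix_coord(i) for i in range(length)])
    elif kind == "strand":
        half = math.radians(STRAND_ZIGZAG_DEG / 2.0)
        coords = [np.zeros(3)]
        for i in range(1, length):
            sign = 1.0 if i % 2 else -1.0
            step = STRAND_STEP * np.array(
                [math.cos(half), sign * math.sin(half), 0.0]
            )
            coords.append(coords[-1] + step)
        coords = np.array(coords)
    elif kind == "coil":
        coords = _self_avoiding_walk(length, seed)
    else:
        raise ValueError(f"unknown segment kind {kind!r}")
    atoms = [
        AtomRecord(chain=chain, res_num=start_res + i, res_name=res_name,
                   atom_name="CA", x=float(p[0]), y=float(p[1]), z=float(p[2]))
        for i, p in enumerate(coords)
    ]
    return Structure(atoms, name=f"{kind}-{length}")


def _self_avoiding_walk(length: int, seed: int, max_attempts: int = 2000
                        ) -> np.ndarray:
    rng = np.random.default_rng(seed)
    for _ in range(20):  # whole-chain restarts
        coords = [np.zeros(3)]
        failed = False
        for _ in range(length - 1):
            for attempt in range(max_attempts):
                v = rng.normal(size=3)
                v *= COIL_STEP / np.linalg.norm(v)
                cand = coords[-1] + v
                if len(coords) < 2:
                    break
                d = np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)
                if d.min() >= COIL_MIN_SEPARATION:
                    break
            else:
                failed = True
                break
            coords.append(cand)
        if not failed:
            return np.array(coords)
    raise RuntimeError(
        "coil generation failed after maximum attempts; "
        "try a different seed or a larger box"
    )


# ---------------------------------------------------------------------------
# planting restraints

def plant_crosslinks(
    assembly_truth: Structure | Sequence[Structure],
    linker: LinkerChemistry = DSSO,
    mix: Mapping[str, int] | None = None,
    seed: int = 0,
    *,
    grace: float = DEFAULT_GRACE,
    between: tuple[set[int], set[int]] | None = None,
    max_distance: float | None = None,
) -> tuple[list[CrossLink], dict[tuple[int, int], float]]:
    """Sample residue pairs whose true distances fall in requested bands.

    ``mix`` gives counts per category, e.g. ``{"satisfied": 56, "marginal":
    3, "violated": 5}`` (bands: ≤ threshold, (threshold, grace], > grace).
    ``between`` restricts sampling to pairs with one endpoint in each residue
    set (for inter-segment links); ``max_distance`` additionally caps the
    satisfied band (useful for planting safely-satisfiable links).  Returns
    the links plus ground-truth distances.  Raises when a band cannot supply
    the requested count.
    """
    structure = (assembly_truth if isinstance(assembly_truth, Structure)
                 else merge(assembly_truth))
    mix = dict(mix or {"satisfied": 10})
    threshold = linker.reported_threshold()
    res = structure.residues()
    coords = np.array([structure.coord(r) for r in res])
    rng = np.random.default_rng(seed)

    idx_a = np.arange(len(res))
    pairs = []
    for i in idx_a:
        for j in range(i + 1, len(res)):
            if between is not None:
                ra, rb = res[i], res[j]
                ok = (ra in between[0] and rb in between[1]) or (
                    ra in between[1] and rb in between[0])
                if not ok:
                    continue
            pairs.append((i, j))
    pairs = np.array(pairs)
    if len(pairs) == 0:
        raise ValueError("no candidate residue pairs available")
    dists = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)

    bands = {
        "satisfied": (0.0, threshold if max_distance is None
                      else min(threshold, max_distance)),
        "marginal": (threshold, grace),
        "violated": (grace, np.inf),
    }
    links: list[CrossLink] = []
    truth: dict[tuple[int, int], float] = {}
    counter = 1
    for category, count in mix.items():
        lo, hi = bands[category]
        eligible = np.flatnonzero((dists > lo) & (dists <= hi))
        if len(eligible) < count:
            raise ValueError(
                f"band {category!r} ({lo:.1f}, {hi:.1f}] Å has only "
                f"{len(eligible)} candidate pairs; {count} requested"
            )
        chosen = rng.choice(eligible, size=count, replace=False)
        for k in chosen:
            i, j = pairs[k]
            ra, rb = res[i], res[j]
            link = CrossLink(id=f"XL{counter:03d}", res_a=ra, res_b=rb,
                             linker=linker.name)
            links.append(link)
            truth[link.pair] = float(dists[k])
            counter += 1
    return links, truth


def scramble(
    segment: Structure,
    seed: int = 0,
    *,
    mirror: bool = False,
    max_translation: float = 60.0,
) -> tuple[Structure, Pose]:
    """Displace a segment by a random rigid transform (optionally reflected).

    Returns the displaced copy and the truth pose that restores the original
    placement (i.e. ``transform(displaced, truth_pose)`` reproduces the
    input).
    """
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    scramble_pose = Pose(R, t)
    if mirror:
        c = segment.coords.mean(axis=0)
        scramble_pose = scramble_pose.compose(
            mirror_pose(c, np.array([0.0, 0.0, 1.0]))
        )
    displaced = transform(segment, scramble_pose)
    return displaced, scramble_pose.inverse()


# ---------------------------------------------------------------------------
# toy five-subunit fixture

@dataclass
class ToyAssembly:
    """A miniature five-segment architecture with planted restraints."""

    segments: dict[str, Structure]
    truth: dict[str, Structure]
    scheme: SegmentationScheme
    links: list[CrossLink] = field(default_factory=list)
    truth_distances: dict[tuple[int, int], float] = field(default_factory=dict)


#: segment lengths ≈ 1/10 of the apoB-100 subunit sizes; compact coil blobs
#: keep the toy architecture globular so ring neighbours stay in link range
TOY_LENGTHS = {"I": 99, "II": 106, "III": 48, "IV": 151, "V": 51}
TOY_KINDS = {"I": "coil", "II": "coil", "III": "coil",
             "IV": "coil", "V": "coil"}


def toy_apob_fixture(
    seed: int = 0,
    *,
    n_inter_links: int = 13,
    n_intra_links: int = 8,
    linker: LinkerChemistry = DSSO,
) -> ToyAssembly:
    """Build the packaged toy apoB-like fixture.

    Five idealized segments (lengths one tenth of the real subunits, residue
    numbering contiguous) are arranged clash-free in an architecture echoing
    the real one; cross-links are planted between neighbouring segments at
    comfortably satisfiable distances, echoing the thirteen inter-subunit
    links of the full protein, plus a few intra-segment links.  Occasional
    seeds give geometrically infeasible layouts; those retry deterministically
    with an offset sub-seed, so every seed yields a fixture.
    """
    try:
        return _build_toy(seed, n_inter_links, n_intra_links, linker)
    except (RuntimeError, ValueError):
        for attempt in range(1, 6):
            try:
                return _build_toy(seed + 1009 * attempt, n_inter_links,
                                  n_intra_links, linker)
            except (RuntimeError, ValueError):
                continue
        raise


def _build_toy(
    seed: int,
    n_inter_links: int,
    n_intra_links: int,
    linker: LinkerChemistry,
) -> ToyAssembly:
    rng = np.random.default_rng(seed)
    names = list(TOY_LENGTHS)
    # contiguous numbering
    starts, pos = {}, 1
    for name in names:
        starts[name] = pos
        pos += TOY_LENGTHS[name]
    span = (1, pos - 1)

    segments: dict[str, Structure] = {}
    for k, name in enumerate(names):
        segments[name] = make_segment(
            TOY_KINDS[name], TOY_LENGTHS[name], seed=seed + k,
            start_res=starts[name], chain=chr(ord("A") + k), res_name="LYS",
        )

    # ground-truth arrangement mimicking the real architecture: II beside I,
    # III and V on either side of II, IV bridging III and V.  Each blob
    # slides along its direction until it just clears the placed union.
    truth: dict[str, Structure] = {}

    def place(name: str, anchor: np.ndarray, direction: np.ndarray,
              near: Sequence[str] = (), near_max: float = 16.0) -> None:
        """Slide a randomly oriented copy of the segment along ``direction``
        from ``anchor`` until it clears the placed union (min distance ≥ 6 Å)
        while staying within ``near_max`` of every segment named in ``near``;
        retries with fresh orientations when no radius satisfies both."""
        local = segments[name]
        placed = [s.coords for s in truth.values()]
        if not placed:
            R = Rotation.random(rng=rng).as_matrix()
            centered = local.coords @ R.T
            centered -= centered.mean(axis=0)
            truth[name] = local.with_coords(centered + anchor)
            return
        tree = cKDTree(np.vstack(placed))
        near_trees = {n: cKDTree(truth[n].coords) for n in near}
        for _ in range(40):
            R = Rotation.random(rng=rng).as_matrix()
            centered = local.coords @ R.T
            centered -= centered.mean(axis=0)
            for radius in np.arange(0.0, 300.0, 1.0):
                cand = centered + anchor + radius * direction
                if tree.query(cand)[0].min() < 6.0:
                    continue
                if all(t.query(cand)[0].min() <= near_max
                       for t in near_trees.values()):
                    truth[name] = local.with_coords(cand)
                    return
                break  # clear of the union but too far from a target; reorient
        raise RuntimeError(
            f"could not place toy segment {name!r} clash-free within link "
            "range of its neighbours"
        )

    ex, ey = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    place("I", np.zeros(3), ex)
    c_i = truth["I"].coords.mean(axis=0)
    place("II", c_i, ex, near=["I"])
    c_ii = truth["II"].coords.mean(axis=0)
    place("III", c_ii, ey, near=["II"])
    place("V", c_ii, -ey, near=["II"])
    c_iii = truth["III"].coords.mean(axis=0)
    c_v = truth["V"].coords.mean(axis=0)
    place("IV", 0.5 * (c_iii + c_v), ex, near=["III", "V"])

    seg_ranges = {
        name: (starts[name], starts[name] + TOY_LENGTHS[name] - 1)
        for name in names
    }
    scheme = SegmentationScheme(
        segments=tuple(
            Segment(name=f"Subunit {name}", level="subunit",
                    ranges=(seg_ranges[name],))
            for name in names
        ),
        sequence_span=span,
    )

    merged_truth = merge(truth.values())
    links: list[CrossLink] = []
    truth_d: dict[tuple[int, int], float] = {}
    residue_sets = {
        name: set(range(seg_ranges[name][0], seg_ranges[name][1] + 1))
        for name in names
    }
    # inter-segment links echoing the real topology: I–II, II–III, II–V,
    # III–IV, IV–V; split the requested count as evenly as possible
    neighbour_pairs = [("I", "II"), ("II", "III"), ("II", "V"),
                       ("III", "IV"), ("IV", "V")]
    per_pair = [n_inter_links // len(neighbour_pairs)] * len(neighbour_pairs)
    for i in range(n_inter_links % len(neighbour_pairs)):
        per_pair[i] += 1
    for pair_idx, ((na, nb), count) in enumerate(zip(neighbour_pairs, per_pair)):
        if count == 0:
            continue
        new_links, new_truth = plant_crosslinks(
            merged_truth, linker, {"satisfied": count},
            seed=seed + 100 + pair_idx,
            between=(residue_sets[na], residue_sets[nb]),
            max_distance=0.8 * linker.reported_threshold(),
        )
        links.extend(new_links)
        truth_d.update(new_truth)
    # intra-segment links
    for k, name in enumerate(names):
        if n_intra_links == 0:
            break
        count = max(1, n_intra_links // len(names))
        new_links, new_truth = plant_crosslinks(
            merged_truth, linker, {"satisfied": count}, seed=seed + 200 + k,
            between=(residue_sets[name], residue_sets[name]),
            max_distance=0.8 * linker.reported_threshold(),
        )
        links.extend(new_links)
        truth_d.update(new_truth)
    # re-id sequentially after planting
    links = [
        CrossLink(id=f"XL{i:03d}", res_a=l.res_a, res_b=l.res_b, linker=l.linker)
        for i, l in enumerate(links, start=1)
    ]
    return ToyAssembly(segments=segments, truth=truth, scheme=scheme,
                       links=links, truth_distances=truth_d)


# ---------------------------------------------------------------------------
# painting datasets

def make_painting_dataset(
    sequence: str,
    exposed_ranges: Sequence[tuple[int, int]],
    n_replicates: int = 3,
    dropout: float = 0.0,
    seed: int = 0,
    *,
    min_len: int = 5,
) -> list[PeptideObservation]:
    """Simulate a protein-painting experiment over a tryptic digest.

    Peptides overlapping an exposed range are absent from painted replicates
    (the dye blocks their detection) and present in unpainted ones; peptides
    elsewhere are present in both conditions.  ``dropout`` removes each
    present (peptide, replicate) observation independently with the given
    probability.
    """
    for start, end in exposed_ranges:
        if start < 1 or end > len(sequence) or end < start:
            raise ValueError(f"exposed range [{start},{end}] outside sequence")
    rng = np.random.default_rng(seed)
    peptides = digest(sequence, missed_cleavages=0, min_len=min_len)
    observations: list[PeptideObservation] = []
    for pep in peptides:
        exposed = any(
            pep.start <= end and pep.end >= start
            for start, end in exposed_ranges
        )
        for cond in ("unpainted", "painted"):
            present = not (cond == "painted" and exposed)
            for r in range(1, n_replicates + 1):
                if present and rng.random() >= dropout:
                    observations.append(
                        PeptideObservation(
                            peptide=pep.sequence, start=pep.start, end=pep.end,
                            replicate=f"R{r}", condition=cond,
                        )
                    )
    return observations
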