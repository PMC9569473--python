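"""Cross-link and disulfide distance restraints: thresholds, evaluation, reports.

An amine-reactive cross-linker of known geometry bounds the Cα–Cα distance of
the two linked residues: the maximum is the spacer length plus the two
side-chain arms plus a flexibility allowance for backbone dynamics.  For DSSO
(disuccinimidyl sulfoxide, lysine-reactive) this is 10.1 + 2×6.29 + 3.0 =
25.68 Å, reported as the familiar ~26 Å threshold.  Distances measured in a
model are classified as satisfied (≤ threshold), marginal (within a grace
band just beyond it, default 30 Å) or violated; endpoints missing from the
model make a restraint unmeasurable rather than an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure import Structure

SATISFIED = "satisfied"
MARGINAL = "marginal"
VIOLATED = "violated"
UNMEASURABLE = "unmeasurable"

#: default width of a distance-histogram bin, Å (right-open bins from 0)
HISTOGRAM_BIN_WIDTH = 2.0

#: default outer bound of the "slightly beyond threshold" grace band, Å
DEFAULT_GRACE = 30.0


@dataclass(frozen=True)
class LinkerChemistry:
    """Geometry of a cross-linking reagent.

    ``sidechain_arm`` maps one-letter residue types to the side-chain arm
    length in Å (lysine: 6.29).  ``rounding`` controls how the reported
    threshold is derived from the raw sum ("nearest_int" or "none").
    """

    name: str
    spacer_length: float
    sidechain_arm: Mapping[str, float]
    flexibility_allowance: float = 0.0
    rounding: str = "nearest_int"

    def __post_init__(self):
        if self.spacer_length < 0 or self.flexibility_allowance < 0:
            raise ValueError("linker lengths must be non-negative")
        if any(v < 0 for v in self.sidechain_arm.values()):
            raise ValueError("side-chain arm lengths must be non-negative")

    def arm(self, res_type: str) -> float:
        try:
            return self.sidechain_arm[res_type]
        except KeyError:
            raise KeyError(
                f"linker {self.name!r} has no side-chain arm defined for "
                f"residue type {res_type!r}"
            ) from None

    def max_ca_ca(self, res_type_a: str = "K", res_type_b: str = "K") -> float:
        """Raw maximum Cα–Cα distance for a link between two residue types."""
        return (
            self.spacer_length
            + self.arm(res_type_a)
            + self.arm(res_type_b)
            + self.flexibility_allowance
        )

    def reported_threshold(self, res_type_a: str = "K", res_type_b: str = "K") -> float:
        raw = self.max_ca_ca(res_type_a, res_type_b)
        if self.rounding == "nearest_int":
            return float(round(raw))
        return raw


#: DSSO preset: 10.1 Å spacer, 6.29 Å lysine arm each side, 3.0 Å flexibility.
DSSO = LinkerChemistry(
    name="DSSO",
    spacer_length=10.1,
    sidechain_arm={"K": 6.29},
    flexibility_allowance=3.0,
)


def derive_max_ca_distance(
    linker: LinkerChemistry, res_type_a: str = "K", res_type_b: str = "K"
) -> tuple[float, float]:
    """Return (raw, reported) maximum Cα–Cα distance for the linker."""
    return (
        linker.max_ca_ca(res_type_a, res_type_b),
        linker.reported_threshold(res_type_a, res_type_b),
    )


@dataclass(frozen=True)
class CrossLink:
    """A residue-pair restraint in full-sequence numbering (canonical a < b)."""

    id: str
    res_a: int
    res_b: int
    linker: str = "DSSO"
    unique: bool = True

    def __post_init__(self):
        if self.res_a == self.res_b:
            raise ValueError(f"cross-link {self.id!r} links residue {self.res_a} to itself")
        a, b = sorted((self.res_a, self.res_b))
        object.__setattr__(self, "res_a", a)
        object.__setattr__(self, "res_b", b)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.res_a, self.res_b)


def dedupe_links(links: Iterable[CrossLink]) -> list[CrossLink]:
    """Collapse links identical after canonical ordering; first id wins."""
    seen: dict[tuple[int, int], CrossLink] = {}
    for link in links:
        seen.setdefault(link.pair, link)
    return list(seen.values())


@dataclass(frozen=True)
class DisulfidePair:
    """A cysteine pair expected to bond; sulfurs must lie within the bound."""

    cys_a: int
    cys_b: int
    max_ss_distance: float = 5.6

    def __post_init__(self):
        if self.max_ss_distance <= 0:
            raise ValueError("max_ss_distance must be positive")


#: Cα–Cα fallback bound for disulfides when SG atoms are absent (Cα-only model)
DISULFIDE_CA_FALLBACK = 7.5


@dataclass(frozen=True)
class RestraintEvaluation:
    """Outcome of measuring one restraint against a model."""

    restraint: object
    distance: float | None
    category: str
    atoms_used: tuple[str, str] = ("CA", "CA")
    fallback: bool = False

    def __post_init__(self):
        if (self.distance is None) != (self.category == UNMEASURABLE):
            raise ValueError("category is 'unmeasurable' iff distance is absent")


def measure_distance(
    structure: Structure, res_a: int, res_b: int, atom_name: str = "CA"
) -> float | None:
    """Euclidean distance between the named atoms, or None if either is missing."""
    pa = structure.coord(res_a, atom_name)
    pb = structure.coord(res_b, atom_name)
    if pa is None or pb is None:
        return None
    return float(np.linalg.norm(pa - pb))


def classify_distance(
    d: float, threshold: float = 26.0, grace: float = DEFAULT_GRACE
) -> str:
    """Partition a distance into satisfied / marginal / violated.

    The threshold is closed (d == threshold counts as satisfied), as is the
    grace bound.
    """
    if d < 0 or not math.isfinite(d):
        raise ValueError(f"distance must be finite and non-negative, got {d}")
    if threshold > grace:
        raise ValueError("threshold must not exceed grace bound")
    if d <= threshold:
        return SATISFIED
    if d <= grace:
        return MARGINAL
    return VIOLATED


def evaluate_crosslinks(
    structures: Structure | Sequence[Structure],
    links: Iterable[CrossLink],
    linker: LinkerChemistry = DSSO,
    coverage_mask: set[int] | None = None,
    *,
    threshold: float | None = None,
    grace: float = DEFAULT_GRACE,
    sequence_span: tuple[int, int] | None = None,
    atom_name: str = "CA",
) -> list[RestraintEvaluation]:
    """Evaluate unique cross-links against one or several segment models.

    ``coverage_mask``, when given, is the set of residues actually modeled;
    links with an endpoint outside it are unmeasurable.  ``threshold``
    defaults to the linker's reported threshold (26 Å for DSSO K–K).
    Endpoints outside ``sequence_span`` (when given) raise, since they cannot
    belong to the protein at all.
    """
    from .structure import merge as merge_structures

    if isinstance(structures, Structure):
        structure = structures
    else:
        structure = merge_structures(structures)
    if threshold is None:
        threshold = linker.reported_threshold()
    out: list[RestraintEvaluation] = []
    for link in dedupe_links(links):
        for res in link.pair:
            if sequence_span is not None and not (
                sequence_span[0] <= res <= sequence_span[1]
            ):
                raise ValueError(
                    f"cross-link {link.id!r} endpoint {res} outside sequence "
                    f"span {sequence_span}"
                )
        if coverage_mask is not None and (
            link.res_a not in coverage_mask or link.res_b not in coverage_mask
        ):
            out.append(
                RestraintEvaluation(link, None, UNMEASURABLE, (atom_name, atom_name))
            )
            continue
        d = measure_distance(structure, link.res_a, link.res_b, atom_name)
        if d is None:
            out.append(
                RestraintEvaluation(link, None, UNMEASURABLE, (atom_name, atom_name))
            )
        else:
            out.append(
                RestraintEvaluation(
                    link, d, classify_distance(d, threshold, grace),
                    (atom_name, atom_name),
                )
            )
    return out


def evaluate_disulfide(
    structure: Structure, pair: DisulfidePair
) -> RestraintEvaluation:
    """Evaluate one disulfide restraint (SG–SG; Cα fallback on Cα-only models).

    Both residues must be cysteines in the model. When SG atoms are absent the
    Cα–Cα distance is compared against a wider bound
    (:data:`DISULFIDE_CA_FALLBACK`) and the evaluation is flagged.
    """
    for res in (pair.cys_a, pair.cys_b):
        name = structure.residue_name(res)
        if name is not None and name.upper() not in ("CYS", "C"):
            raise ValueError(f"residue {res} is {name}, not cysteine")
    d = measure_distance(structure, pair.cys_a, pair.cys_b, "SG")
    if d is not None:
        cat = SATISFIED if d <= pair.max_ss_distance else VIOLATED
        return RestraintEvaluation(pair, d, cat, ("SG", "SG"))
    d = measure_distance(structure, pair.cys_a, pair.cys_b, "CA")
    if d is None:
        return RestraintEvaluation(pair, None, UNMEASURABLE, ("SG", "SG"))
    cat = SATISFIED if d <= DISULFIDE_CA_FALLBACK else VIOLATED
    return RestraintEvaluation(pair, d, cat, ("CA", "CA"), fallback=True)


@dataclass
class ValidationReport:
    """Bookkeeping totals of a restraint evaluation run."""

    n_identified: int
    n_measured: int
    n_satisfied: int
    n_marginal: int
    n_violated: int
    percent_within_threshold: float
    per_segment: dict = field(default_factory=dict)
    per_topology: dict = field(default_factory=dict)
    histogram: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)
    marginals: list = field(default_factory=list)

    @property
    def n_unmeasurable(self) -> int:
        return self.n_identified - self.n_measured

    def to_dict(self) -> dict:
        return {
            "n_identified": self.n_identified,
            "n_measured": self.n_measured,
            "n_unmeasurable": self.n_unmeasurable,
            "n_satisfied": self.n_satisfied,
            "n_marginal": self.n_marginal,
            "n_violated": self.n_violated,
            "percent_within_threshold": self.percent_within_threshold,
            "per_segment": self.per_segment,
            "per_topology": self.per_topology,
            "histogram": self.histogram,
            "violations": self.violations,
            "marginals": self.marginals,
        }


def summarize(
    evaluations: Sequence[RestraintEvaluation],
    scheme=None,
    *,
    bin_width: float = HISTOGRAM_BIN_WIDTH,
) -> ValidationReport:
    """Aggregate evaluations into a :class:`ValidationReport`.

    When a segmentation scheme is given, counts are additionally broken down
    per subunit-level segment and by link topology (intra-domain /
    intra-subunit / inter-subunit).  Violation and marginal lists are ordered
    by distance descending, ties by residue index.
    """
    measured = [e for e in evaluations if e.distance is not None]
    n_sat = sum(1 for e in measured if e.category == SATISFIED)
    n_marg = sum(1 for e in measured if e.category == MARGINAL)
    n_viol = sum(1 for e in measured if e.category == VIOLATED)
    n_meas = len(measured)
    pct = 100.0 * n_sat / n_meas if n_meas else 0.0

    def _link_key(e):
        r = e.restraint
        return (getattr(r, "res_a", getattr(r, "cys_a", 0)),
                getattr(r, "res_b", getattr(r, "cys_b", 0)))

    def _entry(e):
        a, b = _link_key(e)
        return {
            "id": getattr(e.restraint, "id", f"{a}-{b}"),
            "res_a": a,
            "res_b": b,
            "distance": round(e.distance, 2),
            "category": e.category,
        }

    order = lambda e: (-e.distance, _link_key(e))
    violations = [_entry(e) for e in sorted(
        (e for e in measured if e.category == VIOLATED), key=order)]
    marginals = [_entry(e) for e in sorted(
        (e for e in measured if e.category == MARGINAL), key=order)]

    histogram: dict = {}
    if measured:
        dists = np.array([e.distance for e in measured])
        n_bins = int(np.floor(dists.max() / bin_width)) + 1
        edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
        counts, _ = np.histogram(dists, bins=edges)
        histogram = {
            "bin_width": bin_width,
            "edges": [round(float(x), 6) for x in edges],
            "counts": [int(c) for c in counts],
        }

    per_segment: dict = {}
    per_topology: dict = {}
    if scheme is not None:
        for e in evaluations:
            a, b = _link_key(e)
            seg_a = scheme.locate(a).get("subunit")
            seg_b = scheme.locate(b).get("subunit")
            for seg in {s for s in (seg_a, seg_b) if s}:
                bucket = per_segment.setdefault(
                    seg, {SATISFIED: 0, MARGINAL: 0, VIOLATED: 0, UNMEASURABLE: 0}
                )
                bucket[e.category] += 1
        for e in measured:
            a, b = _link_key(e)
            try:
                topo = scheme.classify_topology(a, b)
            except ValueError:
                topo = "outside"
            bucket = per_topology.setdefault(
                topo, {SATISFIED: 0, MARGINAL: 0, VIOLATED: 0}
            )
            bucket[e.category] += 1

    return ValidationReport(
        n_identified=len(evaluations),
        n_measured=n_meas,
        n_satisfied=n_sat,
        n_marginal=n_marg,
        n_violated=n_viol,
        percent_within_threshold=pct,
        per_segment=per_segment,
        per_topology=per_topology,
        histogram=histogram,
        violations=violations,
        marginals=marginals,
    )


def evaluations_from_distances(
    distances: Iterable[float],
    threshold: float = 26.0,
    grace: float = DEFAULT_GRACE,
) -> list[RestraintEvaluation]:
    """Build evaluations directly from a list of measured distances.

    Useful for re-summarizing published distance lists when the underlying
    coordinates are unavailable.  Links get sequential synthetic ids.
    """
    out = []
    for i, d in enumerate(distances, start=1):
        link = CrossLink(id=f"L{i:03d}", res_a=2 * i - 1, res_b=2 * i)
        out.append(
            RestraintEvaluation(link, float(d), classify_distance(d, threshold, grace))
        )
    return out
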