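"""Divide-and-conquer segmentation bookkeeping for very large proteins.

A segmentation scheme names subunits, domains and long coils as inclusive
residue ranges in full-sequence (preproprotein) numbering, e.g. apoB-100's
five subunits over residues 28–4563.  The module maps residues to segments,
classifies cross-link topology (intra-domain / intra-subunit / inter-subunit),
tabulates secondary-structure content, builds consensus domain boundaries
from overlapping sliding-window predictions, and performs in-silico tryptic
digestion for peptide-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

LEVELS = ("subunit", "domain", "coil")

Range = tuple[int, int]


def residue_count(ranges: Range | Iterable[Range]) -> int:
    """Number of residues in one or several inclusive 1-based ranges."""
    if isinstance(ranges, tuple) and len(ranges) == 2 and isinstance(ranges[0], int):
        ranges = [ranges]
    total = 0
    for start, end in ranges:
        if end < start:
            raise ValueError(f"invalid range [{start}, {end}]: end < start")
        total += end - start + 1
    return total


@dataclass(frozen=True)
class Segment:
    """A named region at one level, possibly built from several ranges
    (e.g. a domain assembled from three separate stretches of sequence)."""

    name: str
    level: str
    ranges: tuple[Range, ...]

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        for start, end in self.ranges:
            if end < start:
                raise ValueError(f"segment {self.name!r}: invalid range [{start},{end}]")

    def __contains__(self, residue: int) -> bool:
        return any(start <= residue <= end for start, end in self.ranges)

    @property
    def n_residues(self) -> int:
        return residue_count(self.ranges)


@dataclass(frozen=True)
class SegmentationScheme:
    """Named subunits/domains/coils with the overall modeled sequence span."""

    segments: tuple[Segment, ...]
    sequence_span: Range
    coverage_mask: frozenset[int] | None = None

    def __post_init__(self):
        lo, hi = self.sequence_span
        by_level: dict[str, list[Range]] = {}
        for seg in self.segments:
            for start, end in seg.ranges:
                if start < lo or end > hi:
                    raise ValueError(
                        f"segment {seg.name!r} range [{start},{end}] outside "
                        f"sequence span {self.sequence_span}"
                    )
            by_level.setdefault(seg.level, []).extend(seg.ranges)
        for level, ranges in by_level.items():
            ranges = sorted(ranges)
            for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping ranges at level {level!r}: "
                        f"[{s1},{e1}] and [{s2},{e2}]"
                    )

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def at_level(self, level: str) -> list[Segment]:
        return [s for s in self.segments if s.level == level]

    def locate(self, residue: int) -> dict[str, str]:
        """Map a residue to its segment name at each level.

        Returns ``{"outside": True}``-style marker (an empty mapping with key
        ``"outside"``) when the residue falls outside the sequence span; a
        residue inside the span maps to at most one segment per level and
        levels with no segment covering it are simply absent from the result.
        """
        lo, hi = self.sequence_span
        if residue < lo or residue > hi:
            return {"outside": "outside"}
        return {
            seg.level: seg.name for seg in self.segments if residue in seg
        }

    def classify_topology(self, res_a: int, res_b: int) -> str:
        """intra-domain / intra-subunit / inter-subunit for a residue pair."""
        loc_a, loc_b = self.locate(res_a), self.locate(res_b)
        if "outside" in loc_a or "outside" in loc_b:
            raise ValueError(
                f"residue pair ({res_a}, {res_b}) has an endpoint outside "
                f"span {self.sequence_span}"
            )
        if loc_a.get("subunit") != loc_b.get("subunit"):
            return "inter-subunit"
        dom_a, dom_b = loc_a.get("domain"), loc_b.get("domain")
        if dom_a is not None and dom_a == dom_b:
            return "intra-domain"
        return "intra-subunit"


def coverage_fraction(segment: Segment | str, scheme: SegmentationScheme) -> float:
    """Segment size as a percentage of the scheme's span, 1-decimal rounded."""
    if isinstance(segment, str):
        segment = scheme.segment(segment)
    total = residue_count(scheme.sequence_span)
    return round(100.0 * segment.n_residues / total, 1)


# ---------------------------------------------------------------------------
# secondary-structure content

SS_LABELS = ("H", "E", "C")


def ss_content(
    assignment: str | Mapping[int, str],
    scheme: SegmentationScheme,
    *,
    convention: str = "total",
) -> dict[str, dict[str, float]]:
    """Helix/strand/coil percentages per subunit-level segment plus a total row.

    ``assignment`` is either a per-residue label string covering the whole
    sequence span (first character = first residue of the span) or a mapping
    residue → label.  With the default ``convention="total"`` each cell is the
    segment's residues of that class divided by the whole-span length, so the
    table's cells sum to ~100 overall and the Total row is the column sums.
    ``convention="per_segment"`` normalizes each row by its own segment length.
    """
    lo, hi = scheme.sequence_span
    span_len = hi - lo + 1
    if isinstance(assignment, str):
        if len(assignment) != span_len:
            raise ValueError(
                f"assignment string length {len(assignment)} != span length {span_len}"
            )
        labels = {lo + i: c for i, c in enumerate(assignment)}
    else:
        labels = dict(assignment)

    subunits = scheme.at_level("subunit")
    missing = sorted(
        res
        for seg in subunits
        for start, end in seg.ranges
        for res in range(start, end + 1)
        if res not in labels
    )
    if missing:
        head = ", ".join(map(str, missing[:10]))
        raise ValueError(
            f"{len(missing)} residues lack a secondary-structure label "
            f"(first few: {head})"
        )
    bad = sorted({v for v in labels.values() if v not in SS_LABELS})
    if bad:
        raise ValueError(f"unknown secondary-structure labels: {bad}")

    table: dict[str, dict[str, float]] = {}
    for seg in subunits:
        counts = {lab: 0 for lab in SS_LABELS}
        for start, end in seg.ranges:
            for res in range(start, end + 1):
                counts[labels[res]] += 1
        denom = span_len if convention == "total" else seg.n_residues
        table[seg.name] = {
            lab: round(100.0 * counts[lab] / denom, 1) for lab in SS_LABELS
        }
    table["Total"] = aggregate_content(
        {k: v for k, v in table.items() if k != "Total"}
    )
    return table


def aggregate_content(rows: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Column sums of a per-segment content table (percent-of-total cells)."""
    return {
        lab: round(sum(row.get(lab, 0.0) for row in rows.values()), 1)
        for lab in SS_LABELS
    }


# ---------------------------------------------------------------------------
# consensus domain boundaries

@dataclass(frozen=True)
class BoundaryPrediction:
    """Predicted domain boundaries from one sliding window of the sequence."""

    window: Range
    boundaries: tuple[int, ...]

    def __post_init__(self):
        start, end = self.window
        for b in self.boundaries:
            if not (start < b < end):
                raise ValueError(
                    f"boundary {b} not strictly inside window [{start},{end}]"
                )

    def covers(self, position: int) -> bool:
        return self.window[0] <= position <= self.window[1]


def consensus_boundaries(
    predictions: Sequence[BoundaryPrediction],
    tolerance: int = 10,
    min_support: int = 2,
) -> list[int]:
    """Cluster per-window boundary predictions into consensus positions.

    Positions from all windows are single-linkage clustered (adjacent gaps
    > ``tolerance`` split clusters).  A cluster is kept when the number of
    distinct windows contributing to it reaches ``min(min_support, number of
    windows covering its representative)``; the representative is the rounded
    median.  Window order does not matter.
    """
    if tolerance < 0 or min_support < 1:
        raise ValueError("tolerance must be >= 0 and min_support >= 1")
    points = sorted(
        (b, i) for i, pred in enumerate(predictions) for b in pred.boundaries
    )
    if not points:
        return []
    clusters: list[list[tuple[int, int]]] = [[points[0]]]
    for p in points[1:]:
        if p[0] - clusters[-1][-1][0] <= tolerance:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for cluster in clusters:
        rep = int(round(median(b for b, _ in cluster)))
        support = len({i for _, i in cluster})
        covering = sum(1 for pred in predictions if pred.covers(rep))
        if support >= min(min_support, max(covering, 1)):
            out.append(rep)
    return out


# ---------------------------------------------------------------------------
# in-silico digestion

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")


def digest(
    sequence: str,
    enzyme: str = "trypsin",
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: int | None = None,
    on_nonstandard: str = "error",
) -> list[Peptide]:
    """Tryptic digestion: cleave after K/R except before P.

    Enumerates peptides with up to ``missed_cleavages`` internal cleavage
    sites, then filters by length.  Non-standard residues raise by default;
    ``on_nonstandard="skip-site"`` treats them as ordinary non-cleaving
    residues instead.
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    sequence = sequence.upper()
    bad = sorted(set(sequence) - STANDARD_AA)
    if bad:
        if on_nonstandard == "error":
            raise ValueError(f"non-standard residues in sequence: {bad}")
        if on_nonstandard != "skip-site":
            raise ValueError(f"unknown on_nonstandard mode {on_nonstandard!r}")
    n = len(sequence)
    # cleavage points: index i means a cut between sequence[i-1] and sequence[i]
    cuts = [0]
    for i in range(1, n):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            cuts.append(i)
    cuts.append(n)
    peptides: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[i], cuts[j]
            length = end - start
            if length < min_len or (max_len is not None and length > max_len):
                continue
            peptides.append(Peptide(sequence[start:end], start + 1, end))
    return peptides


# ---------------------------------------------------------------------------
# packaged apoB-100 segmentation

def apob100_scheme() -> SegmentationScheme:
    """The packaged apoB-100 five-subunit / eleven-domain segmentation.

    Mature apoB-100 spans preproprotein residues 28–4563 (the 27-residue
    signal peptide keeps its coordinates but lies outside the span).  Subunit
    IV domain 3 is assembled from three separate sequence stretches; residues
    2274–2292 and a few other short linkers belong to no domain.  The
    coverage mask excludes 2551–2590, which the subunit IV model leaves
    unmodeled.
    """
    from .io_formats import load_packaged_scheme

    return load_packaged_scheme()


#: Per-subunit secondary-structure content (percent of total sequence) of the
#: packaged apoB-100 model: helix/strand/coil cells sum across subunits to the
#: whole-protein composition (~24% H, 41% E, 35% C).
APOB100_SS_CONTENT: dict[str, dict[str, float]] = {
    "Subunit I": {"H": 7.0, "E": 6.5, "C": 8.0},
    "Subunit II": {"H": 0.5, "E": 12.5, "C": 10.5},
    "Subunit III": {"H": 5.0, "E": 0.0, "C": 5.0},
    "Subunit IV": {"H": 1.0, "E": 22.0, "C": 10.5},
    "Subunit V": {"H": 10.5, "E": 0.0, "C": 1.0},
}
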