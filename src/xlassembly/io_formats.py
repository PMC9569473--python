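"""Readers and writers for the formats the toolkit owns.

Structures are exchanged as PDB (read through gemmi, model 1 only, highest-
occupancy altloc kept, insertion codes rejected); cross-links as TSV with a
required header (id, res_a, res_b, linker[, n_csms, score]); segmentation
schemes as YAML; validation reports as stable-ordered JSON.  Residue indices
are 1-based inclusive full-sequence numbering everywhere.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import pandas as pd
import yaml
from Bio import SeqIO

from .restraints import CrossLink, RestraintEvaluation, ValidationReport, dedupe_links
from .segmentation import Segment, SegmentationScheme
from .structure import AtomRecord, Structure

__all__ = [
    "AtomRecord",
    "Structure",
    "read_structure",
    "write_structure",
    "read_links",
    "write_links",
    "read_scheme",
    "write_scheme",
    "load_packaged_scheme",
    "read_fasta",
    "write_report",
    "write_pseudobonds",
]


def read_structure(path: str | Path, *, numbering_offset: int = 0) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Multi-model files use model 1 (with a warning).  For atoms with
    alternate locations the highest-occupancy conformer is kept.  Insertion
    codes are rejected: full-sequence numbering leaves no room for them.
    ``numbering_offset`` is added to every residue number, supporting domain
    models numbered from 1.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) > 1:
        warnings.warn(
            f"{path.name}: {len(st)} models present; using model 1", stacklevel=2
        )
    model = st[0]
    atoms: list[AtomRecord] = []
    best: dict[tuple[str, int, str], tuple[float, AtomRecord]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            if residue.seqid.icode not in (" ", "", "\x00"):
                raise ValueError(
                    f"{path.name}: insertion code {residue.seqid.icode!r} at "
                    f"residue {residue.seqid.num} not supported "
                    "(full-sequence numbering required)"
                )
            for atom in residue:
                rec = AtomRecord(
                    chain=chain.name,
                    res_num=residue.seqid.num + numbering_offset,
                    res_name=residue.name,
                    atom_name=atom.name,
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    element=atom.element.name,
                )
                key = (rec.chain, rec.res_num, rec.atom_name)
                occ = atom.occ if atom.altloc not in ("", "\x00") else float("inf")
                if key not in best:
                    order.append(key)
                    best[key] = (occ, rec)
                elif occ > best[key][0]:
                    best[key] = (occ, rec)
    atoms = [best[k][1] for k in order]
    return Structure(atoms, name=path.stem)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as plain PDB ATOM records."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        element = (a.element or a.atom_name[:1]).rjust(2)
        lines.append(
            f"ATOM  {i:>5d} {name:<4s} {a.res_name:<3s} {a.chain:1s}"
            f"{a.res_num:>4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cross-link TSV

_REQUIRED_LINK_COLUMNS = ("id", "res_a", "res_b", "linker")
_OPTIONAL_LINK_COLUMNS = ("n_csms", "score")


def read_links(path: str | Path) -> list[CrossLink]:
    """Read a cross-link TSV; duplicate canonical pairs are collapsed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_LINK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [
        c
        for c in df.columns
        if c not in _REQUIRED_LINK_COLUMNS + _OPTIONAL_LINK_COLUMNS
    ]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    links = []
    for row in df.itertuples(index=False):
        try:
            res_a, res_b = int(row.res_a), int(row.res_b)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-integer residue index in link {row.id!r}: "
                f"res_a={row.res_a!r} res_b={row.res_b!r}"
            ) from None
        links.append(CrossLink(id=str(row.id), res_a=res_a, res_b=res_b,
                               linker=str(row.linker)))
    return dedupe_links(links)


def write_links(links: Iterable[CrossLink], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"id": l.id, "res_a": l.res_a, "res_b": l.res_b, "linker": l.linker}
         for l in links]
    )
    if df.empty:
        df = pd.DataFrame(columns=list(_REQUIRED_LINK_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segmentation scheme YAML

def _scheme_from_dict(doc: dict) -> SegmentationScheme:
    span = tuple(doc["sequence_span"])
    names = [s["name"] for s in doc["segments"]]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate segment names in scheme: {dupes}")
    segments = tuple(
        Segment(
            name=s["name"],
            level=s["level"],
            ranges=tuple((int(a), int(b)) for a, b in s["ranges"]),
        )
        for s in doc["segments"]
    )
    mask = None
    if doc.get("coverage_mask_excludes"):
        mask_set = set(range(span[0], span[1] + 1))
        for a, b in doc["coverage_mask_excludes"]:
            mask_set -= set(range(int(a), int(b) + 1))
        mask = frozenset(mask_set)
    return SegmentationScheme(segments=segments, sequence_span=span,
                              coverage_mask=mask)


def read_scheme(path: str | Path) -> SegmentationScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _scheme_from_dict(doc)


def write_scheme(scheme: SegmentationScheme, path: str | Path,
                 name: str = "scheme") -> None:
    doc = {
        "name": name,
        "sequence_span": list(scheme.sequence_span),
        "segments": [
            {"name": s.name, "level": s.level,
             "ranges": [list(r) for r in s.ranges]}
            for s in scheme.segments
        ],
    }
    if scheme.coverage_mask is not None:
        lo, hi = scheme.sequence_span
        excluded = sorted(set(range(lo, hi + 1)) - scheme.coverage_mask)
        runs, start = [], None
        prev = None
        for r in excluded:
            if start is None:
                start = prev = r
            elif r == prev + 1:
                prev = r
            else:
                runs.append([start, prev])
                start = prev = r
        if start is not None:
            runs.append([start, prev])
        doc["coverage_mask_excludes"] = runs
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_packaged_scheme() -> SegmentationScheme:
    """The apoB-100 scheme shipped with the package."""
    text = resources.files("xlassembly.data").joinpath(
        "apob100_scheme.yaml").read_text()
    return _scheme_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# sequences, reports, pseudobonds

def read_fasta(path: str | Path) -> str:
    """First sequence of a FASTA file, as an uppercase string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_report(report: ValidationReport | dict, path: str | Path) -> None:
    """Stable-ordered, diff-friendly JSON export of a validation report."""
    payload = report.to_dict() if isinstance(report, ValidationReport) else report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


_CATEGORY_COLORS = {
    "satisfied": "#2ca02c",
    "marginal": "#ff7f0e",
    "violated": "#d62728",
    "unmeasurable": "#7f7f7f",
}


def write_pseudobonds(
    evaluations: Sequence[RestraintEvaluation],
    path: str | Path,
    chain: str = "A",
) -> None:
    """Export links as a pseudobond text file loadable by molecular viewers:
    one line per link, ``/<chain>:<res_a>@CA /<chain>:<res_b>@CA <color>``."""
    lines = []
    for e in evaluations:
        r = e.restraint
        a = getattr(r, "res_a", getattr(r, "cys_a", None))
        b = getattr(r, "res_b", getattr(r, "cys_b", None))
        atom_a, atom_b = e.atoms_used
        color = _CATEGORY_COLORS[e.category]
        lines.append(f"/{chain}:{a}@{atom_a} /{chain}:{b}@{atom_b} {color}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
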