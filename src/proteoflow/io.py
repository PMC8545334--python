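"""Readers and writers for every external format the pipeline touches.

Supported inputs: TSV/CSV expression tables (rows = proteins, first column =
identifier), sample-design tables, Reactome-style annotation flat files
(all-levels layout) and two-column parent/child relation files, GMT gene-set
files, and STRING-style protein links files.  Database freshness is checked
with MD5 digests of the raw bytes.
"""

from __future__ import annotations

import csv
import hashlib
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .errors import (
    DimensionError,
    EmptyDatabaseError,
    FormatError,
    ValidationError,
)
from .network import InteractionNetwork

#: Cell contents treated as missing, compared case-insensitively.
MISSING_TOKENS = ("", "na", "nan", "null")


def md5_digest(path) -> str:
    """MD5 hex digest (32 lowercase hex chars) of a file's raw bytes."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class DatasetFile:
    """A dataset on disk together with its byte-level identity."""

    path: str
    digest: str
    n_rows: int
    n_cols: int

    @classmethod
    def from_path(cls, path) -> "DatasetFile":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        n_rows = max(len(lines) - 1, 0)
        n_cols = len(lines[0].split("\t")) if lines else 0
        return cls(str(path), md5_digest(path), n_rows, n_cols)


@dataclass
class DatabaseRelease:
    """Version tag + per-file digests of a pathway or interaction release."""

    source_name: str  # "pathway" | "interaction"
    version_tag: str
    file_digests: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version_tag:
            raise ValidationError("version_tag must be non-empty")

    @classmethod
    def from_files(cls, source_name: str, version_tag: str, paths: Iterable) -> "DatabaseRelease":
        digests = {os.path.basename(str(p)): md5_digest(p) for p in paths}
        return cls(source_name, version_tag, digests)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_expression_table(
    path,
    delimiter: Optional[str] = None,
    missing_tokens: Iterable[str] = MISSING_TOKENS,
) -> ExpressionMatrix:
    """Parse a proteins x samples abundance table.

    The first column holds protein identifiers; the remaining columns are
    numeric or missing-value tokens (empty, NA, NaN, null — case-insensitive).
    Duplicate identifiers are kept, suffixed ``#2``, ``#3``... and reported
    in :attr:`ExpressionMatrix.duplicates`; nothing is aggregated silently.

    Raises :class:`FormatError` naming the first offending line when a cell
    is neither numeric nor a missing token, and :class:`DimensionError` when
    fewer than two sample columns are present.
    """
    sep = delimiter or _sniff_delimiter(path)
    missing = {t.lower() for t in missing_tokens}
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] < 3:
        raise DimensionError(
            f"{path}: need an identifier column plus >=2 sample columns, "
            f"got {raw.shape[1] - 1} sample column(s)"
        )

    ids = [str(x).strip() for x in raw.iloc[:, 0]]
    body = raw.iloc[:, 1:].copy()
    cleaned = body.apply(lambda col: col.str.strip())
    is_missing = cleaned.apply(lambda col: col.str.lower().isin(missing))
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        # +2: header line plus 1-based counting
        raise FormatError(
            f"{path}: line {row + 2} has a non-numeric value "
            f"({ids[row]!r}) that is not a recognized missing token"
        )
    numeric = numeric.where(~is_missing)

    counts: dict[str, int] = {}
    duplicates: dict[str, int] = {}
    unique_ids = []
    for pid in ids:
        counts[pid] = counts.get(pid, 0) + 1
        if counts[pid] == 1:
            unique_ids.append(pid)
        else:
            unique_ids.append(f"{pid}#{counts[pid]}")
            duplicates[pid] = counts[pid]
    numeric.index = pd.Index(unique_ids, name=raw.columns[0])
    numeric.columns = [str(c) for c in raw.columns[1:]]
    return ExpressionMatrix(values=numeric.astype(float), duplicates=duplicates)


def write_expression_table(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Inverse of :func:`read_expression_table`; missing cells written empty."""
    m.values.to_csv(path, sep=delimiter, na_rep="")


def read_design_table(path) -> SampleDesign:
    """Sample design TSV/CSV with columns sample, condition[, subject]."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    return SampleDesign.from_frame(df)


# ---------------------------------------------------------------------------
# pathway annotation + relation files
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecords:
    """Raw protein -> pathway annotation records after species filtering."""

    records: pd.DataFrame  # columns: protein_id, pathway_id, pathway_name, species
    n_kept: int
    n_dropped: int


def read_pathway_annotations(
    path, species: str = "Homo sapiens", fmt: str = "auto"
) -> AnnotationRecords:
    """Parse pathway annotations from a Reactome-style flat file or GMT.

    The flat-file layout is tab-separated with either four columns
    (protein, pathway id, pathway name, species) or the six-column
    all-levels layout (protein, pathway id, url, pathway name, evidence,
    species).  Records are filtered to the selected species.  GMT files
    (set name, description, members...) expand to one record per member and
    are species-agnostic.
    """
    if fmt == "auto":
        fmt = "gmt" if str(path).lower().endswith(".gmt") else "flat"

    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if fmt == "gmt":
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}: line {lineno}: GMT needs name, description "
                        "and at least one member"
                    )
                set_id, _desc = parts[0], parts[1]
                for member in parts[2:]:
                    if member:
                        rows.append((member, set_id, set_id, species))
                continue
            if len(parts) == 6:  # all-levels layout
                pid, pw, _url, name, _evidence, sp = parts
            elif len(parts) == 4:
                pid, pw, name, sp = parts
            else:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 or 6 tab-separated "
                    f"fields, got {len(parts)}"
                )
            if not pw.strip():
                raise FormatError(f"{path}: line {lineno}: missing pathway id")
            if sp == species:
                rows.append((pid, pw, name, sp))
            else:
                dropped += 1

    if not rows:
        raise EmptyDatabaseError(f"{path}: no records for species {species!r}")
    records = pd.DataFrame(
        rows, columns=["protein_id", "pathway_id", "pathway_name", "species"]
    )
    return AnnotationRecords(records=records, n_kept=len(rows), n_dropped=dropped)


def read_pathway_relations(path) -> list[tuple[str, str]]:
    """Two-column parent/child relation file -> deduplicated edge list.

    Self-loops are structural corruption and raise :class:`ValidationError`.
    """
    edges: list[tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected parent and child columns"
                )
            parent, child = parts[0].strip(), parts[1].strip()
            if parent == child:
                raise ValidationError(
                    f"{path}: line {lineno}: self-loop {parent!r} -> {child!r}"
                )
            if (parent, child) not in seen:
                seen.add((parent, child))
                edges.append((parent, child))
    return edges


# ---------------------------------------------------------------------------
# interaction files
# ---------------------------------------------------------------------------

def strip_species_prefix(pid: str) -> str:
    """Drop a leading STRING species prefix such as ``9606.`` if present."""
    head, dot, tail = pid.partition(".")
    if dot and head.isdigit() and tail:
        return tail
    return pid


def read_interactions(path, score_cutoff: float = 400.0) -> InteractionNetwork:
    """Parse a STRING-style links file (protein_a, protein_b, combined_score).

    Whitespace- or tab-separated; scores on the native 0-1000 scale.  A-B and
    B-A duplicates collapse to a single undirected edge keeping the maximum
    score; edges below ``score_cutoff`` are dropped.  A species prefix like
    ``9606.`` is stripped from identifiers.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected protein_a protein_b score"
                )
            a, b, raw_score = parts[0], parts[1], parts[2]
            if lineno == 1 and not _is_number(raw_score):
                continue  # header line
            if not _is_number(raw_score):
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric score {raw_score!r}"
                )
            score = float(raw_score)
            a, b = strip_species_prefix(a), strip_species_prefix(b)
            if a == b:
                continue  # self-interactions carry no network information
            edges.append((a, b, score))
    net = InteractionNetwork.from_edges(edges)
    keep = [(a, b, s) for a, b, s in net.edges_with_scores() if s >= score_cutoff]
    return InteractionNetwork.from_edges(keep)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# release freshness
# ---------------------------------------------------------------------------

def verify_release(release: DatabaseRelease, files: Iterable) -> dict:
    """Compare recorded digests against files on disk.

    Files are matched to release entries by basename.  The overall status is
    ``"fresh"`` only when every recorded file is present and byte-identical;
    a single mismatch or absence makes it ``"stale"``.
    """
    by_name = {os.path.basename(str(p)): str(p) for p in files}
    per_file = {}
    for name, recorded in release.file_digests.items():
        path = by_name.get(name)
        if path is None or not os.path.exists(path):
            per_file[name] = "absent"
        elif md5_digest(path) == recorded:
            per_file[name] = "match"
        else:
            per_file[name] = "mismatch"
    status = "fresh" if all(v == "match" for v in per_file.values()) else "stale"
    return {"status": status, "files": per_file, "version_tag": release.version_tag}
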