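"""Identifier namespace detection and five-way conversion.

Uploaded protein lists arrive keyed by one of five namespaces: UniProt
accessions, gene symbols, Ensembl gene ids, Ensembl protein ids or Entrez
gene ids.  The namespace is auto-detected by majority vote of per-identifier
pattern classification, and conversion among namespaces goes through an
explicit relation-valued mapping table so that unmapped and one-to-many
cases are accounted for rather than lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .containers import ExpressionMatrix
from .errors import CoverageError, ValidationError

UNIPROT_ACCESSION = "uniprot_accession"
GENE_SYMBOL = "gene_symbol"
ENSEMBL_GENE = "ensembl_gene"
ENSEMBL_PROTEIN = "ensembl_protein"
ENTREZ_GENE = "entrez_gene"

NAMESPACES = (
    UNIPROT_ACCESSION,
    GENE_SYMBOL,
    ENSEMBL_GENE,
    ENSEMBL_PROTEIN,
    ENTREZ_GENE,
)

# Official UniProt accession grammar (6- and 10-character forms).
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
_ENSEMBL_GENE_RE = re.compile(r"^ENS[A-Z]*G\d{11}$")
_ENSEMBL_PROTEIN_RE = re.compile(r"^ENS[A-Z]*P\d{11}$")
_ENTREZ_RE = re.compile(r"^\d+$")
_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.\-@]*$")

# More specific grammars win ties; gene_symbol is the fallback.
_PRIORITY = (
    (UNIPROT_ACCESSION, _UNIPROT_RE),
    (ENSEMBL_PROTEIN, _ENSEMBL_PROTEIN_RE),
    (ENSEMBL_GENE, _ENSEMBL_GENE_RE),
    (ENTREZ_GENE, _ENTREZ_RE),
    (GENE_SYMBOL, _SYMBOL_RE),
)


def classify_id(identifier: str) -> Optional[str]:
    """Namespace of a single identifier, or None if unclassifiable."""
    identifier = identifier.strip()
    for ns, pattern in _PRIORITY:
        if pattern.match(identifier):
            return ns
    return None


def detect_namespace(
    ids: Iterable[str], sample_size: int = 200
) -> tuple[str, float]:
    """Majority-vote namespace detection over up to ``sample_size`` ids.

    Returns ``(namespace, confidence)`` where confidence is the winning
    fraction among the sampled ids.  Ties break by grammar specificity
    (uniprot > ensembl_protein > ensembl_gene > entrez > symbol).
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("cannot detect namespace of an empty id list")
    sampled = ids[: max(1, sample_size)]
    votes: dict[str, int] = {}
    for identifier in sampled:
        ns = classify_id(str(identifier))
        if ns is not None:
            votes[ns] = votes.get(ns, 0) + 1
    if not votes:
        raise ValidationError(
            "no identifier matched any known namespace grammar"
        )
    order = {ns: i for i, (ns, _) in enumerate(_PRIORITY)}
    winner = min(votes, key=lambda ns: (-votes[ns], order[ns]))
    return winner, votes[winner] / len(sampled)


@dataclass
class MappingTable:
    """Relation-valued map among identifier namespaces.

    ``pairs`` holds directed (source_ns, source_id, target_ns, target_id)
    rows with duplicates removed; one-to-many mappings are permitted and
    surface explicitly during conversion.
    """

    pairs: pd.DataFrame
    provenance: str = "unversioned"

    def __post_init__(self) -> None:
        expected = ["source_ns", "source_id", "target_ns", "target_id"]
        if list(self.pairs.columns) != expected:
            self.pairs = self.pairs[expected]
        if (self.pairs[["source_id", "target_id"]] == "").any().any():
            raise ValidationError("mapping table contains empty identifiers")
        self.pairs = self.pairs.drop_duplicates(ignore_index=True)

    @classmethod
    def from_tsv(cls, path, provenance: str = "unversioned") -> "MappingTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype=str,
            keep_default_na=False,
            names=["source_ns", "source_id", "target_ns", "target_id"],
            header=0,
        )
        return cls(df, provenance=provenance)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    def covers(self, from_ns: str, to_ns: str) -> bool:
        sel = (self.pairs["source_ns"] == from_ns) & (
            self.pairs["target_ns"] == to_ns
        )
        return bool(sel.any())

    def lookup(self, from_ns: str, to_ns: str) -> dict[str, list[str]]:
        """source id -> lexicographically sorted target ids."""
        sel = self.pairs[
            (self.pairs["source_ns"] == from_ns)
            & (self.pairs["target_ns"] == to_ns)
        ]
        out: dict[str, list[str]] = {}
        for sid, tid in zip(sel["source_id"], sel["target_id"]):
            out.setdefault(sid, []).append(tid)
        return {k: sorted(set(v)) for k, v in out.items()}


@dataclass
class ConversionResult:
    """Per-identifier conversion outcomes plus summary counts."""

    ids: list[str]  # input order preserved
    outcomes: list[str]  # "mapped" | "multi" | "unmapped" | "dropped"
    targets: list[Optional[list[str]]]  # resolved targets (None if unmapped)
    policy: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def converted(self) -> list[str]:
        """Flat output list after policy resolution (input order)."""
        out = []
        for outcome, tgt in zip(self.outcomes, self.targets):
            if outcome in ("mapped", "multi") and tgt:
                out.extend(tgt if self.policy == "all" else tgt[:1])
        return out

    def mapping(self) -> dict[str, Optional[str]]:
        """input id -> first resolved target (None when unmapped/dropped)."""
        out = {}
        for i, outcome, tgt in zip(self.ids, self.outcomes, self.targets):
            out[i] = tgt[0] if outcome in ("mapped", "multi") and tgt else None
        return out


def convert(
    ids: Iterable[str],
    from_ns: str,
    to_ns: str,
    table: MappingTable,
    policy: str = "first",
) -> ConversionResult:
    """Convert identifiers between namespaces.

    Policies for one-to-many mappings: ``first`` keeps the lexicographically
    first target, ``all`` keeps every target, ``drop`` discards the
    ambiguous identifier entirely.  Identity conversion (from == to) maps
    every id to itself.  Output order always follows input order.
    """
    if policy not in ("first", "all", "drop"):
        raise ValidationError(f"unknown policy {policy!r}")
    ids = [str(i) for i in ids]
    if from_ns == to_ns:
        n = len(ids)
        return ConversionResult(
            ids=ids,
            outcomes=["mapped"] * n,
            targets=[[i] for i in ids],
            policy=policy,
            counts={"mapped": n, "multi": 0, "unmapped": 0, "dropped": 0},
        )
    if not table.covers(from_ns, to_ns):
        raise CoverageError(
            f"mapping table has no {from_ns} -> {to_ns} pairs"
        )
    lut = table.lookup(from_ns, to_ns)
    outcomes, targets = [], []
    counts = {"mapped": 0, "multi": 0, "unmapped": 0, "dropped": 0}
    for identifier in ids:
        hits = lut.get(identifier)
        if not hits:
            outcomes.append("unmapped")
            targets.append(None)
            counts["unmapped"] += 1
        elif len(hits) == 1:
            outcomes.append("mapped")
            targets.append(hits)
            counts["mapped"] += 1
        elif policy == "drop":
            outcomes.append("dropped")
            targets.append(None)
            counts["dropped"] += 1
        else:
            outcomes.append("multi")
            targets.append(hits)
            counts["multi"] += 1
    return ConversionResult(
        ids=ids, outcomes=outcomes, targets=targets, policy=policy, counts=counts
    )


def annotate_matrix(
    m: ExpressionMatrix, table: MappingTable, policy: str = "first"
) -> ExpressionMatrix:
    """Attach labels in all five namespaces to each matrix row.

    The matrix namespace is detected if not already declared.  Unresolvable
    targets are left missing (pd.NA), never invented.  The label for the
    source namespace is the row's own identifier.
    """
    ns = m.namespace or detect_namespace(m.protein_ids)[0]
    base_ids = [pid.split("#")[0] for pid in m.protein_ids]  # undo dup suffix
    labels = pd.DataFrame(index=m.values.index)
    for target in NAMESPACES:
        if target == ns:
            labels[target] = base_ids
            continue
        if not table.covers(ns, target):
            labels[target] = pd.NA
            continue
        result = convert(base_ids, ns, target, table, policy=policy)
        labels[target] = [result.mapping()[pid] for pid in base_ids]
    return ExpressionMatrix(
        values=m.values, namespace=ns, duplicates=m.duplicates, labels=labels
    )
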