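"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a label-free proteomics experiment on the log2
scale: per-protein baselines, optional per-subject random effects (repeated
measures), a condition effect on a chosen fraction of proteins, Gaussian
residual noise, and missing values from a completely-at-random component
plus an intensity-dependent logistic dropout.  Around the expression data
it builds a matched pathway database (forest-of-DAGs hierarchy, one pathway
spiked with the differentially abundant proteins), a STRING-style
interaction network with elevated within-pathway density, and a five-way
identifier mapping table — everything the real pipeline consumes, with the
truth recorded.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .errors import ParameterError
from .identifiers import (
    ENSEMBL_GENE,
    ENSEMBL_PROTEIN,
    ENTREZ_GENE,
    GENE_SYMBOL,
    NAMESPACES,
    UNIPROT_ACCESSION,
    MappingTable,
)
from .io import DatabaseRelease
from .network import InteractionNetwork
from .pathways import PathwayDB


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic experiment.

    Defaults describe a desk-scale label-free study: 1500 proteins over two
    conditions of six samples each, 10% of proteins shifted by 1 log2 unit
    (twice the residual standard deviation), 5% random missingness plus
    intensity-dependent dropout, and 50 pathways in a three-level hierarchy
    with one pathway carrying most of the affected proteins.
    """

    n_proteins: int = 1500
    n_per_condition: int = 6
    paired: bool = False
    n_subjects: int = 6  # used when paired
    frac_de: float = 0.10
    effect_size: float = 1.0  # log2 units
    residual_sd: float = 0.5
    variance_prior_df: float = 4.0  # spread of per-protein variances (inf = constant)
    subject_sd: float = 1.0  # between-subject spread (paired mode)
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    mcar_rate: float = 0.05
    dropout_amplitude: float = 0.10  # intensity-dependent component, max prob
    dropout_scale: float = 1.0
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (5, 40)
    hierarchy_depth: int = 3
    spike_concentration: float = 0.8  # fraction of DE proteins in the spiked pathway
    p_within: float = 0.25  # interaction probability inside a pathway
    p_background: float = 0.01
    score_range: tuple[int, int] = (150, 999)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "mcar_rate", "dropout_amplitude",
                     "spike_concentration", "p_within", "p_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1 or self.n_per_condition < 1:
            raise ParameterError("sizes must be >= 1")
        if self.frac_de > 0 and int(round(self.frac_de * self.n_proteins)) < 1:
            raise ParameterError("frac_de > 0 needs at least one DE protein")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi <= self.n_proteins:
            raise ParameterError("infeasible pathway size range")


def _rng(spec: SimulationSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, salt])


def protein_ids(spec: SimulationSpec) -> list[str]:
    return [f"P{i:05d}" for i in range(1, spec.n_proteins + 1)]


def de_protein_ids(spec: SimulationSpec) -> list[str]:
    """The differentially abundant subset, deterministic given the seed."""
    ids = protein_ids(spec)
    n_de = int(round(spec.frac_de * spec.n_proteins))
    if n_de == 0:
        return []
    picks = _rng(spec, salt=11).choice(spec.n_proteins, size=n_de, replace=False)
    return [ids[i] for i in sorted(picks)]


def simulate_expression(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame]:
    """Expression matrix + design + exact truth table.

    Signal model per protein g, sample j: baseline_g (+ subject effect in
    paired mode) + effect_g * 1[j in condition B] + N(0, sd_g^2);
    effect_g = +-effect_size for the DE subset (sign random), 0 otherwise.
    Per-protein variances sd_g^2 are scaled inverse-chi-square around
    residual_sd^2 with ``variance_prior_df`` degrees of freedom — the
    heterogeneity the moderated-t prior describes — or constant when that
    df is infinite.
    """
    rng = _rng(spec, salt=23)
    ids = protein_ids(spec)
    de_ids = set(de_protein_ids(spec))
    n_per = spec.n_subjects if spec.paired else spec.n_per_condition
    samples = [f"S{c}{i + 1:02d}" for c in ("A", "B") for i in range(n_per)]
    conditions = ["A"] * n_per + ["B"] * n_per
    subjects = None
    if spec.paired:
        subjects = [f"subj{i + 1:02d}" for i in range(n_per)] * 2
    design = SampleDesign(samples=samples, conditions=conditions, subjects=subjects)

    G, S = spec.n_proteins, len(samples)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    signs = rng.choice([-1.0, 1.0], size=G)
    effect = np.array(
        [spec.effect_size * signs[i] if ids[i] in de_ids else 0.0 for i in range(G)]
    )
    if np.isfinite(spec.variance_prior_df) and spec.variance_prior_df > 0:
        d0 = spec.variance_prior_df
        sd_g = spec.residual_sd * np.sqrt(d0 / rng.chisquare(d0, size=G))
    else:
        sd_g = np.full(G, spec.residual_sd)
    X = baseline[:, None] + rng.normal(0.0, 1.0, size=(G, S)) * sd_g[:, None]
    in_b = np.array([c == "B" for c in conditions])
    X[:, in_b] += effect[:, None]
    if spec.paired:
        subj_effect = rng.normal(0.0, spec.subject_sd, size=(G, n_per))
        for j, s in enumerate(samples):
            X[:, j] += subj_effect[:, j % n_per]

    # missingness: MCAR + logistic intensity-dependent dropout
    miss_p = np.full((G, S), spec.mcar_rate)
    midpoint = spec.baseline_mean - 2.0 * spec.baseline_sd
    miss_p += spec.dropout_amplitude / (
        1.0 + np.exp((X - midpoint) / max(spec.dropout_scale, 1e-9))
    )
    mask = rng.random(size=(G, S)) < miss_p
    values = pd.DataFrame(np.where(mask, np.nan, X), index=ids, columns=samples)
    values.index.name = "protein"

    truth = pd.DataFrame(
        {
            "id": ids,
            "is_de": [i in de_ids for i in ids],
            "true_effect": effect,
        }
    )
    matrix = ExpressionMatrix(values=values, namespace=UNIPROT_ACCESSION)
    return matrix, design, truth


def simulate_pathway_db(spec: SimulationSpec) -> tuple[PathwayDB, str]:
    """Pathway database with a known hierarchy and one spiked pathway.

    The hierarchy is a forest of DAGs of the requested depth (level-0 nodes
    are roots; deeper pathways draw one or two parents from the level
    above).  Memberships are uniform draws within the size range, except the
    spiked pathway, whose membership is ``spike_concentration`` of the DE
    proteins plus a 20% complement of unaffected proteins.  Returns the
    database and the spiked pathway id.
    """
    rng = _rng(spec, salt=37)
    ids = protein_ids(spec)
    de_ids = de_protein_ids(spec)
    n_pw = spec.n_pathways
    pw_ids = [f"PW{i:04d}" for i in range(1, n_pw + 1)]
    depth = max(1, spec.hierarchy_depth)
    levels = [int(i * depth / n_pw) for i in range(n_pw)]  # roughly even levels
    edges: list[tuple[str, str]] = []
    by_level: dict[int, list[str]] = {}
    for pw, lv in zip(pw_ids, levels):
        by_level.setdefault(lv, []).append(pw)
    for lv in range(1, depth):
        parents = by_level.get(lv - 1, [])
        for pw in by_level.get(lv, []):
            if not parents:
                continue
            k = int(rng.integers(1, min(2, len(parents)) + 1))
            chosen = rng.choice(len(parents), size=k, replace=False)
            edges.extend((parents[c], pw) for c in sorted(chosen))

    lo, hi = spec.pathway_size_range
    spiked = pw_ids[-1]  # a leaf-level pathway
    records = []
    non_de = [i for i in ids if i not in set(de_ids)]
    for pw in pw_ids:
        if pw == spiked and de_ids:
            n_spike = max(1, int(round(spec.spike_concentration * len(de_ids))))
            members = list(
                np.asarray(de_ids)[
                    sorted(rng.choice(len(de_ids), size=n_spike, replace=False))
                ]
            )
            n_pad = max(0, int(round(0.2 * n_spike)))
            if n_pad and non_de:
                pad = rng.choice(len(non_de), size=min(n_pad, len(non_de)),
                                 replace=False)
                members += [non_de[i] for i in sorted(pad)]
        else:
            size = int(rng.integers(lo, hi + 1))
            picks = rng.choice(spec.n_proteins, size=size, replace=False)
            members = [ids[i] for i in sorted(picks)]
        for m in members:
            records.append((m, pw, f"Synthetic pathway {pw}", "Homo sapiens"))
    frame = pd.DataFrame(
        records, columns=["protein_id", "pathway_id", "pathway_name", "species"]
    )
    db = PathwayDB.from_records(frame, relations=edges,
                                version_tag=f"synthetic-{spec.seed}")
    return db, spiked


def simulate_interactions(
    spec: SimulationSpec, db: PathwayDB | None = None
) -> InteractionNetwork:
    """STRING-style network with elevated density inside pathways.

    Background edges are drawn G(n, p_background) over all proteins; each
    pathway additionally receives member-member edges with probability
    p_within.  Combined scores are uniform integers in ``score_range``.
    """
    rng = _rng(spec, salt=53)
    ids = protein_ids(spec)
    index = {p: i for i, p in enumerate(ids)}
    if db is None:
        db, _ = simulate_pathway_db(spec)
    lo, hi = spec.score_range

    chosen: set[tuple[int, int]] = set()
    if spec.p_background > 0:
        n = spec.n_proteins
        n_pairs = n * (n - 1) // 2
        n_draw = rng.binomial(n_pairs, spec.p_background)
        flat = rng.choice(n_pairs, size=n_draw, replace=False)
        iu_rows, iu_cols = np.triu_indices(n, k=1)
        chosen.update(zip(iu_rows[flat].tolist(), iu_cols[flat].tolist()))
    for pw in sorted({p for s in db.annotations.values() for p in s}):
        members = sorted(db.members(pw))
        idx = [index[m] for m in members if m in index]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if rng.random() < spec.p_within:
                    i, j = sorted((idx[a], idx[b]))
                    chosen.add((i, j))
    edges = [
        (ids[i], ids[j], float(rng.integers(lo, hi + 1)))
        for i, j in sorted(chosen)
    ]
    return InteractionNetwork.from_edges(edges, nodes=ids)


def simulate_mapping_table(spec: SimulationSpec) -> MappingTable:
    """Bijective five-namespace mapping for the synthetic proteins."""
    ids = protein_ids(spec)
    per_ns = {
        UNIPROT_ACCESSION: ids,
        GENE_SYMBOL: [f"GENE{i}" for i in range(1, spec.n_proteins + 1)],
        ENSEMBL_GENE: [f"ENSG{i:011d}" for i in range(1, spec.n_proteins + 1)],
        ENSEMBL_PROTEIN: [f"ENSP{i:011d}" for i in range(1, spec.n_proteins + 1)],
        ENTREZ_GENE: [str(i) for i in range(1, spec.n_proteins + 1)],
    }
    rows = []
    for src in NAMESPACES:
        for dst in NAMESPACES:
            if src == dst:
                continue
            rows.extend(
                (src, a, dst, b) for a, b in zip(per_ns[src], per_ns[dst])
            )
    pairs = pd.DataFrame(
        rows, columns=["source_ns", "source_id", "target_ns", "target_id"]
    )
    return MappingTable(pairs, provenance=f"synthetic-{spec.seed}")


@dataclass
class FixtureSet:
    """Paths of all written fixture files plus ground truth."""

    expression: str
    design: str
    annotations: str
    relations: str
    interactions: str
    mapping: str
    truth: str
    release: str
    spiked_pathway: str
    spec: SimulationSpec = field(repr=False, default=None)


def write_fixture_files(spec: SimulationSpec, outdir) -> FixtureSet:
    """Generate every input file the pipeline consumes, in its native dialect."""
    os.makedirs(outdir, exist_ok=True)
    matrix, design, truth = simulate_expression(spec)
    db, spiked = simulate_pathway_db(spec)
    net = simulate_interactions(spec, db)
    mapping = simulate_mapping_table(spec)

    paths = {k: os.path.join(outdir, v) for k, v in {
        "expression": "expression.tsv",
        "design": "design.tsv",
        "annotations": "annotations.tsv",
        "relations": "relations.tsv",
        "interactions": "interactions.tsv",
        "mapping": "mapping.tsv",
        "truth": "truth.tsv",
        "release": "release.json",
    }.items()}

    matrix.values.to_csv(paths["expression"], sep="\t", na_rep="")
    design.to_frame().to_csv(paths["design"], sep="\t", index=False)
    records = []
    names = db.pathway_names()
    for prot in sorted(db.annotations):
        for pw in sorted(db.annotations[prot]):
            records.append((prot, pw, names[pw], "Homo sapiens"))
    with open(paths["annotations"], "w") as fh:
        for rec in records:
            fh.write("\t".join(rec) + "\n")
    with open(paths["relations"], "w") as fh:
        for parent, child in db.hierarchy:
            fh.write(f"{parent}\t{child}\n")
    with open(paths["interactions"], "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, s in sorted(net.edges_with_scores()):
            fh.write(f"{a} {b} {int(s)}\n")
    mapping.to_tsv(paths["mapping"])
    truth.to_csv(paths["truth"], sep="\t", index=False)

    release = {
        "pathway": DatabaseRelease.from_files(
            "pathway", f"synthetic-{spec.seed}",
            [paths["annotations"], paths["relations"]],
        ),
        "interaction": DatabaseRelease.from_files(
            "interaction", f"synthetic-{spec.seed}", [paths["interactions"]]
        ),
    }
    with open(paths["release"], "w") as fh:
        json.dump(
            {k: {"source_name": r.source_name, "version_tag": r.version_tag,
                 "file_digests": r.file_digests} for k, r in release.items()},
            fh, indent=2,
        )
    return FixtureSet(spiked_pathway=spiked, spec=spec, **paths)
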