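"""Quality control: missing-value filtering and (multilevel) PCA.

PCA treats samples as observations and proteins as variables, computed by
singular value decomposition of the column-centered (optionally unit-scaled)
matrix — the classical prcomp contract.  Multilevel PCA handles repeated
measures by first removing between-subject variation: each sample is
replaced by its deviation from its subject's mean profile (the split-up
variation decomposition), and ordinary PCA runs on those deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .errors import DesignError, ParameterError, ValidationError


@dataclass
class FilterReport:
    removed: list[str]
    n_kept: int
    n_removed: int
    cutoff: float
    scope: str


def filter_missing(
    m: ExpressionMatrix,
    cutoff: float,
    scope: str = "overall",
    design: SampleDesign | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop proteins exceeding the missing-value cutoff.

    ``scope="overall"``: keep a protein iff its missing fraction across all
    samples is <= cutoff.  ``scope="per_group"``: keep iff the missing
    fraction is <= cutoff within at least one condition group (the protein
    is quantifiable somewhere); requires a design.  Idempotent.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError(f"cutoff must be in [0, 1], got {cutoff}")
    if scope not in ("overall", "per_group"):
        raise ParameterError(f"unknown scope {scope!r}")
    mask = m.mask
    if scope == "overall":
        keep = mask.mean(axis=1) <= cutoff
    else:
        if design is None:
            raise ParameterError("per_group filtering needs a sample design")
        frames = []
        for _, samples in design.groups().items():
            frames.append(mask[samples].mean(axis=1) <= cutoff)
        keep = pd.concat(frames, axis=1).any(axis=1)
    kept = m.values.loc[keep]
    removed = [pid for pid, k in keep.items() if not k]
    report = FilterReport(
        removed=removed,
        n_kept=int(keep.sum()),
        n_removed=len(removed),
        cutoff=cutoff,
        scope=scope,
    )
    out = ExpressionMatrix(
        values=kept,
        namespace=m.namespace,
        duplicates=m.duplicates,
        labels=m.labels.loc[keep] if m.labels is not None else None,
    )
    return out, report


def complete_cases(m: ExpressionMatrix) -> ExpressionMatrix:
    """Restrict to proteins quantified in every sample (PCA prerequisite)."""
    filtered, _ = filter_missing(m, cutoff=0.0, scope="overall")
    return filtered


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA.

    ``scores`` is samples x components, ``loadings`` proteins x components;
    ``scores @ loadings.T`` reconstructs the centered (and scaled) data when
    all components are kept.  Explained-variance fractions are non-increasing
    and sum to 1 over the full rank.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    m: ExpressionMatrix,
    center: bool = True,
    scale: bool = False,
    k: int | None = None,
) -> PCAResult:
    """Classical PCA of samples over protein variables via SVD.

    Requires a complete matrix (run :func:`filter_missing` with cutoff 0 or
    :func:`complete_cases` first).  The sign of each component is fixed by
    forcing its largest-magnitude loading positive, so output is
    reproducible across linear-algebra backends.
    """
    if not m.is_complete():
        raise ValidationError(
            "matrix has missing cells; filter to complete cases before PCA "
            "(filter_missing with cutoff=0.0)"
        )
    X = m.values.to_numpy().T  # samples x proteins
    n_samples, n_proteins = X.shape
    max_k = min(n_samples, n_proteins)
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ParameterError(f"k must be in [1, {max_k}], got {k}")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S**2).sum())
    ratios = (S**2) / total if total > 0 else np.zeros_like(S)

    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=m.protein_ids, columns=comp_names),
        explained_variance_ratio=ratios[:k],
    )


def within_subject_deviations(
    m: ExpressionMatrix, design: SampleDesign
) -> ExpressionMatrix:
    """Subtract each subject's mean profile from its samples.

    Removes all between-subject variation: adding any constant per-subject
    shift to the input leaves the result unchanged, and each subject's
    deviations sum to zero.  Every subject needs >= 2 samples.
    """
    if not design.has_subjects:
        raise DesignError("multilevel analysis needs subject ids in the design")
    subj = design.subject_map()
    counts: dict[str, int] = {}
    for s in m.sample_ids:
        counts[subj[s]] = counts.get(subj[s], 0) + 1
    singletons = sorted(k for k, v in counts.items() if v < 2)
    if singletons:
        raise DesignError(
            f"subjects with a single sample cannot be centered: {singletons}"
        )
    vals = m.values.copy()
    groups = pd.Series({s: subj[s] for s in m.sample_ids})
    centered = vals.sub(vals.T.groupby(groups).transform("mean").T)
    return ExpressionMatrix(values=centered, namespace=m.namespace)


def run_multilevel_pca(
    m: ExpressionMatrix,
    design: SampleDesign,
    center: bool = True,
    scale: bool = False,
    k: int | None = None,
) -> PCAResult:
    """PCA on the within-subject deviation matrix (repeated-measures QC)."""
    within = within_subject_deviations(m, design)
    return run_pca(within, center=center, scale=scale, k=k)
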