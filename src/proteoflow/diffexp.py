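"""Two-contrast differential expression with empirical-Bayes moderated t.

Per protein, an ordinary linear-model fit gives the effect (log2 fold change
of condition B over A), the residual variance s2_g and its degrees of
freedom d_g.  Residual variances are then shrunk toward a common prior by
empirical Bayes: the prior (d0, s0^2) is estimated by closed-form
method-of-moments on log s2 (digamma/trigamma matching), the posterior
variance is

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t-statistic effect / (s~_g * sqrt(v_g)) is referred to a
t-distribution with d0 + d_g degrees of freedom.  Multiple testing is
controlled by Benjamini-Hochberg step-up FDR within the run.

Input abundances are assumed to be log2-transformed already.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, SampleDesign
from .errors import DegenerateVarianceError, DesignError, ParameterError


@dataclass
class ContrastSpec:
    """A two-condition contrast (B vs A), paired or unpaired."""

    condition_a: str
    condition_b: str
    paired: bool = False

    def validate(self, design: SampleDesign) -> None:
        if self.condition_a == self.condition_b:
            raise DesignError("contrast conditions must differ")
        groups = design.groups()
        for label in (self.condition_a, self.condition_b):
            if label not in groups:
                raise DesignError(f"condition {label!r} absent from the design")
        if self.paired:
            if not design.has_subjects:
                raise DesignError("paired contrast needs subject ids")
            subj = design.subject_map()
            a_subjects = sorted(subj[s] for s in groups[self.condition_a])
            b_subjects = sorted(subj[s] for s in groups[self.condition_b])
            if a_subjects != b_subjects or len(set(a_subjects)) != len(a_subjects):
                raise DesignError(
                    "paired design requires subjects matched 1:1 across conditions"
                )


@dataclass
class DEResult:
    """Differential-expression table plus the global eB hyperparameters."""

    table: pd.DataFrame  # id, logFC, s2, df_resid, t, df_total, p, p_adj, flagged
    d0: float  # prior degrees of freedom
    s0_2: float  # prior variance
    contrast: ContrastSpec


def fit_linear_models(
    m: ExpressionMatrix, design: SampleDesign, contrast: ContrastSpec
) -> pd.DataFrame:
    """Per-protein effect, residual variance and residual df.

    Unpaired: effect = mean(B) - mean(A), s2 = pooled two-group residual
    variance, d_g = nA + nB - 2, scale v_g = 1/nA + 1/nB.  Paired: effect =
    mean of per-subject differences, s2 = variance of those differences,
    d_g = n_pairs - 1, v_g = 1/n_pairs.  All computed on the non-missing
    observations per protein; proteins with d_g < 1 or a condition entirely
    missing are flagged not-testable instead of failing the run.
    """
    contrast.validate(design)
    groups = design.groups()
    a_samples = groups[contrast.condition_a]
    b_samples = groups[contrast.condition_b]
    vals = m.values
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # all-missing rows legitimately produce empty-slice means (-> nan)
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        if contrast.paired:
            subj = design.subject_map()
            by_subject: dict[str, list] = {}
            for s in a_samples:
                by_subject.setdefault(subj[s], [None, None])[0] = s
            for s in b_samples:
                by_subject.setdefault(subj[s], [None, None])[1] = s
            A = vals[[sa for sa, _ in by_subject.values()]].to_numpy()
            B = vals[[sb for _, sb in by_subject.values()]].to_numpy()
            D = B - A  # nan where either member missing
            n = np.sum(~np.isnan(D), axis=1)
            effect = np.nanmean(D, axis=1)
            mean = effect[:, None]
            ss = np.nansum((D - mean) ** 2, axis=1)
            testable = n >= 2
            d_g = np.where(testable, n - 1, 0)
            s2 = np.where(testable, ss / np.maximum(n - 1, 1), np.nan)
            v = np.where(testable, 1.0 / np.maximum(n, 1), np.nan)
            n_obs = n
        else:
            A = vals[a_samples].to_numpy()
            B = vals[b_samples].to_numpy()
            na = np.sum(~np.isnan(A), axis=1)
            nb = np.sum(~np.isnan(B), axis=1)
            mean_a = np.nanmean(A, axis=1) if A.size else np.zeros(len(vals))
            mean_b = np.nanmean(B, axis=1) if B.size else np.zeros(len(vals))
            ss = (np.nansum((A - mean_a[:, None]) ** 2, axis=1)
                  + np.nansum((B - mean_b[:, None]) ** 2, axis=1))
            d_g_raw = na + nb - 2
            testable = (na >= 1) & (nb >= 1) & (d_g_raw >= 1)
            effect = mean_b - mean_a
            d_g = np.where(testable, d_g_raw, 0)
            s2 = np.where(testable, ss / np.maximum(d_g_raw, 1), np.nan)
            v = np.where(
                testable,
                1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1),
                np.nan,
            )
            n_obs = na + nb
    effect = np.where(testable, effect, np.nan)
    return pd.DataFrame({
        "id": vals.index,
        "effect": effect,
        "s2": s2,
        "df_resid": d_g.astype(int),
        "v": v,
        "n_obs": n_obs.astype(int),
        "testable": testable,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# empirical Bayes hyperparameter estimation (method of moments on log s2)
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges for any
    positive y (large y -> small x ~ 1/y, small y -> x ~ 1/y as well since
    trigamma(x) ~ 1/x for large x).
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from scaled-chi^2 variances.

    Under s2_g ~ s0^2 * chi^2_{d_g}/d_g * F-mixing with prior df d0,
    e_g = log s2_g - digamma(d_g/2) + log(d_g/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2)
    beyond the known trigamma(d_g/2) sampling term; matching the first two
    moments gives closed-form estimates.  Infinite d0 (all variances equal)
    is returned when the excess variance is non-positive.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    s2, df = np.asarray(s2[ok], dtype=float), np.asarray(df[ok], dtype=float)
    if len(s2) < 2:
        raise DegenerateVarianceError(
            "need >=2 proteins with positive residual variance to moderate"
        )
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_2 = math.exp(emean)
    return d0, s0_2


def posterior_variance(
    s2: np.ndarray, df: np.ndarray, d0: float, s0_2: float
) -> np.ndarray:
    """Shrink each s2_g toward s0^2: (d0*s0^2 + d_g*s2_g)/(d0 + d_g)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if math.isinf(d0):
        return np.full_like(s2, s0_2)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0_2 + df * s2) / (d0 + df)


def ebayes_moderate(
    fits: pd.DataFrame, d0: float | None = None, s0_2: float | None = None
) -> tuple[pd.DataFrame, float, float]:
    """Moderated t-statistics and two-sided p-values for a fit table.

    Hyperparameters are estimated from the testable proteins unless supplied
    (supplying d0=0 reduces the moderated t to the ordinary t exactly).
    Returns (table with t/df_total/p columns, d0, s0_2).
    """
    out = fits.copy()
    testable = out["testable"].to_numpy()
    s2 = out["s2"].to_numpy(dtype=float)
    df = out["df_resid"].to_numpy(dtype=float)
    if d0 is None or s0_2 is None:
        if not np.any(testable & np.isfinite(s2) & (s2 > 0)):
            raise DegenerateVarianceError("all residual variances are zero")
        est_d0, est_s0 = estimate_prior(s2[testable], df[testable])
        d0 = est_d0 if d0 is None else d0
        s0_2 = est_s0 if s0_2 is None else s0_2
    s2_post = posterior_variance(s2, df, d0, s0_2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * out["v"].to_numpy(dtype=float))
        t = out["effect"].to_numpy(dtype=float) / se
    df_total = df + (0.0 if math.isinf(d0) else d0)
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero posterior variance with nonzero effect -> infinitely confident
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(np.isnan(t) & testable, 1.0, p)
    out["s2_post"] = s2_post
    out["t"] = t
    out["df_total"] = np.where(testable, df_total, np.nan)
    out["p"] = np.where(testable, p, np.nan)
    return out, float(d0), float(s0_2)


def adjust_bh(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by a
    cumulative minimum from the largest rank down, cap at 1.  NaNs pass
    through and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def run_differential_expression(
    m: ExpressionMatrix,
    design: SampleDesign,
    contrast: ContrastSpec,
    d0_override: float | None = None,
) -> DEResult:
    """Full moderated-t differential expression for one contrast.

    The result table is sorted by raw p ascending, ties broken by |logFC|
    descending then identifier; not-testable proteins sink to the bottom
    flagged, with NaN statistics.
    """
    fits = fit_linear_models(m, design, contrast)
    moderated, d0, s0_2 = ebayes_moderate(fits, d0=d0_override)
    moderated["p_adj"] = adjust_bh(moderated["p"].to_numpy())
    table = moderated.rename(columns={"effect": "logFC"})
    table["flagged"] = ~table["testable"]
    table = table.sort_values(
        by=["p", "logFC", "id"],
        key=lambda col: -col.abs() if col.name == "logFC" else col,
        na_position="last",
    ).reset_index(drop=True)
    cols = ["id", "logFC", "t", "df_total", "p", "p_adj", "s2", "df_resid", "flagged"]
    return DEResult(table=table[cols], d0=d0, s0_2=s0_2, contrast=contrast)


def significant_proteins(
    result: DEResult, threshold: float = 0.05, direction: str = "both"
) -> list[str]:
    """Query list for enrichment: BH-adjusted p below threshold.

    ``direction`` may restrict to "up" (logFC > 0) or "down" (logFC < 0).
    """
    t = result.table
    sel = t["p_adj"] < threshold
    if direction == "up":
        sel &= t["logFC"] > 0
    elif direction == "down":
        sel &= t["logFC"] < 0
    elif direction != "both":
        raise ParameterError(f"unknown direction {direction!r}")
    return list(t.loc[sel.fillna(False), "id"])
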