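"""Simplified negative-binomial differential expression for two-group contrasts.

This engine provides the pieces the localization statistic needs from a
DESeq2-style analysis — median-of-ratios size factors, count filtering, and a
per-feature two-group NB Wald test emitting (log2fc, SE, Wald, p, q) — without
shrinkage, Cook's filtering, or multi-factor GLMs. Externally produced
(log2fc, se) tables can be substituted downstream; only those two columns are
consumed by the mislocalization stage.

Model per feature: normalized counts y = count / size_factor; group means
mu_A, mu_B; a pooled method-of-moments dispersion alpha (variance
mu + alpha*mu^2, floored at 1e-8); log2fc = log2((mu_B + c)/(mu_A + c)) with
pseudo-count c = 0.5 / geometric mean size factor; SE by the delta method
from the NB variance of the group means; Wald = log2fc / SE with two-sided
Student-t p (nA + nB - 2 df, reflecting the degrees of freedom behind the
dispersion estimate) and Benjamini-Hochberg q.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountDataset

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "se", "wald", "p", "q"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def estimate_size_factors(
    ds: CountDataset, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    The reference profile is the per-feature geometric mean over samples,
    computed only over features with no zero count in any sample; each
    sample's size factor is the median ratio of its counts to the reference.

    When no feature is nonzero in every sample the default is a hard error;
    ``allow_pseudo_reference=True`` instead computes the geometric mean over
    positive counts only (a "positive counts" fallback).
    """
    counts = ds.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no feature has nonzero counts in every sample; pass "
                "allow_pseudo_reference=True to use a positive-count reference"
            )
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), np.nan)
        ref = np.exp(np.nanmean(logc, axis=1))
        use = ~np.isnan(ref) & (ref > 0)
    else:
        sub = counts[all_positive]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        counts = sub
        use = np.ones(len(ref), dtype=bool)
    ratios = counts[use] / ref[use, None]
    with np.errstate(invalid="ignore"):
        sf = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factor estimation produced non-positive factors")
    return pd.Series(sf, index=ds.counts.columns, name="size_factor")


def filter_features(
    ds: CountDataset, min_count: int, min_samples: int
) -> CountDataset:
    """Keep features with >= min_count counts in at least min_samples samples.

    Order is preserved. Thresholds are inclusive: a feature with exactly
    min_count in exactly min_samples samples is kept.
    """
    if min_count < 1 or min_samples < 1:
        raise ValueError("filter thresholds must be >= 1")
    keep = (ds.counts.to_numpy() >= min_count).sum(axis=1) >= min_samples
    return ds.subset_features(ds.counts.index[keep])


def _pooled_dispersion(
    yA: np.ndarray, yB: np.ndarray, inv_sf_mean: float
) -> np.ndarray:
    """Per-feature method-of-moments dispersion pooled across the two groups.

    Within each group the sample variance of normalized counts estimates
    approximately mu*mean(1/sf) + alpha*mu^2; the shot-noise term is
    subtracted and the two group estimates are pooled by degrees of freedom.
    """
    nA, nB = yA.shape[1], yB.shape[1]
    muA, muB = yA.mean(axis=1), yB.mean(axis=1)
    varA = yA.var(axis=1, ddof=1)
    varB = yB.var(axis=1, ddof=1)
    pooled_var = ((nA - 1) * varA + (nB - 1) * varB) / (nA + nB - 2)
    pooled_mu = (nA * muA + nB * muB) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mu * inv_sf_mean) / pooled_mu**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def two_group_de(
    ds: CountDataset,
    group_labels: pd.Series,
    contrast: tuple[str, str],
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B versus group A.

    Parameters
    ----------
    group_labels
        Series indexed by sample id giving each sample's group.
    contrast
        (B, A): log2 fold changes are B over A.
    size_factors
        Per-sample positive reals; estimated by median-of-ratios if omitted.

    Returns a DataFrame with columns feature_id, base_mean, log2fc, se, wald,
    p, q (BH), one row per feature in input order.
    """
    b_level, a_level = contrast
    labels = group_labels.reindex(ds.counts.columns)
    a_samples = list(labels.index[labels == a_level])
    b_samples = list(labels.index[labels == b_level])
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"each group needs >= 2 samples; got {len(b_samples)} in "
            f"{b_level!r} and {len(a_samples)} in {a_level!r}"
        )
    if size_factors is None:
        size_factors = estimate_size_factors(ds.subset_samples(a_samples + b_samples))
    sf = size_factors.reindex(a_samples + b_samples).astype(float)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive for every sample used")

    y = ds.counts[a_samples + b_samples].to_numpy(dtype=float) / sf.to_numpy()
    yA = y[:, : len(a_samples)]
    yB = y[:, len(a_samples) :]
    sfA = sf.to_numpy()[: len(a_samples)]
    sfB = sf.to_numpy()[len(a_samples) :]
    nA, nB = len(a_samples), len(b_samples)

    muA = yA.mean(axis=1)
    muB = yB.mean(axis=1)
    base_mean = y.mean(axis=1)

    c = 0.5 / stats.gmean(sf.to_numpy())
    inv_sf_mean = float(np.mean(1.0 / sf.to_numpy()))
    alpha = _pooled_dispersion(yA, yB, inv_sf_mean)

    # difference of logs (not log of ratio) so contrast swap negates exactly
    log2fc = np.log2(muB + c) - np.log2(muA + c)

    # delta method: Var(muhat_g) = (1/n^2) sum_s (mu_g/sf_s + alpha mu_g^2)
    varA = (muA[:, None] / sfA[None, :] + alpha[:, None] * muA[:, None] ** 2).sum(
        axis=1
    ) / nA**2
    varB = (muB[:, None] / sfB[None, :] + alpha[:, None] * muB[:, None] ** 2).sum(
        axis=1
    ) / nB**2
    se = np.sqrt(varB / (muB + c) ** 2 + varA / (muA + c) ** 2) / LN2

    # degenerate guard: a feature with zero counts in both groups
    dead = (muA == 0) & (muB == 0)
    se = np.where(dead | (se == 0), 1.0, se)
    log2fc = np.where(dead, 0.0, log2fc)

    wald = log2fc / se
    # SE rests on a dispersion estimated from nA + nB - 2 residual df, so the
    # Wald statistic is t-like in small samples; normal tails would run ~8%
    # at the nominal 5% level for n = 6 per group.
    p = 2.0 * stats.t.sf(np.abs(wald), df=nA + nB - 2)
    p = np.where(dead, 1.0, p)
    q = bh_adjust(p)

    return pd.DataFrame(
        {
            "feature_id": ds.counts.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "q": q,
        }
    )


def overlap_concordance(
    deA: pd.DataFrame, deB: pd.DataFrame, alpha: float
) -> dict:
    """Overlap of significant features between two DE tables and the percent
    with the same log2fc sign.

    Significance is raw p < alpha in each table. Returns a dict with keys
    n_sig_A, n_sig_B, n_overlap, pct_concordant_sign (NaN when the overlap
    is empty).
    """
    a = deA.set_index("feature_id")
    b = deB.set_index("feature_id")
    sig_a = set(a.index[a["p"] < alpha])
    sig_b = set(b.index[b["p"] < alpha])
    overlap = sorted(sig_a & sig_b)
    if overlap:
        same = sum(
            1
            for f in overlap
            if np.sign(a.loc[f, "log2fc"]) == np.sign(b.loc[f, "log2fc"])
        )
        pct = 100.0 * same / len(overlap)
    else:
        pct = float("nan")
    return {
        "n_sig_A": len(sig_a),
        "n_sig_B": len(sig_b),
        "n_overlap": len(overlap),
        "pct_concordant_sign": pct,
    }
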