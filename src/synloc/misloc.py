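"""Mislocalization statistics for fraction-by-condition interaction effects.

A transcript is mislocalized when its case-vs-control fold change in the
synaptosome fraction differs from its fold change in the bulk homogenate —
a fraction x condition interaction. The statistic compares the two contrasts
per feature:

    misloc_lfc = lfc_syn - lfc_hom                (log2 of the ratio of ratios)
    rw         = lfc_syn/se_syn - lfc_hom/se_hom  (difference of Wald statistics)
    T_i        = rw_i / sqrt( (sum_j rw_j^2 / G) / N )

where G is the number of features tested and N the number of samples that
contributed to both contrasts. The denominator is the root-mean-square of rw
shrunk by sqrt(N), so T is invariant to a global rescaling of rw. Two-tailed
p-values come from a Student t with N-1 degrees of freedom by default (the
``normal`` option uses standard normal tails instead); q-values are
Benjamini-Hochberg, and features are classed up/down/ns by the sign of rw at
the chosen FDR cutoff.

Note this standardization scales with sqrt(N): the larger the study, the
larger |T| for the same rw, so the test is anti-conservative in the usual
frequentist sense and is best paired with a stringent FDR cutoff (0.001 by
default). See docs/methods.md for the calibration analysis.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

MISLOC_COLUMNS = [
    "feature_id",
    "lfc_syn",
    "se_syn",
    "lfc_hom",
    "se_hom",
    "misloc_lfc",
    "rw",
    "t",
    "p",
    "q",
    "direction",
]


def misloc_foldchange(lfc_syn, lfc_hom):
    """Mislocalization fold change: log2 of the ratio of the two fold-change
    ratios, i.e. lfc_syn - lfc_hom on the log2 scale."""
    return np.asarray(lfc_syn, dtype=float) - np.asarray(lfc_hom, dtype=float)


def wald_difference(lfc_syn, se_syn, lfc_hom, se_hom):
    """rw = lfc_syn/se_syn - lfc_hom/se_hom.

    Each fold change is weighted by its own standard error, so rw is the
    difference of the two per-feature Wald statistics.
    """
    se_syn = np.asarray(se_syn, dtype=float)
    se_hom = np.asarray(se_hom, dtype=float)
    if np.any(se_syn <= 0) or np.any(se_hom <= 0) or not (
        np.all(np.isfinite(se_syn)) and np.all(np.isfinite(se_hom))
    ):
        raise ValueError("standard errors must be strictly positive and finite")
    return np.asarray(lfc_syn, dtype=float) / se_syn - np.asarray(
        lfc_hom, dtype=float
    ) / se_hom


def misloc_test(
    inputs: pd.DataFrame,
    n_samples: int,
    fdr_cutoff: float = 0.001,
    null_dist: str = "student_t",
) -> pd.DataFrame:
    """Run the mislocalization test over a table of paired contrast results.

    Parameters
    ----------
    inputs
        DataFrame with columns feature_id, lfc_syn, se_syn, lfc_hom, se_hom
        (one row per feature; G = number of rows, must be >= 2).
    n_samples
        N in the T standardization (total samples behind both contrasts).
    fdr_cutoff
        BH FDR threshold for the up/down direction call.
    null_dist
        "student_t" (N-1 df) or "normal" two-tailed p-values.

    Returns a DataFrame with the input columns plus misloc_lfc, rw, t, p, q
    and direction in {"up", "down", "ns"}.
    """
    if null_dist not in ("student_t", "normal"):
        raise ValueError("null_dist must be 'student_t' or 'normal'")
    if len(inputs) < 2:
        raise ValueError("need at least 2 features to standardize the statistic")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")

    lfc_syn = inputs["lfc_syn"].to_numpy(dtype=float)
    se_syn = inputs["se_syn"].to_numpy(dtype=float)
    lfc_hom = inputs["lfc_hom"].to_numpy(dtype=float)
    se_hom = inputs["se_hom"].to_numpy(dtype=float)

    rw = wald_difference(lfc_syn, se_syn, lfc_hom, se_hom)
    G = len(rw)
    denom_sq = (np.sum(rw**2) / G) / n_samples
    if denom_sq == 0.0:
        logger.warning("all rw are zero; returning degenerate t=0, p=1")
        t = np.zeros(G)
        p = np.ones(G)
    else:
        t = rw / np.sqrt(denom_sq)
        if null_dist == "student_t":
            p = 2.0 * stats.t.sf(np.abs(t), df=n_samples - 1)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        # a zero numerator is never evidence of mislocalization
        p = np.where(rw == 0.0, 1.0, p)
    q = bh_adjust(p)

    direction = np.where(
        (q < fdr_cutoff) & (rw > 0),
        "up",
        np.where((q < fdr_cutoff) & (rw < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature_id": inputs["feature_id"].to_numpy(),
            "lfc_syn": lfc_syn,
            "se_syn": se_syn,
            "lfc_hom": lfc_hom,
            "se_hom": se_hom,
            "misloc_lfc": misloc_foldchange(lfc_syn, lfc_hom),
            "rw": rw,
            "t": t,
            "p": p,
            "q": q,
            "direction": direction,
        }
    )


def misloc_from_de_tables(
    de_syn: pd.DataFrame,
    de_hom: pd.DataFrame,
    n_samples: int,
    fdr_cutoff: float = 0.001,
    null_dist: str = "student_t",
) -> pd.DataFrame:
    """Join two case-vs-control DE tables (synaptosome and homogenate
    contrasts) on feature_id and run :func:`misloc_test` on the intersection.
    """
    syn = de_syn.set_index("feature_id")[["log2fc", "se"]]
    hom = de_hom.set_index("feature_id")[["log2fc", "se"]]
    shared = syn.index.intersection(hom.index)
    inputs = pd.DataFrame(
        {
            "feature_id": shared,
            "lfc_syn": syn.loc[shared, "log2fc"].to_numpy(),
            "se_syn": syn.loc[shared, "se"].to_numpy(),
            "lfc_hom": hom.loc[shared, "log2fc"].to_numpy(),
            "se_hom": hom.loc[shared, "se"].to_numpy(),
        }
    )
    return misloc_test(inputs, n_samples, fdr_cutoff, null_dist)
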