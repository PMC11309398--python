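"""miRNA binding-site enrichment in a shortlist of 3'UTRs versus background.

Site counting itself (e.g. TargetScan output) is consumed as precomputed
per-gene tables; this module tests whether each miRNA's share of all binding
sites in a shortlist exceeds its share in a transcriptome-wide background.

For miRNA m with s_m shortlist sites out of S total and b_m background sites
out of B total:

    log2fc = log2( (s_m/S) / (b_m/B) )

with a +0.5 continuity offset on s_m and b_m (flagged) when either is zero,
and significance from a 1-df chi-square on the 2x2 table
[[s_m, S-s_m], [b_m, B-b_m]] without continuity correction (upper tail),
followed by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

ENRICHMENT_COLUMNS = [
    "mirna_id",
    "sites_shortlist",
    "total_shortlist",
    "sites_background",
    "total_background",
    "log2fc",
    "zero_guarded",
    "chi2",
    "p",
    "q",
    "call",
]


def site_totals(table: pd.DataFrame) -> pd.Series:
    """Collapse a gene-by-miRNA site table to per-miRNA totals."""
    totals = table.sum(axis=0).astype(np.int64)
    totals.index.name = "mirna_id"
    return totals


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Pearson chi-square for 2x2 tables [[a, b], [c, d]], no continuity
    correction; degenerate margins give chi2 = 0."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, chi2, 0.0)


def site_enrichment_test(
    shortlist: Union[pd.Series, pd.DataFrame],
    background: Union[pd.Series, pd.DataFrame],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA 2x2 chi-square enrichment of shortlist versus background.

    Parameters
    ----------
    shortlist, background
        Per-miRNA total site counts (Series) or gene-by-miRNA tables
        (collapsed with :func:`site_totals`). Every shortlist miRNA must be
        present in the background. By convention the background is the full
        transcriptome table, shortlist genes included.
    fdr_cutoff
        BH threshold for the enriched/de-enriched call.

    Returns one row per shortlist miRNA with the observed counts, log2 fold
    change of the observed versus expected fraction, chi2, p, q, and a call
    in {"enriched", "de-enriched", "ns"}.
    """
    s = site_totals(shortlist) if isinstance(shortlist, pd.DataFrame) else shortlist
    b = site_totals(background) if isinstance(background, pd.DataFrame) else background
    s = s.astype(np.int64)
    b = b.astype(np.int64)
    missing = sorted(set(s.index) - set(b.index))
    if missing:
        raise ValueError(f"shortlist miRNA(s) absent from background: {missing}")
    b = b.reindex(s.index)
    S = int(s.sum())
    B = int(b.sum())
    if S <= 0 or B <= 0:
        raise ValueError("shortlist and background must each have > 0 total sites")

    sm = s.to_numpy(dtype=float)
    bm = b.to_numpy(dtype=float)
    zero_guard = (sm == 0) | (bm == 0)
    sm_adj = np.where(zero_guard, sm + 0.5, sm)
    bm_adj = np.where(zero_guard, bm + 0.5, bm)
    log2fc = np.log2((sm_adj / S) / (bm_adj / B))

    chi2 = _chi2_2x2(sm, S - sm, bm, B - bm)
    p = stats.chi2.sf(chi2, df=1)
    q = bh_adjust(p)
    call = np.where(
        (q < fdr_cutoff) & (log2fc > 0),
        "enriched",
        np.where((q < fdr_cutoff) & (log2fc < 0), "de-enriched", "ns"),
    )
    return pd.DataFrame(
        {
            "mirna_id": s.index,
            "sites_shortlist": s.to_numpy(),
            "total_shortlist": S,
            "sites_background": b.to_numpy(),
            "total_background": B,
            "log2fc": log2fc,
            "zero_guarded": zero_guard,
            "chi2": chi2,
            "p": p,
            "q": q,
            "call": call,
        }
    )
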