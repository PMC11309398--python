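"""Core in-memory containers shared across the pipeline.

The pipeline operates on a 2x2 factorial bulk RNA-seq design: each sample is a
(Fraction, Condition) combination where Fraction distinguishes the synaptosome
preparation from the unfractionated tissue homogenate, and Condition
distinguishes disease cases from controls.

Coordinate convention: all internal coordinates are 0-based half-open.
Annotation readers convert from 1-based inclusive records at the boundary
(see :func:`to_zero_based` / :func:`to_one_based`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FRACTION_SYNAPTOSOME = "synaptosome"
FRACTION_HOMOGENATE = "homogenate"
CONDITION_CASE = "case"
CONDITION_CONTROL = "control"

FRACTIONS = (FRACTION_SYNAPTOSOME, FRACTION_HOMOGENATE)
CONDITIONS = (CONDITION_CASE, CONDITION_CONTROL)

_VALID_BASES = frozenset("ACGTN")


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive (inverse of
    :func:`to_zero_based`)."""
    return start0 + 1, end0


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript with its exon structure in transcript (5'->3') order.

    ``exons`` holds 0-based half-open genomic intervals ordered so that exon 1
    is the 5'-most exon of the *transcript* regardless of genomic strand.
    ``exon_sequences``, when present, are the sense-strand (transcript
    orientation) sequences, one per exon.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    exon_sequences: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) == 0:
            raise ValueError(f"transcript {self.transcript_id}: empty exon list")
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(
                    f"transcript {self.transcript_id}: bad exon interval ({start}, {end})"
                )
        if self.exon_sequences is not None:
            if len(self.exon_sequences) != len(self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: {len(self.exon_sequences)} "
                    f"exon sequences for {len(self.exons)} exons"
                )
            for i, seq in enumerate(self.exon_sequences):
                if len(seq) != self.exons[i][1] - self.exons[i][0]:
                    raise ValueError(
                        f"transcript {self.transcript_id} exon {i + 1}: sequence "
                        f"length {len(seq)} != interval length"
                    )
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise ValueError(
                        f"transcript {self.transcript_id} exon {i + 1}: "
                        f"invalid characters {sorted(bad)}"
                    )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def sequence(self) -> str:
        """Spliced transcript sequence (concatenated exons, 5'->3')."""
        if self.exon_sequences is None:
            raise ValueError(f"transcript {self.transcript_id} has no sequences")
        return "".join(self.exon_sequences)


@dataclass
class CountDataset:
    """Feature-by-sample integer counts with the two per-sample factors.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample; ``fraction`` and ``condition`` are Series indexed by sample id.
    """

    counts: pd.DataFrame
    fraction: pd.Series
    condition: pd.Series
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for name, factor, levels in (
            ("fraction", self.fraction, FRACTIONS),
            ("condition", self.condition, CONDITIONS),
        ):
            missing = [s for s in self.counts.columns if s not in factor.index]
            if missing:
                raise ValueError(f"samples missing {name} assignment: {missing}")
            factor = factor.reindex(self.counts.columns)
            bad = factor[~factor.isin(levels) | factor.isna()]
            if len(bad):
                raise ValueError(
                    f"invalid {name} level for sample(s) {list(bad.index[:5])}: "
                    f"expected one of {levels}"
                )
            setattr(self, name, factor)
        if self.size_factors is not None:
            sf = self.size_factors.reindex(self.counts.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise ValueError("size factors must be positive for every sample")
            self.size_factors = sf.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "CountDataset":
        samples = list(samples)
        return CountDataset(
            counts=self.counts[samples].copy(),
            fraction=self.fraction[samples].copy(),
            condition=self.condition[samples].copy(),
            size_factors=None
            if self.size_factors is None
            else self.size_factors[samples].copy(),
        )

    def subset_features(self, features: Sequence[str]) -> "CountDataset":
        return replace(self, counts=self.counts.loc[list(features)].copy())

    def samples_where(
        self, fraction: Optional[str] = None, condition: Optional[str] = None
    ) -> list[str]:
        """Sample ids matching the given factor level(s)."""
        keep = pd.Series(True, index=self.counts.columns)
        if fraction is not None:
            keep &= self.fraction == fraction
        if condition is not None:
            keep &= self.condition == condition
        return list(keep.index[keep])


@dataclass
class AnalysisConfig:
    """Tunable thresholds for the full analysis.

    min_count / min_samples
        mRNA expression filter: keep features with >= min_count in at least
        min_samples samples (defaults 10 and 9).
    circ_min_count / circ_min_samples
        same rule for back-splice junction features (defaults 4 and 5).
    misloc_fdr_cutoff
        BH FDR threshold for calling a feature mislocalized (default 0.001;
        0.01 is the preset for smaller designs).
    de_alpha
        raw p threshold used for overlap/concordance summaries.
    flank_len
        nucleotides taken on each side of a back-splice breakpoint when
        building the junction reference.
    min_anchor / max_mismatch
        junction-read acceptance rule: an ungapped alignment must cover at
        least min_anchor nt on each side of the breakpoint with at most
        max_mismatch mismatches.
    n_samples_N
        the N in the mislocalization T standardization; "auto" resolves to
        the total number of samples in the dataset feeding both contrasts.
    p_null
        tail distribution for the mislocalization p value: "student_t"
        (N-1 df, default) or "normal".
    """

    min_count: int = 10
    min_samples: int = 9
    circ_min_count: int = 4
    circ_min_samples: int = 5
    misloc_fdr_cutoff: float = 0.001
    de_alpha: float = 0.05
    flank_len: int = 150
    min_anchor: int = 10
    max_mismatch: int = 2
    n_samples_N: int | str = "auto"
    p_null: str = "student_t"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_count",
            "min_samples",
            "circ_min_count",
            "circ_min_samples",
            "flank_len",
            "min_anchor",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        for name in ("misloc_fdr_cutoff", "de_alpha"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p_null not in ("student_t", "normal"):
            raise ValueError("p_null must be 'student_t' or 'normal'")
        if self.n_samples_N != "auto" and (
            not isinstance(self.n_samples_N, int) or self.n_samples_N < 2
        ):
            raise ValueError("n_samples_N must be 'auto' or an integer >= 2")
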