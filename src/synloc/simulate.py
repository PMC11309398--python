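"""Synthetic data generators with recorded ground truth.

Three generators emulate the statistical structure the analyses assume:

* a 2x2 factorial (fraction x condition) negative-binomial count matrix with
  planted fraction, condition, and interaction (mislocalization) effects;
* a toy multi-exon transcriptome emitting linear and back-spliced
  (circularized) single-end reads with i.i.d. substitution errors;
* per-gene miRNA binding-site count tables with planted fold enrichment.

Every generator is deterministic given its seed and returns a
:class:`SyntheticTruth` sufficient to score downstream sensitivity/FDR
without re-deriving parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CONDITION_CASE,
    CONDITION_CONTROL,
    CountDataset,
    FRACTION_HOMOGENATE,
    FRACTION_SYNAPTOSOME,
    TranscriptModel,
)
from ._align import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticTruth:
    """Planted generative parameters recorded for recovery scoring."""

    misloc_genes: dict[str, float] = field(default_factory=dict)
    circle_expected_junction_reads: dict[str, dict] = field(default_factory=dict)
    enriched_mirnas: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# factorial NB counts
# ---------------------------------------------------------------------------

@dataclass
class CountSimParams:
    """Parameters of the factorial count simulator.

    Per-gene effect arrays (``beta_fraction``, ``beta_condition``,
    ``beta_interaction``) are on the log2 scale and default to zero; the
    interaction effect is the mislocalization truth. ``dispersion`` is the NB
    overdispersion alpha (variance mu + alpha*mu^2); alpha = 0 degenerates to
    Poisson. ``library_multipliers`` (one per sample, fraction order
    homogenate-control, homogenate-case, synaptosome-control, synaptosome-
    case) default to lognormal draws with sigma ~ 0.15, emulating modest
    library-size variation.
    """

    n_genes: int = 2000
    replicates: int = 6
    baseline_log2_mean: tuple[float, float] = (6.64, 1.5)
    beta_fraction: Optional[np.ndarray] = None
    beta_condition: Optional[np.ndarray] = None
    beta_interaction: Optional[np.ndarray] = None
    dispersion: float | np.ndarray = 0.1
    library_multipliers: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("n_genes and replicates must be >= 1")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be >= 0")
        if self.library_multipliers is not None and np.any(
            np.asarray(self.library_multipliers) <= 0
        ):
            raise ValueError("library multipliers must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray):
    """NB(mean, dispersion alpha) with variance mean + alpha*mean^2;
    alpha below 1e-12 is treated as Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_mask = alpha < 1e-12
    if poisson_mask.any():
        out[poisson_mask] = rng.poisson(mean[poisson_mask])
    nb_mask = ~poisson_mask
    if nb_mask.any():
        a = alpha[nb_mask]
        m = mean[nb_mask]
        n = 1.0 / a
        p = n / (n + m)
        out[nb_mask] = rng.negative_binomial(n, p)
    return out


def simulate_count_dataset(
    params: CountSimParams,
) -> tuple[CountDataset, SyntheticTruth]:
    """Simulate the 2x2 factorial count matrix.

    Count for gene g in sample s is NB with mean
    m_s * 2**(b0_g + bF_g*[synaptosome] + bC_g*[case] + bI_g*[syn and case])
    and dispersion alpha_g, where m_s is the sample's library multiplier.
    """
    rng = np.random.default_rng(params.seed)
    G, r = params.n_genes, params.replicates

    b0 = rng.normal(*params.baseline_log2_mean, size=G)
    bF = np.zeros(G) if params.beta_fraction is None else np.asarray(
        params.beta_fraction, dtype=float
    )
    bC = np.zeros(G) if params.beta_condition is None else np.asarray(
        params.beta_condition, dtype=float
    )
    bI = np.zeros(G) if params.beta_interaction is None else np.asarray(
        params.beta_interaction, dtype=float
    )
    for name, arr in (("beta_fraction", bF), ("beta_condition", bC),
                      ("beta_interaction", bI)):
        if arr.shape != (G,):
            raise ValueError(f"{name} must have shape ({G},)")
    alpha = np.broadcast_to(np.asarray(params.dispersion, dtype=float), (G,))

    cells = [
        (FRACTION_HOMOGENATE, CONDITION_CONTROL),
        (FRACTION_HOMOGENATE, CONDITION_CASE),
        (FRACTION_SYNAPTOSOME, CONDITION_CONTROL),
        (FRACTION_SYNAPTOSOME, CONDITION_CASE),
    ]
    n_samples = 4 * r
    if params.library_multipliers is None:
        m = np.exp(rng.normal(0.0, 0.15, size=n_samples))
    else:
        m = np.asarray(params.library_multipliers, dtype=float)
        if m.shape != (n_samples,):
            raise ValueError(f"library_multipliers must have shape ({n_samples},)")

    sample_ids, fractions, conditions = [], [], []
    log2_mean = np.empty((G, n_samples))
    col = 0
    for frac, cond in cells:
        for i in range(r):
            sample_ids.append(f"{frac[:3]}_{cond[:4]}_{i + 1}")
            fractions.append(frac)
            conditions.append(cond)
            is_syn = frac == FRACTION_SYNAPTOSOME
            is_case = cond == CONDITION_CASE
            log2_mean[:, col] = (
                b0 + bF * is_syn + bC * is_case + bI * (is_syn and is_case)
            )
            col += 1
    mean = m[None, :] * np.exp2(log2_mean)
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite NB mean; check effect sizes")

    counts = _nb_draw(rng, mean, np.broadcast_to(alpha[:, None], mean.shape))
    gene_ids = [f"gene{i + 1:05d}" for i in range(G)]
    ds = CountDataset(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        fraction=pd.Series(fractions, index=sample_ids),
        condition=pd.Series(conditions, index=sample_ids),
    )
    truth = SyntheticTruth(
        misloc_genes={g: float(v) for g, v in zip(gene_ids, bI) if v != 0.0}
    )
    return ds, truth


# ---------------------------------------------------------------------------
# toy transcriptome + reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    """Parameters of the read simulator.

    ``circle_specs`` lists planted circles as (transcript_id, donor_idx,
    acceptor_idx, weight) with 1-based exon indices in transcript order and
    donor >= acceptor. ``linear_weights`` maps transcript_id to its linear
    abundance weight (unlisted transcripts get weight 1). Reads are
    single-end, length ``read_length``, with per-base substitution rate
    ``error_rate``.
    """

    n_transcripts: int = 20
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (80, 400)
    circle_specs: Sequence[tuple[str, int, int, float]] = ()
    linear_weights: Optional[Mapping[str, float]] = None
    read_length: int = 100
    total_reads: int = 20000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        for tid, d, a, w in self.circle_specs:
            if d < a:
                raise ValueError(f"circle {tid}:{d}->{a}: donor must be >= acceptor")
            if w < 0:
                raise ValueError("circle weights must be >= 0")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def simulate_transcriptome(
    n_transcripts: int,
    exon_count_range: tuple[int, int],
    exon_length_range: tuple[int, int],
    rng: np.random.Generator,
    intron_length: int = 100,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Random multi-exon transcripts, each on its own contig.

    Strands alternate so both orientations of the annotation reader are
    exercised; for '-' strand transcripts the contig holds the reverse
    complement of the exon/intron layout, with exon coordinates mirrored.
    Returns (transcripts, genome) where genome maps contig name to sequence.
    """
    transcripts: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    for i in range(n_transcripts):
        tid = f"tx{i + 1:03d}"
        gid = f"g{i + 1:03d}"
        strand = "+" if i % 2 == 0 else "-"
        E = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_seqs = tuple(
            _random_seq(rng, int(rng.integers(*exon_length_range, endpoint=True)))
            for _ in range(E)
        )
        # forward layout: intron, exon1, intron, exon2, ..., intron
        pieces, fwd_exon_coords, pos = [], [], 0
        for seq in exon_seqs:
            intron = _random_seq(rng, intron_length)
            pieces.append(intron)
            pos += intron_length
            fwd_exon_coords.append((pos, pos + len(seq)))
            pieces.append(seq)
            pos += len(seq)
        pieces.append(_random_seq(rng, intron_length))
        pos += intron_length
        fwd = "".join(pieces)
        if strand == "+":
            contig_seq = fwd
            exons = tuple(fwd_exon_coords)
        else:
            contig_seq = reverse_complement(fwd)
            exons = tuple((pos - e, pos - s) for s, e in fwd_exon_coords)
        contig = f"contig_{tid}"
        genome[contig] = contig_seq
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gid.upper(),
                strand=strand,
                exons=exons,
                exon_sequences=exon_seqs,
            )
        )
    return transcripts, genome


def circle_sequence(transcript: TranscriptModel, donor: int, acceptor: int) -> str:
    """Sequence of the circle made by joining exon ``donor``'s 3' end to exon
    ``acceptor``'s 5' end (1-based transcript-order indices, donor >= acceptor):
    the concatenation of exons acceptor..donor."""
    if not (1 <= acceptor <= donor <= transcript.n_exons):
        raise ValueError(
            f"invalid circle {donor}->{acceptor} for transcript "
            f"{transcript.transcript_id} with {transcript.n_exons} exons"
        )
    return "".join(transcript.exon_sequences[acceptor - 1 : donor])


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    n = int(hit.sum())
    if n:
        # shift by 1-3 positions in the base alphabet => always a different base
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    transcripts: Sequence[TranscriptModel],
    params: ReadSimParams,
    rng: np.random.Generator,
    read_prefix: str = "r",
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Draw single-end reads from linear transcripts and planted circles.

    Linear reads start uniformly over valid positions of the spliced
    transcript; circular reads start uniformly over the circle and wrap
    across the back-splice point, so the expected fraction of a circle's
    reads spanning the breakpoint with >= a nt on each side is
    (L - 2a + 1) / C for circle length C >= read length L. Circles shorter
    than L are generated with wrap-around and flagged in the truth.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    L = params.read_length
    lin_w = dict(params.linear_weights or {})
    sources: list[tuple[str, str, float]] = []  # (kind, key, weight)
    for t in transcripts:
        w = float(lin_w.get(t.transcript_id, 1.0))
        if w > 0 and len(t.sequence) < L:
            raise ValueError(
                f"linear transcript {t.transcript_id} shorter than read length"
            )
        sources.append(("linear", t.transcript_id, w))
    circ_seqs: dict[str, str] = {}
    for tid, d, a, w in params.circle_specs:
        if tid not in by_id:
            raise ValueError(f"circle references unknown transcript {tid}")
        key = f"{by_id[tid].gene_id}|{tid}|{d}|{a}"
        circ_seqs[key] = circle_sequence(by_id[tid], d, a)
        sources.append(("circle", key, float(w)))
    weights = np.array([w for _, _, w in sources], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("at least one source weight must be positive")
    n_per_source = rng.multinomial(params.total_reads, weights / weights.sum())

    reads: list[tuple[str, str]] = []
    truth = SyntheticTruth()
    ridx = 0
    for (kind, key, _), n in zip(sources, n_per_source):
        if kind == "circle":
            cseq = circ_seqs[key]
            C = len(cseq)
            truth.circle_expected_junction_reads[key] = {
                "n_reads": int(n),
                "circle_len": C,
                "read_length": L,
                "short_circle": C < L,
            }
        if n == 0:
            continue
        if kind == "linear":
            seq = by_id[key].sequence
            starts = rng.integers(0, len(seq) - L + 1, size=n)
            for s in starts:
                reads.append(
                    (f"{read_prefix}{ridx:07d}",
                     _mutate(rng, seq[s : s + L], params.error_rate))
                )
                ridx += 1
        else:
            cseq = circ_seqs[key]
            C = len(cseq)
            tiled = cseq * (L // C + 2)
            starts = rng.integers(0, C, size=n)
            for s in starts:
                reads.append(
                    (f"{read_prefix}{ridx:07d}",
                     _mutate(rng, tiled[s : s + L], params.error_rate))
                )
                ridx += 1
    return reads, truth


def expected_junction_spanning(
    truth: SyntheticTruth, min_anchor: int
) -> dict[str, float]:
    """Expected junction-spanning read count per circle for a given anchor:
    n_reads * (L - 2a + 1) / C when C >= L (wrap-around circles span by
    construction and are reported as their full read count)."""
    out = {}
    for key, rec in truth.circle_expected_junction_reads.items():
        L, C, n = rec["read_length"], rec["circle_len"], rec["n_reads"]
        if C >= L:
            window = max(L - 2 * min_anchor + 1, 0)
            out[key] = n * window / C
        else:
            out[key] = float(n)
    return out


def simulate_transcriptome_and_reads(
    params: ReadSimParams,
) -> tuple[list[TranscriptModel], dict[str, str], list[tuple[str, str]], SyntheticTruth]:
    """Convenience wrapper: generate a transcriptome and one read set.

    Returns (transcripts, genome, reads, truth).
    """
    rng = np.random.default_rng(params.seed)
    transcripts, genome = simulate_transcriptome(
        params.n_transcripts,
        params.exon_count_range,
        params.exon_length_range,
        rng,
    )
    reads, truth = simulate_reads(transcripts, params, rng)
    return transcripts, genome, reads, truth


# ---------------------------------------------------------------------------
# miRNA site tables
# ---------------------------------------------------------------------------

def simulate_mirna_sites(
    n_mirnas: int,
    n_genes_background: int,
    shortlist_size: int,
    enriched: Mapping[str, float],
    seed: int = 0,
    lam_range: tuple[float, float] = (0.2, 2.0),
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Per-gene miRNA binding-site count tables with planted enrichment.

    Background counts per gene are Poisson(lambda_m) with lambda_m uniform
    over ``lam_range``; shortlist genes use lambda_m scaled by the planted
    fold factor for enriched miRNAs. Returns (background, shortlist, truth)
    as gene-by-miRNA DataFrames.
    """
    if shortlist_size > n_genes_background:
        raise ValueError("shortlist_size must be <= n_genes_background")
    rng = np.random.default_rng(seed)
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    unknown = set(enriched) - set(mirna_ids)
    if unknown:
        raise ValueError(f"enriched miRNAs not in the simulated set: {sorted(unknown)}")
    lam = rng.uniform(*lam_range, size=n_mirnas)
    folds = np.array([float(enriched.get(m, 1.0)) for m in mirna_ids])

    bg = rng.poisson(np.broadcast_to(lam, (n_genes_background, n_mirnas)))
    sl = rng.poisson(np.broadcast_to(lam * folds, (shortlist_size, n_mirnas)))
    bg_df = pd.DataFrame(
        bg,
        index=[f"bg_gene{i + 1:05d}" for i in range(n_genes_background)],
        columns=mirna_ids,
    )
    sl_df = pd.DataFrame(
        sl,
        index=[f"sl_gene{i + 1:05d}" for i in range(shortlist_size)],
        columns=mirna_ids,
    )
    truth = SyntheticTruth(enriched_mirnas={m: f for m, f in enriched.items()})
    return bg_df, sl_df, truth
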