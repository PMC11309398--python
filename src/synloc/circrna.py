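"""CircRNA discovery and quantification from back-splice junction evidence.

A circRNA arises when a downstream exon's 3' end (the donor) is spliced to an
upstream exon's 5' end (the acceptor). Detection proceeds in four steps:
(1) enumerate every donor >= acceptor exon pairing within each transcript and
record the junction sequence (up to ``flank_len`` nt on each side of the
breakpoint, clamped to the circularized region); (2) partition reads by
full-length ungapped alignment against the linear transcriptome; (3) align
the unmapped remainder to the junction reference and count reads whose
alignment covers at least ``min_anchor`` nt on each side of the breakpoint;
(4) append junction counts to the linear count matrix so size factors are
estimated in the context of the whole transcriptome, then run the two-group
NB Wald test on the circular features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AnalysisConfig, CountDataset, TranscriptModel
from .diffexpr import estimate_size_factors, filter_features, two_group_de
from .simulate import circle_sequence
from ._align import UngappedIndex

JUNCTION_ID_SEP = "|"


@dataclass(frozen=True)
class BackspliceJunction:
    """One donor->acceptor exon pairing with its flanking junction sequence.

    ``junction_seq`` is donor-side flank followed by acceptor-side flank;
    ``breakpoint_offset`` is the position where the donor side ends, so a
    read spanning the back-splice point covers both sides of that offset.
    Exon indices are 1-based in transcript order; donor == acceptor is a
    single-exon circle.
    """

    gene_id: str
    transcript_id: str
    donor_idx: int
    acceptor_idx: int
    junction_seq: str
    breakpoint_offset: int
    donor_flank_len: int
    acceptor_flank_len: int

    def __post_init__(self) -> None:
        if self.donor_idx < self.acceptor_idx:
            raise ValueError("donor exon index must be >= acceptor exon index")
        if len(self.junction_seq) != self.donor_flank_len + self.acceptor_flank_len:
            raise ValueError("junction_seq length must equal the two flank lengths")
        if self.breakpoint_offset != self.donor_flank_len:
            raise ValueError("breakpoint_offset must equal donor_flank_len")

    @property
    def junction_id(self) -> str:
        return JUNCTION_ID_SEP.join(
            [self.gene_id, self.transcript_id, str(self.donor_idx),
             str(self.acceptor_idx)]
        )

    @property
    def exon_span(self) -> int:
        """donor - acceptor; 0 for a single-exon circle."""
        return self.donor_idx - self.acceptor_idx


def parse_junction_id(junction_id: str) -> tuple[str, str, int, int]:
    gene, transcript, donor, acceptor = junction_id.split(JUNCTION_ID_SEP)
    return gene, transcript, int(donor), int(acceptor)


@dataclass
class JunctionCounts:
    """Junction-by-sample read counts plus the per-sample tally of reads
    discarded for aligning equally well to multiple junctions."""

    counts: pd.DataFrame
    ambiguous_discarded: pd.Series


def build_backsplice_reference(
    transcripts: Sequence[TranscriptModel], flank_len: int = 150
) -> list[BackspliceJunction]:
    """Enumerate all E*(E+1)/2 back-splice junctions per transcript.

    For each (donor d, acceptor a) with d >= a, the donor flank is the last
    min(flank_len, circle length) nt of the circle sequence (which ends at
    the donor exon's 3' end) and the acceptor flank the first
    min(flank_len, circle length) nt (starting at the acceptor exon's 5'
    end); flanks never extend outside the circularized region and do not
    wrap. Junctions identical at the (gene, donor exon genomic span,
    acceptor exon genomic span) level across redundant transcripts are
    emitted once, from the lexicographically first transcript.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    seen: set[tuple] = set()
    junctions: list[BackspliceJunction] = []
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        if t.exon_sequences is None:
            raise ValueError(
                f"transcript {t.transcript_id} lacks exon sequences"
            )
        for d in range(1, t.n_exons + 1):
            for a in range(1, d + 1):
                key = (t.gene_id, t.exons[d - 1], t.exons[a - 1])
                if key in seen:
                    continue
                seen.add(key)
                circ = circle_sequence(t, d, a)
                f = min(flank_len, len(circ))
                junctions.append(
                    BackspliceJunction(
                        gene_id=t.gene_id,
                        transcript_id=t.transcript_id,
                        donor_idx=d,
                        acceptor_idx=a,
                        junction_seq=circ[-f:] + circ[:f],
                        breakpoint_offset=f,
                        donor_flank_len=f,
                        acceptor_flank_len=f,
                    )
                )
    return junctions


def junctions_to_fasta(junctions: Sequence[BackspliceJunction]) -> dict[str, str]:
    return {j.junction_id: j.junction_seq for j in junctions}


def junction_manifest(junctions: Sequence[BackspliceJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "junction_id": [j.junction_id for j in junctions],
            "gene_id": [j.gene_id for j in junctions],
            "transcript_id": [j.transcript_id for j in junctions],
            "donor_idx": [j.donor_idx for j in junctions],
            "acceptor_idx": [j.acceptor_idx for j in junctions],
            "donor_flank_len": [j.donor_flank_len for j in junctions],
            "acceptor_flank_len": [j.acceptor_flank_len for j in junctions],
            "breakpoint_offset": [j.breakpoint_offset for j in junctions],
        }
    )


def partition_reads_by_linear_alignment(
    reads: Sequence[tuple[str, str]],
    transcripts: Sequence[TranscriptModel],
    max_mismatch: int = 0,
    index: Optional[UngappedIndex] = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Split reads into linearly mapped ids and the unmapped remainder.

    A read is mapped iff it has a full-length ungapped alignment (either
    orientation, <= max_mismatch mismatches) to any spliced transcript.
    The unmapped complement preserves input order. An empty input returns
    empty outputs.
    """
    if index is None:
        index = UngappedIndex({t.transcript_id: t.sequence for t in transcripts})
    mapped: list[str] = []
    unmapped: list[tuple[str, str]] = []
    for rid, seq in reads:
        if index.has_hit(seq, max_mismatch):
            mapped.append(rid)
        else:
            unmapped.append((rid, seq))
    return mapped, unmapped


def count_linear_reads(
    reads: Sequence[tuple[str, str]],
    transcripts: Sequence[TranscriptModel],
    max_mismatch: int = 0,
    index: Optional[UngappedIndex] = None,
) -> pd.Series:
    """Per-transcript counts of full-length linearly aligned reads.

    Each read is assigned to its best-hit transcript (fewest mismatches,
    ties broken by transcript id order); unaligned reads are ignored.
    """
    if index is None:
        index = UngappedIndex({t.transcript_id: t.sequence for t in transcripts})
    counts = pd.Series(0, index=[t.transcript_id for t in transcripts],
                       dtype=np.int64)
    for _, seq in reads:
        hits = index.search(seq, max_mismatch)
        if hits:
            counts[hits[0].ref_id] += 1
    return counts


def count_junction_reads(
    unmapped_by_sample: Mapping[str, Sequence[tuple[str, str]]] | Sequence[tuple[str, str]],
    junctions: Sequence[BackspliceJunction],
    min_anchor: int = 10,
    max_mismatch: int = 0,
) -> JunctionCounts:
    """Count junction-spanning reads per sample.

    A read counts toward a junction iff it has a full-length ungapped
    alignment to the junction sequence (either orientation, <= max_mismatch
    mismatches) covering >= min_anchor nt on each side of the breakpoint.
    Among qualifying junctions the unique best (fewest mismatches) wins;
    mismatch-count ties across distinct junction ids discard the read into
    the per-sample ``ambiguous_discarded`` tally.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if not isinstance(unmapped_by_sample, Mapping):
        unmapped_by_sample = {"sample1": unmapped_by_sample}

    by_id = {j.junction_id: j for j in junctions}
    index = UngappedIndex(junctions_to_fasta(junctions))
    jids = [j.junction_id for j in junctions]
    samples = list(unmapped_by_sample)
    counts = pd.DataFrame(0, index=jids, columns=samples, dtype=np.int64)
    ambiguous = pd.Series(0, index=samples, dtype=np.int64)

    for sample, reads in unmapped_by_sample.items():
        for rid, seq in reads:
            L = len(seq)
            if 2 * min_anchor > L:
                continue
            best_mm = None
            best_jids: set[str] = set()
            for hit in index.search(seq, max_mismatch):
                j = by_id[hit.ref_id]
                bp = j.breakpoint_offset
                if hit.pos <= bp - min_anchor and hit.pos + L >= bp + min_anchor:
                    if best_mm is None or hit.mismatches < best_mm:
                        best_mm = hit.mismatches
                        best_jids = {hit.ref_id}
                    elif hit.mismatches == best_mm:
                        best_jids.add(hit.ref_id)
            if best_mm is None:
                continue
            if len(best_jids) == 1:
                counts.loc[next(iter(best_jids)), sample] += 1
            else:
                ambiguous[sample] += 1
    return JunctionCounts(counts=counts, ambiguous_discarded=ambiguous)


def combined_circ_de(
    linear_ds: CountDataset,
    circ_counts: JunctionCounts,
    config: AnalysisConfig,
    group_labels: pd.Series,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Joint normalization and DE restricted to circular features.

    Junction counts are appended to the linear count matrix so size factors
    reflect the whole transcriptome; circular features are then filtered by
    (circ_min_count, circ_min_samples) and the two-group Wald test is run on
    the combined matrix, reporting circular features only.
    """
    lin_samples = set(linear_ds.sample_ids)
    circ_samples = set(circ_counts.counts.columns)
    if lin_samples != circ_samples:
        raise ValueError(
            "sample sets differ between linear and circular counts: "
            f"{sorted(lin_samples.symmetric_difference(circ_samples))}"
        )
    circ = circ_counts.counts[linear_ds.sample_ids]
    clash = set(circ.index) & set(linear_ds.counts.index)
    if clash:
        raise ValueError(f"feature id collision between linear and circular: {sorted(clash)[:5]}")

    circ_ds = CountDataset(
        counts=circ,
        fraction=linear_ds.fraction,
        condition=linear_ds.condition,
    )
    circ_kept = filter_features(circ_ds, config.circ_min_count, config.circ_min_samples)

    combined = CountDataset(
        counts=pd.concat([linear_ds.counts, circ_kept.counts]),
        fraction=linear_ds.fraction,
        condition=linear_ds.condition,
    )
    if circ_kept.counts.empty:
        return pd.DataFrame(
            columns=["feature_id", "base_mean", "log2fc", "se", "wald", "p", "q"]
        )
    labels = group_labels.reindex(combined.counts.columns)
    used = list(labels.index[labels.isin(contrast)])
    sf = estimate_size_factors(combined.subset_samples(used))
    de = two_group_de(combined, group_labels, contrast, size_factors=sf)
    return de[de["feature_id"].isin(circ_kept.counts.index)].reset_index(drop=True)


def detect_isoform_switches(
    circ_de: pd.DataFrame, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Genes with two significant circular isoforms changing in opposite
    directions.

    ``circ_de`` needs columns gene, donor, acceptor, log2fc, p (or a
    feature_id parseable as gene|transcript|donor|acceptor). A gene is
    reported iff it has >= 2 junctions with p < p_cutoff including at least
    one pair with opposite log2fc signs; each such pair is one output row.
    """
    df = circ_de.copy()
    if "gene" not in df.columns:
        parsed = df["feature_id"].map(parse_junction_id)
        df["gene"] = [p[0] for p in parsed]
        df["donor"] = [p[2] for p in parsed]
        df["acceptor"] = [p[3] for p in parsed]
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        sig = sub[sub["p"] < p_cutoff]
        if len(sig) < 2:
            continue
        for (_, r1), (_, r2) in itertools.combinations(sig.iterrows(), 2):
            if np.sign(r1["log2fc"]) * np.sign(r2["log2fc"]) < 0:
                up, down = (r1, r2) if r1["log2fc"] > 0 else (r2, r1)
                rows.append(
                    {
                        "gene": gene,
                        "up_donor": int(up["donor"]),
                        "up_acceptor": int(up["acceptor"]),
                        "up_log2fc": float(up["log2fc"]),
                        "up_p": float(up["p"]),
                        "down_donor": int(down["donor"]),
                        "down_acceptor": int(down["acceptor"]),
                        "down_log2fc": float(down["log2fc"]),
                        "down_p": float(down["p"]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "up_donor",
            "up_acceptor",
            "up_log2fc",
            "up_p",
            "down_donor",
            "down_acceptor",
            "down_log2fc",
            "down_p",
        ],
    )


def exon_span_summary(
    junctions: Sequence[BackspliceJunction],
    counts: Optional[JunctionCounts] = None,
) -> pd.Series:
    """Histogram of donor - acceptor exon spans over detected junctions.

    With ``counts`` supplied, only junctions with a nonzero total count are
    tallied; otherwise all junctions count. Span 0 is a single-exon circle.
    """
    if counts is not None:
        totals = counts.counts.sum(axis=1)
        detected = [j for j in junctions if totals.get(j.junction_id, 0) > 0]
    else:
        detected = list(junctions)
    spans = pd.Series([j.exon_span for j in detected], dtype=int)
    hist = spans.value_counts().sort_index()
    hist.index.name = "exon_span"
    hist.name = "n_junctions"
    return hist
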