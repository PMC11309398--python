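"""Readers and writers for the formats the pipeline touches.

Annotation (GTF/GFF exon records) is parsed with gffutils; FASTA/FASTQ go
through Bio.SeqIO. Count tables are plain TSV with a separate 3-column sample
metadata table (sample_id, fraction, condition) — factors are never inferred
from sample names.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .containers import AnalysisConfig, CountDataset, TranscriptModel, to_zero_based
from ._align import reverse_complement

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.12g"  # >= 12 significant digits for results tables


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_fasta(source: Union[PathLike, TextIO]) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()


def parse_annotation(
    annotation_text: str, sequences: Mapping[str, str]
) -> list[TranscriptModel]:
    """Build TranscriptModels from GTF/GFF exon records plus sequences.

    ``sequences`` may be keyed by contig (exon sequences are sliced from the
    genomic sequence, reverse-complemented for '-' strand transcripts) or by
    transcript id (the spliced sequence is split at exon boundaries).

    Exons are ordered in transcript (5'->3') order: ascending genomic
    coordinate on '+', descending on '-'; an exon_number attribute, when
    present on every exon, takes precedence.

    Raises
    ------
    ValueError
        if there are no exon records, or an exon references a contig/
        transcript absent from ``sequences``.
    """
    db = gffutils.create_db(
        annotation_text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    n_exons = 0
    for feat in db.features_of_type("exon"):
        n_exons += 1
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "transcript_id/gene_id attributes"
            )
        gname = feat.attributes.get("gene_name", [gid])[0]
        by_transcript.setdefault(tid, []).append(feat)
        meta[tid] = (gid, gname, feat.strand, feat.seqid)
    if n_exons == 0:
        raise ValueError("annotation contains zero exon records")

    # transcripts declared but lacking exon records are a hard error
    declared = {
        f.attributes.get("transcript_id", [None])[0]
        for ftype in ("transcript", "mRNA")
        for f in db.features_of_type(ftype)
    } - {None}
    orphans = sorted(declared - set(by_transcript))
    if orphans:
        raise ValueError(f"transcript(s) without exon records: {orphans}")

    models: list[TranscriptModel] = []
    for tid in sorted(by_transcript):
        gid, gname, strand, seqid = meta[tid]
        feats = sorted(by_transcript[tid], key=lambda f: f.start)
        if strand == "-":
            feats = feats[::-1]
        numbers = [f.attributes.get("exon_number", [None])[0] for f in feats]
        if all(n is not None for n in numbers):
            feats = [f for _, f in sorted(zip(map(int, numbers), feats))]
        exons = tuple(to_zero_based(f.start, f.end) for f in feats)

        if tid in sequences:  # transcript-keyed FASTA
            spliced = sequences[tid].upper()
            lengths = [e - s for s, e in exons]
            if sum(lengths) != len(spliced):
                raise ValueError(
                    f"transcript {tid}: spliced sequence length {len(spliced)} "
                    f"!= total exon length {sum(lengths)}"
                )
            offs = np.concatenate([[0], np.cumsum(lengths)])
            exon_seqs = tuple(
                spliced[offs[i] : offs[i + 1]] for i in range(len(lengths))
            )
        elif seqid in sequences:  # contig-keyed FASTA
            contig = sequences[seqid].upper()
            exon_seqs_l = []
            for s, e in exons:
                if e > len(contig):
                    raise ValueError(
                        f"transcript {tid}: exon ({s}, {e}) extends past contig "
                        f"{seqid} (length {len(contig)})"
                    )
                piece = contig[s:e]
                if strand == "-":
                    piece = reverse_complement(piece)
                exon_seqs_l.append(piece)
            exon_seqs = tuple(exon_seqs_l)
        else:
            raise ValueError(
                f"transcript {tid}: no sequence for contig {seqid!r} or "
                f"transcript {tid!r} in the supplied FASTA"
            )
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gname,
                strand=strand,
                exons=exons,
                exon_sequences=exon_seqs,
            )
        )
    return models


# ---------------------------------------------------------------------------
# count tables / metadata
# ---------------------------------------------------------------------------

def write_count_dataset(
    ds: CountDataset, counts_path: PathLike, metadata_path: PathLike
) -> None:
    """Write counts and the 3-column sample metadata table as TSV."""
    out = ds.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "fraction": ds.fraction.values,
            "condition": ds.condition.values,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_count_dataset(
    counts_path: PathLike, metadata_path: PathLike
) -> CountDataset:
    """Read a count table plus sample metadata, validating integer counts.

    Raises
    ------
    ValueError
        on a non-integer count cell (named by row/column), a duplicate
        feature id, or a sample missing a factor assignment.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        bad = counts.index[vals.isna() | (np.mod(vals.fillna(0.5), 1) != 0)]
        if len(bad):
            raise ValueError(
                f"non-integer count at feature {bad[0]!r}, sample {col!r}"
            )
    counts = counts.astype(np.int64)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "fraction", "condition"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")
    for name in ("fraction", "condition"):
        missing = [
            s
            for s in counts.columns
            if s not in meta.index or pd.isna(meta.loc[s, name])
        ]
        if missing:
            raise ValueError(f"sample(s) missing {name}: {missing}")
    return CountDataset(
        counts=counts,
        fraction=meta["fraction"].reindex(counts.columns),
        condition=meta["condition"].reindex(counts.columns),
    )


def write_results_table(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    """Write a results table with >= 12 significant digits for floats."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_results_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA / FASTQ / GTF writing (synthetic data and junction references)
# ---------------------------------------------------------------------------

def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: PathLike, width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(
    reads: Iterable[tuple[str, str]], path: PathLike, quality_char: str = "I"
) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(source: Union[PathLike, TextIO]) -> list[tuple[str, str]]:
    """Read FASTQ into (id, sequence) tuples in file order."""
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fastq")]
    finally:
        if close:
            handle.close()


def transcripts_to_gtf(transcripts: Sequence[TranscriptModel], seqid_of=None) -> str:
    """Render TranscriptModels as GTF exon records (1-based inclusive).

    ``seqid_of`` maps a transcript to its contig name; by default each
    transcript lives on a contig named after its transcript id.
    """
    if seqid_of is None:
        seqid_of = lambda t: f"contig_{t.transcript_id}"
    lines = []
    for t in transcripts:
        for i, (s0, e0) in enumerate(t.exons, start=1):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_name}"; exon_number "{i}";'
            )
            lines.append(
                "\t".join(
                    [
                        seqid_of(t),
                        "synloc",
                        "exon",
                        str(s0 + 1),
                        str(e0),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: PathLike, **overrides) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML key-value file, with overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(AnalysisConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=True)
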