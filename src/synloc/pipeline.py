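"""Top-level orchestration of the three analyses.

``run_full_analysis`` executes, in order and as inputs allow: the mRNA stage
(expression filter, size factors, the four subset two-group contrasts,
mislocalization test, overlap/concordance summary), the circRNA stage
(junction reference, read partitioning, junction counting, joint
normalization and DE, isoform switches, exon-span summary), and the miRNA
site-enrichment stage. Stages with missing inputs are skipped with a logged
warning. Given identical (config, inputs) the written outputs are
byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import circrna as circ_mod
from . import diffexpr, io, misloc
from .containers import (
    CONDITION_CASE,
    CONDITION_CONTROL,
    AnalysisConfig,
    CountDataset,
    FRACTION_HOMOGENATE,
    FRACTION_SYNAPTOSOME,
)
from .mirna import site_enrichment_test

logger = logging.getLogger(__name__)

CONTRAST_NAMES = (
    "syn_vs_hom_in_control",
    "syn_vs_hom_in_case",
    "case_vs_control_in_homogenate",
    "case_vs_control_in_synaptosome",
)


@dataclass
class AnalysisInputs:
    """Optional inputs for each stage; a stage runs iff its inputs are set."""

    counts: Optional[CountDataset] = None
    transcripts: Optional[Sequence] = None  # TranscriptModels with sequences
    reads_by_sample: Optional[Mapping[str, Sequence[tuple[str, str]]]] = None
    linear_counts_for_circ: Optional[CountDataset] = None
    shortlist_sites: Optional[pd.DataFrame] = None
    background_sites: Optional[pd.DataFrame] = None


def _subset_contrasts(
    ds: CountDataset, config: AnalysisConfig
) -> dict[str, pd.DataFrame]:
    """The four subset two-group contrasts of the localization analysis."""
    out: dict[str, pd.DataFrame] = {}
    specs = {
        "syn_vs_hom_in_control": (
            ds.samples_where(condition=CONDITION_CONTROL),
            "fraction",
            (FRACTION_SYNAPTOSOME, FRACTION_HOMOGENATE),
        ),
        "syn_vs_hom_in_case": (
            ds.samples_where(condition=CONDITION_CASE),
            "fraction",
            (FRACTION_SYNAPTOSOME, FRACTION_HOMOGENATE),
        ),
        "case_vs_control_in_homogenate": (
            ds.samples_where(fraction=FRACTION_HOMOGENATE),
            "condition",
            (CONDITION_CASE, CONDITION_CONTROL),
        ),
        "case_vs_control_in_synaptosome": (
            ds.samples_where(fraction=FRACTION_SYNAPTOSOME),
            "condition",
            (CONDITION_CASE, CONDITION_CONTROL),
        ),
    }
    for name, (samples, factor, contrast) in specs.items():
        sub = ds.subset_samples(samples)
        labels = getattr(sub, factor)
        out[name] = diffexpr.two_group_de(sub, labels, contrast)
    return out


def run_full_analysis(
    config: AnalysisConfig,
    inputs: AnalysisInputs,
    outdir: Optional[str | Path] = None,
) -> dict:
    """Run every stage whose inputs are available; return a results bundle.

    The bundle maps stage outputs to DataFrames (or dicts for summaries);
    with ``outdir`` set, every table is also written as TSV plus a run log.
    """
    results: dict = {"log": []}

    def log(msg: str) -> None:
        logger.info(msg)
        results["log"].append(msg)

    log(f"config: {vars(config)}")

    # ---- mRNA localization stage -------------------------------------
    if inputs.counts is not None:
        ds = inputs.counts
        log(f"mRNA stage: {ds.counts.shape[0]} features x {ds.n_samples} samples")
        filtered = diffexpr.filter_features(ds, config.min_count, config.min_samples)
        log(
            f"expression filter (>= {config.min_count} in >= {config.min_samples} "
            f"samples): {filtered.counts.shape[0]} features kept"
        )
        de_tables = _subset_contrasts(filtered, config)
        results["de"] = de_tables
        n_samples = (
            filtered.n_samples
            if config.n_samples_N == "auto"
            else int(config.n_samples_N)
        )
        results["misloc"] = misloc.misloc_from_de_tables(
            de_tables["case_vs_control_in_synaptosome"],
            de_tables["case_vs_control_in_homogenate"],
            n_samples=n_samples,
            fdr_cutoff=config.misloc_fdr_cutoff,
            null_dist=config.p_null,
        )
        n_up = int((results["misloc"]["direction"] == "up").sum())
        n_down = int((results["misloc"]["direction"] == "down").sum())
        log(
            f"mislocalization (N={n_samples}, FDR<{config.misloc_fdr_cutoff}): "
            f"{n_up} up, {n_down} down"
        )
        results["overlap_concordance"] = diffexpr.overlap_concordance(
            de_tables["case_vs_control_in_synaptosome"],
            de_tables["case_vs_control_in_homogenate"],
            alpha=config.de_alpha,
        )
        log(f"overlap/concordance: {results['overlap_concordance']}")
    else:
        log("mRNA stage skipped: no count dataset")

    # ---- circRNA stage ------------------------------------------------
    circ_ready = (
        inputs.transcripts is not None
        and inputs.reads_by_sample is not None
        and inputs.linear_counts_for_circ is not None
    )
    if circ_ready:
        junctions = circ_mod.build_backsplice_reference(
            inputs.transcripts, config.flank_len
        )
        log(f"circ stage: {len(junctions)} candidate back-splice junctions")
        unmapped_by_sample = {}
        from ._align import UngappedIndex

        lin_index = UngappedIndex(
            {t.transcript_id: t.sequence for t in inputs.transcripts}
        )
        for sample, reads in inputs.reads_by_sample.items():
            mapped, unmapped = circ_mod.partition_reads_by_linear_alignment(
                reads, inputs.transcripts, config.max_mismatch, index=lin_index
            )
            unmapped_by_sample[sample] = unmapped
            log(f"  {sample}: {len(mapped)} mapped, {len(unmapped)} unmapped")
        jcounts = circ_mod.count_junction_reads(
            unmapped_by_sample, junctions, config.min_anchor, config.max_mismatch
        )
        results["junctions"] = circ_mod.junction_manifest(junctions)
        results["junction_counts"] = jcounts
        lin = inputs.linear_counts_for_circ
        de_specs = {
            "circ_syn_vs_hom_in_control": (
                lin.samples_where(condition=CONDITION_CONTROL),
                "fraction",
                (FRACTION_SYNAPTOSOME, FRACTION_HOMOGENATE),
            ),
            "circ_case_vs_control_in_synaptosome": (
                lin.samples_where(fraction=FRACTION_SYNAPTOSOME),
                "condition",
                (CONDITION_CASE, CONDITION_CONTROL),
            ),
        }
        results["circ_de"] = {}
        for name, (samples, factor, contrast) in de_specs.items():
            if len(samples) < 4:
                log(f"  {name} skipped: fewer than 2 samples per group")
                continue
            sub = lin.subset_samples(samples)
            sub_counts = circ_mod.JunctionCounts(
                counts=jcounts.counts[samples],
                ambiguous_discarded=jcounts.ambiguous_discarded[samples],
            )
            results["circ_de"][name] = circ_mod.combined_circ_de(
                sub, sub_counts, config, getattr(sub, factor), contrast
            )
            log(f"  {name}: {len(results['circ_de'][name])} circ features tested")
        key = "circ_case_vs_control_in_synaptosome"
        if key in results["circ_de"] and len(results["circ_de"][key]):
            results["isoform_switches"] = circ_mod.detect_isoform_switches(
                results["circ_de"][key], p_cutoff=config.de_alpha
            )
            log(f"  isoform switches: {len(results['isoform_switches'])} pairs")
        results["exon_span"] = circ_mod.exon_span_summary(junctions, jcounts)
    else:
        log("circ stage skipped: needs transcripts, reads, and linear counts")

    # ---- miRNA stage ---------------------------------------------------
    if inputs.shortlist_sites is not None and inputs.background_sites is not None:
        results["mirna"] = site_enrichment_test(
            inputs.shortlist_sites, inputs.background_sites, fdr_cutoff=0.05
        )
        n_enr = int((results["mirna"]["call"] == "enriched").sum())
        log(f"miRNA stage: {n_enr} enriched at q<0.05")
    else:
        log("miRNA stage skipped: needs shortlist and background site tables")

    if outdir is not None:
        _write_bundle(results, Path(outdir))
    return results


def _write_bundle(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in results.get("de", {}).items():
        io.write_results_table(table, outdir / f"de_{name}.tsv")
    if "misloc" in results:
        io.write_results_table(results["misloc"], outdir / "mislocalization.tsv")
    if "junctions" in results:
        io.write_results_table(results["junctions"], outdir / "junction_manifest.tsv")
    if "junction_counts" in results:
        jc = results["junction_counts"]
        counts = jc.counts.copy()
        counts.index.name = "junction_id"
        counts.to_csv(outdir / "junction_counts.tsv", sep="\t")
    for name, table in results.get("circ_de", {}).items():
        io.write_results_table(table, outdir / f"de_{name}.tsv")
    if "isoform_switches" in results:
        io.write_results_table(results["isoform_switches"], outdir / "isoform_switches.tsv")
    if "exon_span" in results:
        results["exon_span"].to_csv(outdir / "exon_span_histogram.tsv", sep="\t")
    if "mirna" in results:
        io.write_results_table(results["mirna"], outdir / "mirna_enrichment.tsv")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(results["log"]) + "\n")
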