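#!/usr/bin/env python
"""Generate the synthetic study bundle used by the downstream analyses.

Emulates a 2x2 factorial synaptosome/homogenate, case/control RNA-seq study:
(1) a negative-binomial count matrix with mislocalization (fraction x
condition interaction) planted in 5% of genes; (2) a toy multi-exon
transcriptome with five planted circRNAs whose abundance is 4x higher in
synaptosome samples, emitting per-sample FASTQ; (3) miRNA binding-site
tables with one 8-fold enriched miRNA. Everything is written under
results/data/ together with the ground truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from synloc import (
    CountDataset,
    CountSimParams,
    ReadSimParams,
    simulate_count_dataset,
    simulate_mirna_sites,
    simulate_reads,
    simulate_transcriptome,
)
from synloc.io import (
    transcripts_to_gtf,
    write_count_dataset,
    write_fasta,
    write_fastq,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # ---- factorial counts with planted mislocalization ----------------
    G, frac_misloc, effect = 2000, 0.05, 1.5
    n_misloc = int(G * frac_misloc)
    bI = np.zeros(G)
    idx = rng.choice(G, n_misloc, replace=False)
    bI[idx] = rng.choice([-effect, effect], size=n_misloc)
    ds, truth = simulate_count_dataset(
        CountSimParams(n_genes=G, replicates=6, beta_interaction=bI, seed=seed)
    )
    write_count_dataset(ds, OUT / "counts.tsv", OUT / "metadata.tsv")
    pd.DataFrame(
        {"gene": list(truth.misloc_genes), "beta_interaction":
         list(truth.misloc_genes.values())}
    ).to_csv(OUT / "truth_misloc.tsv", sep="\t", index=False)
    print(f"counts: {G} genes x {ds.n_samples} samples; "
          f"{n_misloc} genes with planted |interaction| = {effect}")

    # ---- toy transcriptome + per-sample reads --------------------------
    transcripts, genome = simulate_transcriptome(10, (2, 6), (100, 300), rng)
    write_fasta(genome, OUT / "genome.fasta")
    (OUT / "annotation.gtf").write_text(transcripts_to_gtf(transcripts))
    circles = [(t.transcript_id, 2, 2) for t in transcripts[:5]]
    samples = [("syn", i) for i in range(3)] + [("hom", i) for i in range(3)]
    meta_rows = []
    for frac, i in samples:
        name = f"{frac}_{i + 1}"
        w = 0.16 if frac == "syn" else 0.04
        params = ReadSimParams(
            circle_specs=[(tid, d, a, w) for tid, d, a in circles],
            read_length=100, total_reads=10000, error_rate=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        reads, _ = simulate_reads(transcripts, params, rng,
                                  read_prefix=f"{name}_r")
        write_fastq(reads, OUT / f"reads_{name}.fastq")
        meta_rows.append(
            {"sample_id": name,
             "fraction": "synaptosome" if frac == "syn" else "homogenate",
             "condition": "control"}
        )
    pd.DataFrame(meta_rows).to_csv(OUT / "read_samples.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(
        [{"transcript_id": tid, "donor": d, "acceptor": a} for tid, d, a in circles]
    ).to_csv(OUT / "truth_circles.tsv", sep="\t", index=False)
    print(f"reads: {len(samples)} samples x 10000 reads; "
          f"{len(circles)} planted circles (4x synaptosome)")

    # ---- miRNA site tables ---------------------------------------------
    bg, sl, mtruth = simulate_mirna_sites(
        n_mirnas=30, n_genes_background=4000, shortlist_size=300,
        enriched={"miR-011": 8.0}, seed=seed,
    )
    bg.to_csv(OUT / "mirna_background_sites.tsv", sep="\t")
    sl.to_csv(OUT / "mirna_shortlist_sites.tsv", sep="\t")
    print(f"miRNA sites: 30 miRNAs, planted 8x enrichment for "
          f"{list(mtruth.enriched_mirnas)}")
    print(f"wrote bundle to {OUT}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    main(parser.parse_args().seed)
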