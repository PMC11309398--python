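# synloc

Statistics and workflows for studying RNA localization to synapses with bulk
RNA-seq of paired **synaptosome** and **homogenate** fractions from case and
control brain tissue — a 2×2 factorial design (Fraction × Condition).

The package addresses three questions that arise in such studies:

1. **Which transcripts are mislocalized?** A transcript whose case-vs-control
   fold change differs between the synaptosome fraction and the bulk
   homogenate has changed how it localizes, over and above any global
   expression change — a Fraction × Condition interaction.
2. **Which circular RNAs are present and differentially localized?**
   circRNAs arise when a downstream exon's 3′ end (donor) back-splices to an
   upstream exon's 5′ end (acceptor); reads that span the back-splice
   junction do not align to the linear transcriptome and must be recovered
   from the unmapped fraction.
3. **Are particular miRNA binding sites over-represented** in the 3′UTRs of a
   shortlist of transcripts relative to the transcriptome-wide background?

## The core statistic

For each feature, two independent two-group contrasts (case vs control
within each fraction) provide log₂ fold changes and standard errors. The
mislocalization statistic is

```
misloc_lfc = lfc_syn − lfc_hom                    (log2 of the ratio of ratios)
Rw         = lfc_syn/SE_syn − lfc_hom/SE_hom      (difference of Wald statistics)
T_i        = Rw_i / sqrt( (Σ_j Rw_j² / G) / N )
```

with G the number of features tested and N the number of samples behind the
two contrasts. Two-tailed p-values come from Student *t* with N−1 df
(`normal` tails available), q-values from Benjamini–Hochberg, and features
are classed up/down at a configurable FDR cutoff (0.001 by default). Note
the √N in the standardization makes |T| grow with the study size for fixed
Rw; see `docs/methods.md` for the calibration analysis and why a stringent
FDR cutoff should accompany this statistic.

The supporting machinery — median-of-ratios size factors, count filtering
(≥10 counts in ≥9 samples for mRNA; ≥4 in ≥5 for circRNA), a two-group
negative-binomial Wald test, exhaustive back-splice junction enumeration
with 150 nt flanks, anchor-based junction read counting, joint
circular+linear normalization, isoform-switch detection, and per-miRNA 2×2
χ² site enrichment — lives behind small composable functions, with
ground-truthed synthetic data generators for every input type.

## Worked example

The analysis scripts run the whole pipeline on a simulated study
(`results/` output):

```bash
python analysis/01_simulate_data.py      # synthetic bundle + ground truth
python analysis/02_mrna_localization.py
python analysis/03_circrna_discovery.py
python analysis/04_mirna_enrichment.py
```

`03_circrna_discovery.py` prints, for a toy 10-transcript genome with five
single-exon circles planted at 4× synaptosome abundance:

```
junction reference: 151 candidates; 5 circRNAs pass the (4, 5) count filter
planted circles recovered: 5/5, mean synaptosome log2fc = 1.95 (planted 4x => 2.0)
exon-span histogram of detected junctions:
exon_span
0    5
```

i.e. every planted circle is recovered, the jointly normalized synaptosome
enrichment estimate (log₂ ≈ 1.95) matches the planted 4-fold effect, and all
detected junctions are single-exon circles (donor = acceptor, span 0), as
planted. `04_mirna_enrichment.py` recovers the planted 8-fold miRNA as the
unique hit:

```
30 miRNAs tested; 1 enriched at q < 0.05
top hit: miR-011 log2fc 2.81 chi2 5857.6 q 0.00e+00
```

A minimal library-level example of isoform-switch detection on the bundled
worked-example table of circRNA differential-expression records:

```python
from synloc import detect_isoform_switches
from synloc.datasets import load_circ_isoform_examples

switches = detect_isoform_switches(load_circ_isoform_examples(), p_cutoff=0.05)
print(sorted(set(switches["gene"])))
# ['ANKS1B', 'ATF6', 'GSK3B', 'UBA2']
```

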