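"""Small bundled reference tables."""

from importlib import resources

import pandas as pd


def load_circ_isoform_examples() -> pd.DataFrame:
    """Published examples of circRNA isoform differential expression in
    frontal-lobe synaptosomes (case vs control): per-junction gene, donor
    and acceptor exon numbers, log2 fold change, and raw p value. Useful as
    a worked input for :func:`synloc.detect_isoform_switches`."""
    with resources.files("synloc.data").joinpath("circ_isoform_examples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
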