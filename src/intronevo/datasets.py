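"""Bundled reference tables.

``caenorhabditis_counts`` ships the published per-species intron loss/gain
bookkeeping for the ten Caenorhabditis species (loss and confirmed-gain
tallies, gene-class sizes, precise-loss counts, genes with two or more lost
introns, and adjacent lost pairs), derived from a 4892-group one-to-one
ortholog set.  These are inputs for consistency summaries and worked
examples, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: size of the ten-species one-to-one ortholog set behind the bundled counts
ORTHOLOG_GROUPS = 4892


def caenorhabditis_counts() -> pd.DataFrame:
    """Per-species loss/gain count table, indexed by species."""
    with resources.files("intronevo.data").joinpath("caenorhabditis_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="species")
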