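"""Bundled published reference tables.

Both tables come from a published 4x4 diallel heterosis experiment in
Chinese cabbage (*Brassica rapa* ssp. *pekinensis*): four female inbred
lines (A-D) crossed with four male inbred lines (E-H) giving 16 F1
hybrids.  They are the printed study results used here as inputs for
summary recomputation and for exercising the grouping rules on real
numbers; the underlying raw sequencing data is not part of this package.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_pattern_counts", "load_mpv_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_pattern_counts() -> pd.DataFrame:
    """Per-hybrid gene counts in the 12 trio expression patterns.

    Returns a 16 x 12 DataFrame indexed by hybrid code (AE..DH) with
    columns P1..P12: the number of differentially expressed genes each
    hybrid assigned to each expression pattern.
    """
    return _read("cabbage_pattern_counts.tsv").set_index("hybrid")


def load_mpv_table() -> pd.DataFrame:
    """Mid-parent heterosis of plant gross weight for the 16 hybrids.

    Columns: ``heterosis_level`` (published strong/middle/weak label) and
    ``mpv`` (published mid-parent heterosis value, percent), indexed by
    hybrid code.
    """
    return _read("cabbage_mpv.tsv").set_index("hybrid")
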