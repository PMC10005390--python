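"""Tab-separated readers and writers for the pipeline's file formats.

All on-disk formats are plain TSV with a header row:

* expression matrix — first column ``gene_id``, remaining columns one per
  sample; values are counts or FPKM (the layer tag is carried in
  ``DataFrame.attrs["layer"]``, not on disk)
* sample sheet — columns ``sample``, ``line``, ``role``
  (female-parent | male-parent | hybrid), ``replicate``
* trio design — columns ``hybrid``, ``female``, ``male``
* trait table — columns ``line``, ``value`` (replicate-level rows allowed;
  they are averaged per line downstream)
* annotations — GMT (term <tab> description <tab> genes...) or two-column
  ``gene <tab> term`` TSV
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

ROLES = ("female-parent", "male-parent", "hybrid")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def read_expression(path: str | os.PathLike, layer: str = "FPKM") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    df.index.name = "gene_id"
    df.attrs["layer"] = layer
    return df


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "line", "role", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise FormatError(f"{path}: unknown roles {sorted(bad)}")
    return df


def read_trio_design(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"hybrid", "female", "male"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: trio design needs columns {sorted(required)}")
    return df


def read_traits(path: str | os.PathLike) -> pd.Series:
    """Read a trait table and return mean trait value per line."""
    df = pd.read_csv(path, sep="\t")
    if not {"line", "value"}.issubset(df.columns):
        raise FormatError(f"{path}: trait table needs columns ['line', 'value']")
    return df.groupby("line")["value"].mean()


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


@dataclass
class AnnotationMap:
    """Flat term -> gene-set annotation against a population universe."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()

    def restrict(self, universe: set[str]) -> "AnnotationMap":
        """Harmonize annotations to a given population universe."""
        terms = {t: g & universe for t, g in self.terms.items()}
        return AnnotationMap(terms=terms, names=dict(self.names), universe=set(universe))


def read_gmt(path: str | os.PathLike) -> AnnotationMap:
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT lines need term, description, >=1 gene")
            term, desc, genes = parts[0], parts[1], parts[2:]
            terms[term] = {g for g in genes if g}
            names[term] = desc
    return AnnotationMap(terms=terms, names=names)


def read_gene_term_tsv(path: str | os.PathLike) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    terms: dict[str, set[str]] = {}
    for term, grp in df.groupby("term"):
        terms[str(term)] = set(grp["gene"])
    return AnnotationMap(terms=terms)


def read_annotations(path: str | os.PathLike) -> AnnotationMap:
    """Dispatch on content: GMT if any line has >=3 tab-separated fields."""
    with open(path) as fh:
        first = fh.readline()
    if len(first.rstrip("\n").split("\t")) >= 3:
        return read_gmt(path)
    return read_gene_term_tsv(path)
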