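"""Trio expression-pattern classification (additive / dominant / over-dominant).

Each differentially expressed gene of a female-male-hybrid trio is
described by three pairwise relations, one per comparison:

* ``F vs M`` — between the parents,
* ``F vs H`` and ``M vs H`` — hybrid against each parent,

where "=" means the comparison is *not* significant and "<" / ">" means
it is significant with group mean FPKMs in that order.  The twelve
patterns partition the consistent relation triples:

====  =======================================  =============
P1    F>M with M<H<F (all three significant)   additive
P2    F<M with F<H<M (all three significant)   additive
P3    F<M, H=M (hence F<H)                     dominant
P4    F>M, H=M (hence F>H)                     dominant
P5    F>M, H=F (hence H>M)                     dominant
P6    F<M, H=F (hence H<M)                     dominant
P7    F=M, H below both parents                over-dominant
P8    F>M, H below both                        over-dominant
P9    F<M, H below both                        over-dominant
P10   F=M, H above both                        over-dominant
P11   F>M, H above both                        over-dominant
P12   F<M, H above both                        over-dominant
====  =======================================  =============

Triples matching no row — internally contradictory calls, or the
ambiguous all-"=" / double-"=" cases — are returned as ``unclassified``
rather than force-fitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PATTERNS = tuple(f"P{i}" for i in range(1, 13))
UNCLASSIFIED = "unclassified"

CATEGORY = {**{p: "additive" for p in ("P1", "P2")},
            **{p: "dominant" for p in ("P3", "P4", "P5", "P6")},
            **{p: "over-dominant" for p in ("P7", "P8", "P9", "P10", "P11", "P12")}}
CATEGORIES = ("additive", "dominant", "over-dominant")

# relation encoding: parents F vs M in {"F<M", "F>M", "F=M"};
# hybrid vs a parent X in {"H<X", "H>X", "H=X"}
_TRUTH_TABLE = {
    ("F>M", "H<F", "H>M"): "P1",
    ("F<M", "H>F", "H<M"): "P2",
    ("F<M", "H>F", "H=M"): "P3",
    ("F>M", "H<F", "H=M"): "P4",
    ("F>M", "H=F", "H>M"): "P5",
    ("F<M", "H=F", "H<M"): "P6",
    ("F=M", "H<F", "H<M"): "P7",
    ("F>M", "H<F", "H<M"): "P8",
    ("F<M", "H<F", "H<M"): "P9",
    ("F=M", "H>F", "H>M"): "P10",
    ("F>M", "H>F", "H>M"): "P11",
    ("F<M", "H>F", "H>M"): "P12",
}


def classify_gene(
    fpkm_f: float,
    fpkm_m: float,
    fpkm_h: float,
    sig_fm: bool,
    sig_fh: bool,
    sig_mh: bool,
) -> str:
    """Assign one trio call to a pattern label (or ``unclassified``).

    Significance flags come from the three pairwise tests; directions
    are taken from the group mean FPKMs.  A gene significant in none of
    the comparisons is outside the DEG universe.
    """
    if not (sig_fm or sig_fh or sig_mh):
        raise ValueError("gene is not a DEG in any comparison; classify DEGs only")
    # a significant call with tied means is contradictory -> never matches
    rel_fm = "F=M" if not sig_fm else ("F<M" if fpkm_f < fpkm_m else "F>M" if fpkm_f > fpkm_m else "!")
    rel_fh = "H=F" if not sig_fh else ("H<F" if fpkm_h < fpkm_f else "H>F" if fpkm_h > fpkm_f else "!")
    rel_mh = "H=M" if not sig_mh else ("H<M" if fpkm_h < fpkm_m else "H>M" if fpkm_h > fpkm_m else "!")
    return _TRUTH_TABLE.get((rel_fm, rel_fh, rel_mh), UNCLASSIFIED)


def classify_trio(
    de_fm: pd.DataFrame,
    de_fh: pd.DataFrame,
    de_mh: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every DEG of a trio from its three DE tables.

    The tables come from :func:`heteroseq.de.trio_de` (group A is the
    first-named material, so ``mean_a``/``mean_b`` map onto F, M and H).
    The classified universe is the union of the three DEG sets; the
    result has columns ``pattern`` and ``category``.
    """
    if not (de_fm.index.equals(de_fh.index) and de_fm.index.equals(de_mh.index)):
        raise ValueError("the three DE tables must share one gene universe")
    degs = de_fm["is_deg"] | de_fh["is_deg"] | de_mh["is_deg"]
    idx = de_fm.index[degs]
    f = de_fm.loc[idx, "mean_a"].to_numpy()
    m = de_fm.loc[idx, "mean_b"].to_numpy()
    h = de_fh.loc[idx, "mean_b"].to_numpy()
    sig_fm = de_fm.loc[idx, "is_deg"].to_numpy()
    sig_fh = de_fh.loc[idx, "is_deg"].to_numpy()
    sig_mh = de_mh.loc[idx, "is_deg"].to_numpy()

    rel_fm = np.where(~sig_fm, "F=M", np.where(f < m, "F<M", np.where(f > m, "F>M", "!")))
    rel_fh = np.where(~sig_fh, "H=F", np.where(h < f, "H<F", np.where(h > f, "H>F", "!")))
    rel_mh = np.where(~sig_mh, "H=M", np.where(h < m, "H<M", np.where(h > m, "H>M", "!")))
    labels = [
        _TRUTH_TABLE.get(key, UNCLASSIFIED) for key in zip(rel_fm, rel_fh, rel_mh)
    ]
    table = pd.DataFrame({"pattern": labels}, index=idx)
    table["category"] = table["pattern"].map(CATEGORY).fillna("none")
    return table


def summarize_patterns(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Counts per pattern and category percentages over classified genes.

    Returns ``(counts, percentages)``: counts indexed P1..P12 plus
    ``unclassified``; percentages over the three categories summing to
    100 across classified genes (all-NaN when nothing classified).
    """
    if table.empty:
        raise ValueError("empty pattern table")
    counts = table["pattern"].value_counts().reindex(list(PATTERNS) + [UNCLASSIFIED], fill_value=0)
    return counts, category_percentages(counts)


def category_percentages(counts: pd.Series) -> pd.Series:
    """Percent of classified genes per category from P1..P12 counts."""
    cat = pd.Series(0.0, index=pd.Index(CATEGORIES, name="category"))
    for p in PATTERNS:
        cat[CATEGORY[p]] += float(counts.get(p, 0))
    total = cat.sum()
    if total == 0:
        return cat * np.nan
    return 100.0 * cat / total


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def aggregate_across_hybrids(counts_by_hybrid: pd.DataFrame) -> pd.DataFrame:
    """Per-pattern average and standard error across hybrids.

    ``counts_by_hybrid`` is hybrids x patterns.  The average is the
    arithmetic mean rounded half away from zero to an integer; the
    standard error is the population standard deviation (n divisor)
    divided by sqrt(n), rounded to two decimals — the conventions of the
    published per-pattern summary rows.
    """
    if counts_by_hybrid.shape[0] < 2:
        raise ValueError("need >= 2 hybrids to aggregate")
    vals = counts_by_hybrid.to_numpy(dtype=float)
    n = vals.shape[0]
    avg = _round_half_away(vals.mean(axis=0)).astype(int)
    se = np.round(vals.std(axis=0, ddof=0) / np.sqrt(n), 2)
    return pd.DataFrame(
        {"average": avg, "standard_error": se}, index=counts_by_hybrid.columns
    )


def export_pattern_heatmap_data(
    expr: pd.DataFrame, table: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Row-standardized expression for selected genes with pattern labels.

    Constant genes are kept at zero with ``zero_variance`` flagged, so
    heatmap export never raises on flat profiles.
    """
    missing = [g for g in genes if g not in expr.index or g not in table.index]
    if missing:
        raise KeyError(f"genes absent from expression or pattern table: {missing[:5]}")
    sub = expr.loc[genes].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flat = sd == 0
    z = sub.sub(mu, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z.loc[flat] = 0.0
    z["pattern"] = table.loc[genes, "pattern"]
    z["zero_variance"] = flat
    return z
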