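"""Weighted coexpression network: adjacency, TOM, modules, eigengenes.

A minimal unsigned weighted-network workflow in the WGCNA tradition:
soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta, topological
overlap similarity

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage hierarchical clustering on 1 - TOM with a fixed-height
cut, small clusters dropped to "unassigned", and modules with highly
correlated eigengenes (r > merge_r) merged.  Module eigengenes are the
first principal component of the gene-standardized module submatrix;
module-trait association is a Pearson correlation with a two-sided t
test.  Defaults follow the emulated study: beta = 11, minimum module
size 50, significance at p < 0.05.

The ``mpv`` input mode replaces per-sample expression with per-hybrid
mid-parent heterosis of expression, pairing with mid-parent heterosis
of the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


class InsufficientSamplesError(ValueError):
    pass


@dataclass
class NetworkConfig:
    beta: float = 11.0
    min_module_size: int = 50
    cut_height: float = 0.95
    merge_r: float = 0.8
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleResult:
    labels: pd.Series  # gene -> module label, UNASSIGNED for leftovers
    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    variance_explained: pd.Series
    trait_cor: pd.DataFrame | None = None  # per-module r, p, significant
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def module_genes(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()


def adjacency(expr: pd.DataFrame, beta: float = 11.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |r|^beta, genes x genes.

    ``expr`` is genes x samples; zero-variance genes are removed with a
    warning since their correlation is undefined.
    """
    if expr.shape[1] < 3:
        raise InsufficientSamplesError("need >= 3 samples to build a network")
    sd = expr.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("removing %d zero-variance genes", int(flat.sum()))
        expr = expr.loc[~flat]
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(np.clip(adj, 0.0, 1.0), index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of an adjacency matrix.

    Neighborhood products use u != i, j; connectivity k_i excludes the
    diagonal; TOM_ii is defined as 1.
    """
    a = adj.to_numpy(dtype=float)
    s = a @ a
    # remove the diagonal contributions a_ii*a_ij and a_ij*a_jj (a_ii = 1)
    shared = s - 2.0 * a
    k = a.sum(axis=0) - 1.0
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.nan_to_num(tom, nan=0.0)
    return pd.DataFrame(np.clip(tom, 0.0, 1.0), index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Cut the average-linkage 1-TOM tree into size-ranked module labels.

    Clusters below ``min_module_size`` become ``unassigned``.  Labels are
    M1, M2, ... by decreasing size (ties by first member gene), which
    makes repeated runs on identical input yield identical labels.
    """
    genes = tom.index
    if config.min_module_size > len(genes):
        logger.warning("min_module_size exceeds gene count; all genes unassigned")
        return pd.Series(UNASSIGNED, index=genes, name="module")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= config.min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], int(np.argmax(labels.to_numpy() == c))))
    rename = {c: f"M{i+1}" for i, c in enumerate(order)}
    out = labels.map(lambda c: rename.get(c, UNASSIGNED))
    out.name = "module"
    return out


def module_eigengene(expr: pd.DataFrame, genes: list[str]) -> tuple[pd.Series, float]:
    """First PC of the gene-standardized module submatrix.

    Returns a unit-norm sample vector, sign-oriented so its mean
    correlation with member genes is positive, and the fraction of
    variance it explains.
    """
    if not genes:
        raise ValueError("empty module")
    sub = expr.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValueError("all module genes are constant; eigengene undefined")
    sub = sub[sd > 0]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    # orient: positive average correlation with member gene profiles
    if np.mean([np.corrcoef(eig, row)[0, 1] for row in z]) < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(eig, index=expr.columns, name="eigengene"), var_explained


def module_trait(eigengenes: pd.DataFrame, trait: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r and two-sided p (t, df = n-2) per module eigengene."""
    if eigengenes.shape[1] < 3:
        raise InsufficientSamplesError("need >= 3 samples for module-trait correlation")
    t = trait.reindex(eigengenes.columns)
    if t.isna().any():
        raise ValueError("trait missing for some samples")
    rows = {}
    for module, eig in eigengenes.iterrows():
        r, p = stats.pearsonr(eig.to_numpy(), t.to_numpy())
        rows[module] = {"r": r, "p": p, "significant": p < alpha}
    return pd.DataFrame.from_dict(rows, orient="index")


def mpv_transform(
    fpkm: pd.DataFrame, samples: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-hybrid mid-parent heterosis of expression, hybrids x genes.

    For each hybrid and gene: 100 * (H - MP) / MP with MP the mean of
    the two parental line-mean FPKMs.  Genes whose MP is zero for any
    hybrid are dropped with a warning.
    """
    line_means = {}
    for line, grp in samples.groupby("line"):
        line_means[line] = fpkm[grp["sample"].tolist()].mean(axis=1)
    rows = {}
    for hybrid, female, male in design[["hybrid", "female", "male"]].itertuples(index=False):
        for ln in (hybrid, female, male):
            if ln not in line_means:
                raise KeyError(f"line {ln!r} missing from the sample sheet")
        mp = (line_means[female] + line_means[male]) / 2.0
        rows[hybrid] = (100.0 * (line_means[hybrid] - mp), mp)
    mp_all = pd.DataFrame({h: mp for h, (_, mp) in rows.items()})
    ok = (mp_all > 0).all(axis=1)
    if (~ok).any():
        logger.warning("dropping %d genes with zero mid-parent expression", int((~ok).sum()))
    out = pd.DataFrame({h: num[ok] / mp_all.loc[ok, h] for h, (num, _) in rows.items()})
    return out.T  # hybrids x genes


def fit_modules(
    expr: pd.DataFrame,
    config: NetworkConfig | None = None,
    trait: pd.Series | None = None,
) -> ModuleResult:
    """Full network pass: adjacency -> TOM -> modules -> eigengenes.

    After the fixed-height cut, modules whose eigengenes correlate above
    ``merge_r`` are merged (transitively) and eigengenes recomputed.
    When a per-sample ``trait`` is supplied, module-trait correlations
    are attached.
    """
    config = config or NetworkConfig()
    adj = adjacency(expr, config.beta)
    tom = tom_similarity(adj)
    labels = detect_modules(tom, config)
    labels = _merge_correlated(expr.loc[adj.index], labels, config.merge_r)

    modules = [m for m in labels.unique() if m != UNASSIGNED]
    modules.sort(key=lambda m: (-int((labels == m).sum()), m))
    rename = {m: f"M{i+1}" for i, m in enumerate(modules)}
    labels = labels.map(lambda m: rename.get(m, UNASSIGNED))

    eigs, var_exp = {}, {}
    for m in sorted(set(labels) - {UNASSIGNED}, key=lambda s: int(s[1:])):
        eigs[m], var_exp[m] = module_eigengene(expr, labels.index[labels == m].tolist())
    eig_df = pd.DataFrame(eigs).T
    eig_df.index.name = "module"
    result = ModuleResult(
        labels=labels,
        eigengenes=eig_df,
        variance_explained=pd.Series(var_exp),
        config=config,
    )
    if trait is not None and not eig_df.empty:
        result.trait_cor = module_trait(eig_df, trait, alpha=config.alpha)
    return result


def _merge_correlated(expr: pd.DataFrame, labels: pd.Series, merge_r: float) -> pd.Series:
    """Union-merge modules whose eigengene correlation exceeds merge_r."""
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    if len(modules) < 2:
        return labels
    eigs = {m: module_eigengene(expr, labels.index[labels == m].tolist())[0] for m in modules}
    parent = {m: m for m in modules}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for i, mi in enumerate(modules):
        for mj in modules[i + 1 :]:
            r = np.corrcoef(eigs[mi], eigs[mj])[0, 1]
            if abs(r) > merge_r:
                parent[find(mj)] = find(mi)
    return labels.map(lambda m: find(m) if m != UNASSIGNED else m)
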