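"""Pairwise per-gene differential expression and DEG summaries.

The default test is a Welch two-sample t on log2(FPKM + 1); an optional
``method="nb"`` runs a negative-binomial Wald test on counts (moment
estimate of the dispersion, log-link contrast of group means).  DEGs are
called on the Benjamini-Hochberg adjusted p at a configurable threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR = 0.05
EPSILON = 1.0


class InsufficientReplicationError(ValueError):
    pass


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    method: str = "welch",
    epsilon: float = EPSILON,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-gene two-group test; rows are genes, columns replicates.

    Returns a table with ``mean_a``, ``mean_b``, ``log2fc`` (positive when
    B > A), ``p``, ``fdr`` and ``is_deg``.  Genes with zero variance in
    both groups get p = 1 when the means agree and p = 0 otherwise.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise InsufficientReplicationError("need >= 2 replicates per group")
    if not group_a.index.equals(group_b.index):
        b = group_b.reindex(group_a.index)
        if b.isna().any().any():
            raise ValueError("gene universes of the two groups differ")
        group_b = b

    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + epsilon) / (mean_a + epsilon))

    if method == "welch":
        la, lb = np.log2(a + epsilon), np.log2(b + epsilon)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
            p[degenerate & same] = 1.0
            p[degenerate & ~same] = 0.0
    elif method == "nb":
        p = _nb_wald(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")

    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "is_deg": fdr <= fdr_threshold,
        },
        index=group_a.index,
    )
    out.attrs["method"] = method
    out.attrs["fdr_threshold"] = fdr_threshold
    return out


def _nb_wald(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """NB Wald test on the log-mean contrast, moment dispersion estimate.

    Per gene, alpha is the moment estimate pooled over both groups
    (var = mu + alpha mu^2, floored at 0).  Var(log mu_hat) per group is
    (1/mu + alpha)/n by the delta method; the Wald z compares log means.
    """
    eps = 0.5  # continuity for empty groups
    mu_a = a.mean(axis=1) + eps
    mu_b = b.mean(axis=1) + eps
    na, nb = a.shape[1], b.shape[1]

    def alpha_hat(x, mu):
        v = x.var(axis=1, ddof=1)
        return np.clip((v - mu) / mu**2, 0.0, None)

    alpha = (alpha_hat(a, mu_a) * (na - 1) + alpha_hat(b, mu_b) * (nb - 1)) / (na + nb - 2)
    var = (1.0 / mu_a + alpha) / na + (1.0 / mu_b + alpha) / nb
    z = (np.log(mu_b) - np.log(mu_a)) / np.sqrt(var)
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class DEGSetCollection:
    """Per-hybrid DEG gene-id sets for the three trio comparisons."""

    fm: dict[str, set[str]] = field(default_factory=dict)  # female vs male
    fh: dict[str, set[str]] = field(default_factory=dict)  # female vs hybrid
    mh: dict[str, set[str]] = field(default_factory=dict)  # male vs hybrid

    def add(self, hybrid: str, fm: set[str], fh: set[str], mh: set[str]) -> None:
        self.fm[hybrid], self.fh[hybrid], self.mh[hybrid] = set(fm), set(fh), set(mh)

    def parent_hybrid_union(self, hybrid: str) -> set[str]:
        return self.fh[hybrid] | self.mh[hybrid]


def deg_ratio(collection: DEGSetCollection, hybrid: str) -> float:
    """Percent of parent-vs-parent DEGs also differential vs the hybrid.

    100 * |FM intersect (FH union MH)| / |FM|.
    """
    fm = collection.fm[hybrid]
    if not fm:
        raise ValueError(f"{hybrid}: no parent-vs-parent DEGs; ratio undefined")
    return 100.0 * len(fm & (collection.fh[hybrid] | collection.mh[hybrid])) / len(fm)


def group_columns(samples: pd.DataFrame, line: str) -> list[str]:
    return samples.loc[samples["line"] == line, "sample"].tolist()


def trio_de(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    female: str,
    male: str,
    hybrid: str,
    method: str = "welch",
    fdr_threshold: float = DEFAULT_FDR,
) -> dict[str, pd.DataFrame]:
    """Run the three trio comparisons F-vs-M, F-vs-H, M-vs-H.

    Comparison keys are ``fm``, ``fh``, ``mh``; in each, group A is the
    first-named material so ``log2fc`` is positive when the second is
    higher.
    """
    cols = {ln: group_columns(samples, ln) for ln in (female, male, hybrid)}
    for ln, cs in cols.items():
        if len(cs) < 2:
            raise InsufficientReplicationError(f"line {ln}: <2 replicates in sample sheet")
    return {
        "fm": de_test(fpkm[cols[female]], fpkm[cols[male]], method=method, fdr_threshold=fdr_threshold),
        "fh": de_test(fpkm[cols[female]], fpkm[cols[hybrid]], method=method, fdr_threshold=fdr_threshold),
        "mh": de_test(fpkm[cols[male]], fpkm[cols[hybrid]], method=method, fdr_threshold=fdr_threshold),
    }


def replicate_correlation(
    fpkm: pd.DataFrame, samples: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Pearson correlation of log2(FPKM+1) for every sample pair.

    Returns the full correlation matrix (constant samples reported as
    NaN) and, when a sample sheet is given, the minimum within-material
    replicate correlation per line — the replicate-quality summary.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need >= 2 samples for replicate correlation")
    log = np.log2(fpkm + 1.0)
    corr = log.corr(method="pearson")  # pandas yields NaN for constant columns
    if samples is None:
        return corr, None
    mins = {}
    for line, grp in samples.groupby("line"):
        reps = [s for s in grp["sample"] if s in corr.index]
        if len(reps) < 2:
            continue
        vals = [corr.loc[x, y] for x, y in itertools.combinations(reps, 2)]
        mins[line] = float(np.nanmin(vals)) if not all(pd.isna(vals)) else np.nan
    return corr, pd.Series(mins, name="min_replicate_r")
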