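"""Seeded synthetic trio data with planted truth.

The generator emulates a complete diallel crossing design: ``n_female``
female inbred lines crossed with ``n_male`` male lines, every line and
hybrid sequenced in ``replicates`` biological replicates.  Counts are
negative binomial (variance = mu + alpha * mu^2), the standard bulk
RNA-seq noise model.  Each gene is planted into one of the 12 trio
expression patterns (or left null): the planted female/male/hybrid group
means satisfy the pattern's ordering exactly before noise, with "=" as
exact equality and "<" driven by ``parent_log2fc`` / ``hybrid_log2fc``.
Patterns are planted globally — all female lines share the planted
female level, all male lines the male level, all hybrids the hybrid
level — so every trio exhibits the same planted pattern for a gene.

A plant-gross-weight-like trait is planted per line, with hybrids given
mid-parent heterosis values drawn from strong / middle / weak bands, and
a separate Gaussian latent-factor generator plants coexpression modules
with a trait correlated to the first module's factor.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PATTERNS = tuple(f"P{i}" for i in range(1, 13))

# Signal split across P1..P12 follows the published per-pattern average
# gene counts of the 16-hybrid cabbage study (401, 414, 1143, ...).
_PATTERN_WEIGHTS = np.array(
    [401, 414, 1143, 1391, 669, 1184, 134, 19, 19, 210, 18, 41], dtype=float
)
_PATTERN_WEIGHTS /= _PATTERN_WEIGHTS.sum()
DEFAULT_PATTERN_MIX = {"null": 0.7, **{p: 0.3 * w for p, w in zip(PATTERNS, _PATTERN_WEIGHTS)}}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generator.

    Defaults mirror the emulated study: a 4 x 4 diallel (16 hybrids),
    three biological replicates per material, library sizes log-uniform
    over 5-15 million mapped reads, gene lengths uniform 500-5000 bp.
    """

    n_genes: int = 2000
    n_female_lines: int = 4
    n_male_lines: int = 4
    replicates: int = 3
    # NB alpha: var = mu + alpha mu^2.  0.01 corresponds to a biological
    # CV of 0.1, the standard figure for genetically identical material
    # (here: pooled samples of inbred lines and their F1s).
    dispersion: float = 0.01
    baseline_mean: float = 300.0  # expected count at reference depth
    parent_log2fc: float = 2.0
    hybrid_log2fc: float = 2.0
    pattern_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_range: tuple[float, float] = (5e6, 15e6)
    # trait (plant gross weight analogue, kg)
    trait_parent_mean: float = 3.0
    trait_parent_sd: float = 0.3
    n_strong: int = 4
    n_weak: int = 4
    mpv_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"strong": (150.0, 240.0), "middle": (50.0, 130.0), "weak": (10.0, 35.0)}
    )
    # coexpression generator
    n_coexpr_samples: int = 24
    module_spec: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(100, 0.9, 0.3), (100, 0.9, 0.3)]
    )
    trait_module_r: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_female_lines <= 0 or self.n_male_lines <= 0:
            raise ConfigurationError("gene and line counts must be positive")
        if self.replicates < 2:
            raise ConfigurationError("need >= 2 replicates per material")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(f"pattern_mix must sum to 1, got {total}")
        bad = set(self.pattern_mix) - set(PATTERNS) - {"null"}
        if bad:
            raise ConfigurationError(f"unknown pattern labels {sorted(bad)}")
        if min(self.pattern_mix.values()) < 0:
            raise ConfigurationError("pattern_mix proportions must be nonnegative")
        if self.baseline_mean <= 0 or min(self.gene_length_range) <= 0 or min(self.library_size_range) <= 0:
            raise ConfigurationError("means, lengths and library sizes must be positive")
        if any(size <= 0 for size, _, _ in self.module_spec):
            raise ConfigurationError("module sizes must be positive")


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying a simulated dataset."""

    gene_truth: pd.DataFrame  # pattern, deg_fm, deg_fh, deg_mh per gene
    line_traits: pd.Series | None = None  # true trait value per line/hybrid
    hybrid_groups: pd.Series | None = None  # planted strong/middle/weak
    module_members: dict[str, list[str]] | None = None


def _line_codes(n_female: int, n_male: int) -> tuple[list[str], list[str]]:
    letters = string.ascii_uppercase
    if n_female + n_male <= len(letters):
        return list(letters[:n_female]), list(letters[n_female : n_female + n_male])
    return [f"F{i+1}" for i in range(n_female)], [f"M{j+1}" for j in range(n_male)]


def _planted_levels(pattern: str, parent_fc: float, hybrid_fc: float) -> tuple[float, float, float]:
    """Relative (female, male, hybrid) means for a planted pattern.

    Baseline 1.0; "<" between parents spans ``parent_fc`` log2 units,
    hybrids outside the parental range extend by ``hybrid_fc`` units, and
    "=" is exact equality.
    """
    up, hy = 2.0**parent_fc, 2.0**hybrid_fc
    mid = 2.0 ** (parent_fc / 2.0)
    table = {
        "null": (1, 1, 1),
        "P1": (up, 1, mid),  # F>M, M<H<F
        "P2": (1, up, mid),  # F<M, F<H<M
        "P3": (1, up, up),  # F<M, H=M
        "P4": (up, 1, 1),  # F>M, H=M
        "P5": (up, 1, up),  # F>M, H=F
        "P6": (1, up, 1),  # F<M, H=F
        "P7": (1, 1, 1 / hy),  # F=M, H below both
        "P8": (up, 1, 1 / hy),
        "P9": (1, up, 1 / hy),
        "P10": (1, 1, hy),  # F=M, H above both
        "P11": (up, 1, up * hy),
        "P12": (1, up, up * hy),
    }
    return table[pattern]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with var = mu + alpha mu^2 via gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha <= 0
    out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        shape = 1.0 / alpha[~poisson]
        lam = rng.gamma(shape, mean[~poisson] / shape)
        out[~poisson] = rng.poisson(lam)
    return out


def simulate_trio_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate NB counts for a full diallel with planted patterns.

    Returns ``(counts, sample_sheet, trio_design, truth)``.  Counts carry
    ``attrs`` entries ``layer="counts"``, ``gene_lengths`` and
    ``library_sizes`` so FPKM conversion can round-trip exactly.
    """
    rng = np.random.default_rng(config.seed)
    females, males = _line_codes(config.n_female_lines, config.n_male_lines)
    hybrids = [f + m for f in females for m in males]
    lines = females + males + hybrids
    roles = (
        ["female-parent"] * len(females) + ["male-parent"] * len(males) + ["hybrid"] * len(hybrids)
    )

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    labels = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[k] for k in labels])
    assigned = rng.choice(labels, size=config.n_genes, p=probs)

    # per-gene baseline expression level, log-normal spread around baseline_mean
    base = config.baseline_mean * rng.lognormal(0.0, 0.7, size=config.n_genes)
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes)
    lo, hi = config.library_size_range
    n_samples = len(lines) * config.replicates
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    ref_lib = float(np.sqrt(lo * hi))

    levels = np.array(
        [_planted_levels(p, config.parent_log2fc, config.hybrid_log2fc) for p in assigned]
    )  # genes x (F, M, H)
    role_col = {"female-parent": 0, "male-parent": 1, "hybrid": 2}

    sample_ids, sample_rows, cols = [], [], []
    alpha = np.full(config.n_genes, float(config.dispersion))
    si = 0
    for line, role in zip(lines, roles):
        mu_line = base * levels[:, role_col[role]]
        for rep in range(1, config.replicates + 1):
            sid = f"{line}_r{rep}"
            sample_ids.append(sid)
            sample_rows.append({"sample": sid, "line": line, "role": role, "replicate": rep})
            mu = mu_line * lib_sizes[si] / ref_lib
            cols.append(_nb_draw(rng, mu, alpha))
            si += 1

    counts = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    counts.attrs["layer"] = "counts"
    counts.attrs["gene_lengths"] = pd.Series(lengths, index=counts.index)
    counts.attrs["library_sizes"] = pd.Series(lib_sizes, index=sample_ids)

    samples = pd.DataFrame(sample_rows)
    design = pd.DataFrame(
        {"hybrid": hybrids, "female": [f for f in females for _ in males], "male": males * len(females)}
    )

    f_lv, m_lv, h_lv = levels[:, 0], levels[:, 1], levels[:, 2]
    gene_truth = pd.DataFrame(
        {
            "pattern": assigned,
            "deg_fm": f_lv != m_lv,
            "deg_fh": f_lv != h_lv,
            "deg_mh": m_lv != h_lv,
        },
        index=counts.index,
    )

    # planted trait: parents around trait_parent_mean, hybrids by planted MPV band
    parent_vals = pd.Series(
        rng.normal(config.trait_parent_mean, config.trait_parent_sd, size=len(females) + len(males)).clip(min=0.1),
        index=females + males,
    )
    order = rng.permutation(len(hybrids))
    groups = pd.Series("middle", index=pd.Index(hybrids, name="hybrid"))
    groups.iloc[order[: config.n_strong]] = "strong"
    groups.iloc[order[config.n_strong : config.n_strong + config.n_weak]] = "weak"
    hybrid_vals = {}
    for h, f, m in design.itertuples(index=False):
        lo_b, hi_b = config.mpv_bands[groups[h]]
        mpv = rng.uniform(lo_b, hi_b)
        mp = (parent_vals[f] + parent_vals[m]) / 2.0
        hybrid_vals[h] = mp * (1.0 + mpv / 100.0)
    line_traits = pd.concat([parent_vals, pd.Series(hybrid_vals)])
    line_traits.index.name = "line"

    truth = SimulationTruth(gene_truth=gene_truth, line_traits=line_traits, hybrid_groups=groups)
    return counts, samples, design, truth


def counts_to_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | np.ndarray | None = None,
    library_sizes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (gene length [bp] * mapped library size).

    ``gene_lengths``/``library_sizes`` default to values stashed in
    ``counts.attrs``; library sizes fall back to per-sample column sums.
    """
    if gene_lengths is None:
        gene_lengths = counts.attrs.get("gene_lengths")
        if gene_lengths is None:
            raise ValueError("gene_lengths required (not found in counts.attrs)")
    if isinstance(gene_lengths, pd.Series):
        if set(gene_lengths.index) != set(counts.index):
            raise ValueError("gene_lengths does not match the gene universe")
        lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
    else:
        lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("gene_lengths does not match the gene universe")
    if library_sizes is None:
        library_sizes = counts.attrs.get("library_sizes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    libs = np.asarray(pd.Series(library_sizes).reindex(counts.columns) if isinstance(library_sizes, pd.Series) else library_sizes, dtype=float)
    if libs.shape[0] != counts.shape[1]:
        raise ValueError("library_sizes does not match the sample set")
    if (lengths <= 0).any() or (libs <= 0).any():
        raise ValueError("gene lengths and library sizes must be positive")
    fpkm = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * libs[None, :])
    out = pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)
    out.attrs["layer"] = "FPKM"
    return out


def simulate_coexpression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Gaussian latent-factor modules plus a trait tracking module 1.

    Each ``(size, loading, noise_sd)`` entry of ``module_spec`` plants a
    module whose genes are ``loading * factor + N(0, noise_sd)`` across
    ``n_coexpr_samples`` samples; remaining genes are independent noise.
    The trait correlates with the first module's factor at
    ``trait_module_r`` in expectation.
    """
    if not config.module_spec:
        raise ConfigurationError("module_spec must be non-empty")
    if sum(size for size, _, _ in config.module_spec) > config.n_genes:
        raise ConfigurationError("module sizes exceed n_genes")
    rng = np.random.default_rng(config.seed)
    n_s = config.n_coexpr_samples
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples = [f"s{j:02d}" for j in range(n_s)]

    expr = rng.normal(0.0, 1.0, size=(config.n_genes, n_s))
    members: dict[str, list[str]] = {}
    start = 0
    factors = []
    for mi, (size, loading, noise_sd) in enumerate(config.module_spec, start=1):
        z = rng.normal(0.0, 1.0, size=n_s)
        factors.append(z)
        block = loading * z[None, :] + rng.normal(0.0, noise_sd, size=(size, n_s))
        expr[start : start + size] = block
        members[f"M{mi}"] = genes[start : start + size]
        start += size

    r = float(config.trait_module_r)
    trait = r * factors[0] + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(0.0, 1.0, size=n_s)
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    expr_df.attrs["layer"] = "latent"
    truth = SimulationTruth(
        gene_truth=pd.DataFrame(
            {"module": [next((m for m, gs in members.items() if g in set(gs)), "none") for g in genes]},
            index=expr_df.index,
        ),
        module_members=members,
    )
    # membership lookup above is O(n*m); fine at simulation scale
    return expr_df, pd.Series(trait, index=samples, name="trait"), truth
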