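"""End-to-end orchestration: simulate/read -> DE -> patterns -> heterosis
-> common DEGs -> enrichment -> coexpression modules -> report bundle.

Every stage writes headered TSVs that round-trip through
:mod:`heteroseq.io`, plus a JSON run manifest (package version, seed and
thresholds) sufficient to reproduce the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, de, heterosis, patterns
from .enrich import hypergeometric_enrichment, top_terms
from .io import (
    AnnotationMap,
    read_annotations,
    read_expression,
    read_sample_sheet,
    read_traits,
    read_trio_design,
    write_expression,
    write_table,
)
from .network import NetworkConfig, fit_modules, mpv_transform
from .simulate import SimulationConfig, counts_to_fpkm, simulate_trio_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and settings for a full run."""

    out_dir: str = "heteroseq_out"
    expression: str | None = None  # FPKM TSV; None -> simulate
    samples: str | None = None
    design: str | None = None
    traits: str | None = None
    annotations: str | None = None
    fdr: float = de.DEFAULT_FDR
    de_method: str = "welch"
    strong_cut: float = heterosis.STRONG_CUT
    weak_cut: float = heterosis.WEAK_CUT
    alpha: float = 0.05
    degset: str = "union"  # fh|mh|union|fm for group-common DEGs
    network: NetworkConfig = field(default_factory=NetworkConfig)
    network_mode: str = "raw"  # raw|mpv
    run_network: bool = True
    seed: int = 0
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if self.strong_cut <= self.weak_cut:
            raise ValueError("strong_cut must exceed weak_cut")
        if not (0 < self.fdr < 1) or not (0 < self.alpha < 1):
            raise ValueError("fdr and alpha must lie in (0, 1)")
        if self.degset not in {"fh", "mh", "union", "fm"}:
            raise ValueError(f"unknown degset {self.degset!r}")
        for path in (self.expression, self.samples, self.design, self.traits, self.annotations):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _deg_set(calls: de.DEGSetCollection, hybrid: str, kind: str) -> set[str]:
    return {
        "fm": lambda: calls.fm[hybrid],
        "fh": lambda: calls.fh[hybrid],
        "mh": lambda: calls.mh[hybrid],
        "union": lambda: calls.parent_hybrid_union(hybrid),
    }[kind]()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the report bundle, return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "package": "heteroseq",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr,
            "strong_cut": config.strong_cut,
            "weak_cut": config.weak_cut,
            "alpha": config.alpha,
        },
        "de_method": config.de_method,
        "degset": config.degset,
        "network": asdict(config.network),
        "network_mode": config.network_mode,
    }

    t0 = time.perf_counter()
    if config.expression is None:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        manifest["simulation"] = {
            k: v for k, v in asdict(sim).items() if not isinstance(v, (dict, list))
        }
        counts, samples, design, truth = simulate_trio_counts(sim)
        fpkm = counts_to_fpkm(counts)
        traits = truth.line_traits
        write_expression(counts, out / "counts.tsv")
        write_table(samples, out / "samples.tsv", index=False)
        write_table(design, out / "design.tsv", index=False)
        write_table(truth.gene_truth, out / "truth_genes.tsv")
        traits.rename("value").to_frame().to_csv(out / "traits.tsv", sep="\t")
        annot = None
    else:
        fpkm = read_expression(config.expression)
        samples = read_sample_sheet(config.samples)
        design = read_trio_design(config.design)
        traits = read_traits(config.traits) if config.traits else None
        annot = read_annotations(config.annotations) if config.annotations else None
    write_expression(fpkm, out / "fpkm.tsv")
    timings["input"] = time.perf_counter() - t0

    # replicate QC
    t0 = time.perf_counter()
    corr, rep_min = de.replicate_correlation(fpkm, samples)
    write_table(corr, out / "replicate_correlation.tsv")
    if rep_min is not None:
        rep_min.to_frame().to_csv(out / "replicate_min_correlation.tsv", sep="\t")
    timings["qc"] = time.perf_counter() - t0

    # per-trio DE + DEG-count summary with the DEG ratio
    t0 = time.perf_counter()
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    calls = de.DEGSetCollection()
    trio_tables: dict[str, dict[str, pd.DataFrame]] = {}
    summary_rows = []
    for hybrid, female, male in design[["hybrid", "female", "male"]].itertuples(index=False):
        tables = de.trio_de(
            fpkm, samples, female, male, hybrid,
            method=config.de_method, fdr_threshold=config.fdr,
        )
        trio_tables[hybrid] = tables
        for key, tab in tables.items():
            write_table(tab, de_dir / f"{hybrid}_{key}.tsv")
        sets = {k: set(t.index[t["is_deg"]]) for k, t in tables.items()}
        calls.add(hybrid, sets["fm"], sets["fh"], sets["mh"])
        ratio = de.deg_ratio(calls, hybrid) if sets["fm"] else float("nan")
        summary_rows.append(
            {
                "hybrid": hybrid,
                "female_vs_male": len(sets["fm"]),
                "female_vs_hybrid": len(sets["fh"]),
                "male_vs_hybrid": len(sets["mh"]),
                "deg_ratio": round(ratio, 2),
            }
        )
    deg_summary = pd.DataFrame(summary_rows).set_index("hybrid")
    write_table(deg_summary, out / "deg_counts.tsv")
    timings["de"] = time.perf_counter() - t0

    # pattern classification
    t0 = time.perf_counter()
    pat_dir = out / "patterns"
    pat_dir.mkdir(exist_ok=True)
    counts_by_hybrid = {}
    pct_rows = {}
    for hybrid, tables in trio_tables.items():
        table = patterns.classify_trio(tables["fm"], tables["fh"], tables["mh"])
        write_table(table, pat_dir / f"{hybrid}_patterns.tsv")
        if table.empty:
            continue
        cnt, pct = patterns.summarize_patterns(table)
        counts_by_hybrid[hybrid] = cnt
        pct_rows[hybrid] = pct
    if counts_by_hybrid:
        cbh = pd.DataFrame(counts_by_hybrid).T
        cbh.index.name = "hybrid"
        pattern_cols = [c for c in cbh.columns if c != patterns.UNCLASSIFIED]
        summary = cbh.copy()
        if len(cbh) >= 2:
            agg = patterns.aggregate_across_hybrids(cbh[pattern_cols])
            summary.loc["average", pattern_cols] = agg["average"]
            summary.loc["standard_error", pattern_cols] = agg["standard_error"]
        write_table(summary, out / "pattern_counts.tsv")
        pct_df = pd.DataFrame(pct_rows).T
        pct_df.index.name = "hybrid"
        write_table(pct_df.round(2), out / "category_percentages.tsv")
    timings["patterns"] = time.perf_counter() - t0

    # heterosis grouping + group-common DEGs
    t0 = time.perf_counter()
    if traits is not None:
        het = heterosis.heterosis_table(traits, design, config.strong_cut, config.weak_cut)
        write_table(het.round(2), out / "heterosis.tsv")
        for group in ("strong", "weak"):
            hybrids = het.index[het["group"] == group].tolist()
            if not hybrids:
                continue
            sets = {h: _deg_set(calls, h, config.degset) for h in hybrids}
            common, regions = heterosis.common_degs(sets)
            write_table(regions, out / f"venn_{group}.tsv", index=False)
            pd.Series(sorted(common), name="gene_id").to_csv(
                out / f"common_degs_{group}.tsv", sep="\t", index=False
            )
            if annot is not None and common:
                enr = hypergeometric_enrichment(common, annot.restrict(set(fpkm.index)), config.alpha)
                write_table(enr, out / f"enrichment_{group}.tsv")
                write_table(top_terms(enr), out / f"enrichment_{group}_top.tsv")
        manifest["groups"] = het["group"].value_counts().to_dict()
    timings["heterosis"] = time.perf_counter() - t0

    # coexpression modules
    t0 = time.perf_counter()
    if config.run_network and traits is not None:
        if config.network_mode == "mpv":
            expr_net = mpv_transform(fpkm, samples, design).T  # genes x hybrids
            het = heterosis.heterosis_table(traits, design, config.strong_cut, config.weak_cut)
            trait_vec = het["MPV"].reindex(expr_net.columns)
        else:
            expr_net = fpkm
            trait_vec = pd.Series(
                {s: traits[ln] for s, ln in samples.set_index("sample")["line"].items()}
            ).reindex(fpkm.columns)
        result = fit_modules(expr_net, config.network, trait=trait_vec)
        result.labels.to_frame().to_csv(out / "modules.tsv", sep="\t")
        write_table(result.eigengenes, out / "eigengenes.tsv")
        if result.trait_cor is not None:
            write_table(result.trait_cor.round(4), out / "module_trait.tsv")
        manifest["n_modules"] = int(len(result.eigengenes))
    timings["network"] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return manifest
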