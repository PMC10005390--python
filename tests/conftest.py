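import pandas as pd
import pytest

from heteroseq.simulate import SimulationConfig, counts_to_fpkm, simulate_trio_counts


@pytest.fixture(scope="session")
def small_trio():
    """A 500-gene diallel simulation shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=500, seed=11)
    counts, samples, design, truth = simulate_trio_counts(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "fpkm": counts_to_fpkm(counts),
        "samples": samples,
        "design": design,
        "truth": truth,
    }


@pytest.fixture()
def toy_fpkm():
    """Two genes, one trio, two replicates each; exact group means."""
    fpkm = pd.DataFrame(
        {
            "A_r1": [2.0, 5.0], "A_r2": [2.0, 5.0],
            "E_r1": [6.0, 5.0], "E_r2": [6.0, 5.0],
            "AE_r1": [6.0, 5.0], "AE_r2": [6.0, 5.0],
        },
        index=pd.Index(["g1", "g2"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "sample": fpkm.columns,
            "line": ["A", "A", "E", "E", "AE", "AE"],
            "role": ["female-parent"] * 2 + ["male-parent"] * 2 + ["hybrid"] * 2,
            "replicate": [1, 2] * 3,
        }
    )
    design = pd.DataFrame({"hybrid": ["AE"], "female": ["A"], "male": ["E"]})
    return fpkm, samples, design
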