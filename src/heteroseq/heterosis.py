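"""Mid-parent heterosis, strong/middle/weak grouping, and group-common DEGs.

Mid-parent heterosis of a trait (here plant gross weight, PGW) is

    MPV = 100 * (F1 - MP) / MP,    MP = (female + male) / 2

with F1 the hybrid's trait value.  Hybrids grade into heterosis groups
by MPV: above ``strong_cut`` (default 140) strong, below ``weak_cut``
(default 40) weak, otherwise middle; the boundary values themselves are
middle since the published rule uses strict inequalities.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

STRONG_CUT = 140.0
WEAK_CUT = 40.0


def mpv(f1: float, parent_f: float, parent_m: float) -> float:
    """Percent mid-parent heterosis; requires a positive mid-parent mean."""
    mp = (parent_f + parent_m) / 2.0
    if mp <= 0:
        raise ValueError(f"mid-parent value must be positive, got {mp}")
    return 100.0 * (f1 - mp) / mp


def classify_heterosis(
    value: float, strong_cut: float = STRONG_CUT, weak_cut: float = WEAK_CUT
) -> str:
    if not np.isfinite(value):
        raise ValueError("MPV must be finite")
    if strong_cut <= weak_cut:
        raise ValueError("strong_cut must exceed weak_cut")
    if value > strong_cut:
        return "strong"
    if value < weak_cut:
        return "weak"
    return "middle"


def heterosis_table(
    traits: pd.Series,
    design: pd.DataFrame,
    strong_cut: float = STRONG_CUT,
    weak_cut: float = WEAK_CUT,
) -> pd.DataFrame:
    """Per-hybrid F1, MP, MPV and heterosis group.

    ``traits`` maps line -> trait value (replicate-level values should be
    averaged upstream); ``design`` has columns hybrid/female/male.
    """
    rows = []
    for hybrid, female, male in design[["hybrid", "female", "male"]].itertuples(index=False):
        for ln in (hybrid, female, male):
            if ln not in traits.index:
                raise KeyError(f"no trait value for line {ln!r}")
        f1 = float(traits[hybrid])
        mp = (float(traits[female]) + float(traits[male])) / 2.0
        value = mpv(f1, float(traits[female]), float(traits[male]))
        rows.append(
            {
                "hybrid": hybrid,
                "F1": f1,
                "MP": mp,
                "MPV": value,
                "group": classify_heterosis(value, strong_cut, weak_cut),
            }
        )
    return pd.DataFrame(rows).set_index("hybrid")


def common_degs(deg_sets: dict[str, set[str]]) -> tuple[set[str], pd.DataFrame]:
    """Intersection of per-hybrid DEG sets plus all Venn region sizes.

    Returns ``(common, regions)`` where ``regions`` has one row per
    non-empty membership combination with the count of genes exclusive
    to exactly that combination of hybrids.
    """
    if not deg_sets:
        raise ValueError("need at least one DEG set")
    names = sorted(deg_sets)
    common = set.intersection(*(set(deg_sets[n]) for n in names))
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(deg_sets[n]) for n in combo))
            outside = set().union(*(set(deg_sets[n]) for n in names if n not in combo)) if r < len(names) else set()
            rows.append({"members": "&".join(combo), "size": len(inside - outside)})
    return common, pd.DataFrame(rows)
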