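"""Allele-specific expression classification from reciprocal crosses.

Zygotic-only ortholog pairs are classified by the pair of log2 allele ratios
measured in the forward and reverse crosses: pairs favoring the same species'
allele in both crosses land in quadrants I/III (species-of-origin effects)
while pairs favoring whichever allele was maternally (paternally) inherited
land in quadrants II/IV (parent-of-origin effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EXPRESSED_FPKM
from .counts import origin_to_species
from .dynamics import FPKMTable

EARLY_STAGES = ("8-cell", "16-cell", "32-cell")
TRANSITION_STAGES = ("64-cell", "112-cell")
# the late evaluation window still includes the 112-cell stage
LATE_STAGES = ("112-cell", "midG", "earN", "lateN")
PRE_ZGA_STAGES = ("1-cell", "2-cell", "4-cell")

EVAL_STAGES = {
    "early": EARLY_STAGES,
    "transition": TRANSITION_STAGES,
    "late": LATE_STAGES,
}


def allele_fpkm(fpkm_forward: FPKMTable, fpkm_reverse: FPKMTable) -> pd.DataFrame:
    """Merge both crosses' FPKM tables onto allele labels.

    Long-form frame with columns pair_id, allele (A/B), cross, stage, fpkm;
    the maternal origin maps to species A in the forward cross and species B
    in the reverse cross.
    """
    frames = []
    for cross, table in (("forward", fpkm_forward), ("reverse", fpkm_reverse)):
        df = table.data.copy()
        df["allele"] = [origin_to_species(o, cross) for o in df["origin"]]
        df["cross"] = cross
        frames.append(df[["pair_id", "allele", "cross", "stage", "fpkm"]])
    return pd.concat(frames, ignore_index=True)


def _wide(expr: pd.DataFrame) -> pd.DataFrame:
    # dropna=False keeps stages whose sample had zero depth (NaN FPKM)
    return expr.pivot_table(index="pair_id", columns=["cross", "allele", "stage"],
                            values="fpkm", aggfunc="first", dropna=False)


def zygotic_only(expr: pd.DataFrame, threshold: float = EXPRESSED_FPKM
                 ) -> set[str]:
    """Pairs silent at the 1/2/4-cell stages but expressed later, in both crosses."""
    wide = _wide(expr)
    stages = wide.columns.get_level_values("stage").unique()
    if missing := set(PRE_ZGA_STAGES) - set(stages):
        raise ValueError(f"missing pre-ZGA stages: {sorted(missing)}")
    later = [s for s in stages if s not in PRE_ZGA_STAGES]
    keep = pd.Series(True, index=wide.index)
    for cross in ("forward", "reverse"):
        sub = wide[cross]
        early = sub.loc[:, (slice(None), list(PRE_ZGA_STAGES))]
        keep &= (early.fillna(0.0) < threshold).all(axis=1)
        late = sub.loc[:, (slice(None), later)]
        keep &= (late.fillna(0.0) >= threshold).any(axis=1)
    return set(keep.index[keep])


def first_expression_stage(expr: pd.DataFrame, pair_id: str,
                           stages: list[str],
                           threshold: float = EXPRESSED_FPKM) -> str:
    """Earliest stage at which any allele in any cross reaches the threshold."""
    sub = expr[expr["pair_id"] == pair_id]
    for stage in stages:
        vals = sub.loc[sub["stage"] == stage, "fpkm"]
        if (vals.fillna(0.0) >= threshold).any():
            return stage
    raise ValueError(f"pair {pair_id!r} is never expressed")


def timing_class(expr: pd.DataFrame, pair_id: str, stages: list[str],
                 threshold: float = EXPRESSED_FPKM) -> str:
    """Expression-timing class of a zygotic-only pair.

    First expression at 8/16/32-cell -> early; 64/112-cell -> transition
    (the boundary 112-cell stage is broken toward the earlier class); later
    stages -> late.
    """
    first = first_expression_stage(expr, pair_id, stages, threshold)
    if first in EARLY_STAGES:
        return "early"
    if first in TRANSITION_STAGES:
        return "transition"
    return "late"


def quadrant_classify(rf: float, rr: float, delta: float = 1.0) -> str:
    """Quadrant category from the forward/reverse log2 allele ratios.

    Both ratios >= delta -> A_dominant (quadrant I); both <= -delta ->
    B_dominant (III); forward-high/reverse-low -> maternal_dominant (II);
    forward-low/reverse-high -> paternal_dominant (IV); else unbiased.
    """
    if not (np.isfinite(rf) and np.isfinite(rr)):
        raise ValueError("log ratios must be finite")
    if rf >= delta and rr >= delta:
        return "A_dominant"
    if rf <= -delta and rr <= -delta:
        return "B_dominant"
    if rf >= delta and rr <= -delta:
        return "maternal_dominant"
    if rf <= -delta and rr >= delta:
        return "paternal_dominant"
    return "unbiased"


def ase_records(expr: pd.DataFrame, pairs: set[str] | list[str],
                stages: list[str], delta: float = 1.0, epsilon: float = 0.1,
                threshold: float = EXPRESSED_FPKM) -> pd.DataFrame:
    """Per-pair log2 allele ratios, timing class and quadrant category.

    Rf (Rr) is log2((A + eps) / (B + eps)) of the mean FPKM over the timing
    class's evaluation stages in the forward (reverse) cross.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    wide = _wide(expr)
    rows = []
    for pair_id in sorted(pairs):
        timing = timing_class(expr, pair_id, stages, threshold)
        eval_stages = [s for s in EVAL_STAGES[timing] if s in stages]
        ratios = {}
        for cross in ("forward", "reverse"):
            mean_a = wide.loc[pair_id, (cross, "A", eval_stages)].mean()
            mean_b = wide.loc[pair_id, (cross, "B", eval_stages)].mean()
            ratios[cross] = float(np.log2((mean_a + epsilon) / (mean_b + epsilon)))
        category = quadrant_classify(ratios["forward"], ratios["reverse"], delta)
        rows.append((pair_id, ratios["forward"], ratios["reverse"], timing,
                     category))
    return pd.DataFrame(rows, columns=["pair_id", "Rf", "Rr", "timing",
                                       "category"])


@dataclass
class ASESummary:
    counts: pd.Series
    species_pct: float | None
    parent_pct: float | None
    all_unbiased: bool


def summarize(categories: pd.Series | list[str]) -> ASESummary:
    """Counts per category plus the species-/parent-of-origin percentages.

    Percentages are over classified (non-unbiased) pairs and rounded to the
    nearest integer; if everything is unbiased they are undefined (flagged).
    """
    cats = pd.Series(list(categories), dtype=object)
    counts = cats.value_counts()
    species = int(counts.get("A_dominant", 0) + counts.get("B_dominant", 0))
    parent = int(counts.get("maternal_dominant", 0)
                 + counts.get("paternal_dominant", 0))
    classified = species + parent
    if classified == 0:
        return ASESummary(counts, None, None, True)
    return ASESummary(counts,
                      round(100.0 * species / classified),
                      round(100.0 * parent / classified),
                      False)
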