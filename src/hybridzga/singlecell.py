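"""Single-cell statistics for housekeeping-gene reactivation.

Covers raw-matrix filtering, definition of the housekeeping gene set from
bulk FPKM profiles, per-cell paternal housekeeping transcript ratios,
between-lineage comparisons with Bonferroni-corrected t-tests, marker-based
lineage annotation, and the correlation of reactivation with cell stiffness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .config import EXPRESSED_FPKM, STAGE_GENE_WINDOWS
from .counts import paternal_species
from .dynamics import FPKMTable

log = logging.getLogger(__name__)


def filter_cells_genes(adata: ad.AnnData, min_cells_per_gene: int = 3,
                       min_genes_per_cell: int = 250,
                       stage_windows: dict[str, tuple[int, int]] | None = None
                       ) -> ad.AnnData:
    """Filter a raw cell matrix: genes first, then cells, each once.

    Genes are kept when expressed (count > 0) in at least ``min_cells_per_gene``
    cells. Cells are kept when their detected-gene count lies within the
    stage's window, with the floor raised to ``min_genes_per_cell``; stages
    without a configured window fall back to the floor alone (logged).
    """
    windows = STAGE_GENE_WINDOWS if stage_windows is None else stage_windows
    X = np.asarray(adata.X)
    gene_ok = (X > 0).sum(axis=0) >= min_cells_per_gene
    adata = adata[:, gene_ok].copy()
    X = np.asarray(adata.X)
    detected = (X > 0).sum(axis=1)
    lo = np.full(adata.n_obs, min_genes_per_cell, dtype=float)
    hi = np.full(adata.n_obs, np.inf)
    for stage in adata.obs["stage"].unique():
        sel = (adata.obs["stage"] == stage).to_numpy()
        if stage in windows:
            wlo, whi = windows[stage]
            lo[sel] = max(min_genes_per_cell, wlo)
            hi[sel] = whi
        else:
            log.info("no detected-gene window for stage %r; floor only", stage)
    cell_ok = (detected >= lo) & (detected <= hi)
    return adata[cell_ok].copy()


def define_housekeeping(bulk: FPKMTable, cv_max: float = 1.0,
                        threshold: float = EXPRESSED_FPKM) -> set[str]:
    """Housekeeping pairs from the bulk maternal/paternal FPKM profiles.

    A pair qualifies when it is maternally expressed at the 1-cell stage,
    its paternal copy has been reactivated by the late-neurula stage, and the
    maternal profile is stable across stages (coefficient of variation at
    most ``cv_max``).
    """
    for required in ("1-cell", "lateN"):
        if required not in bulk.stages:
            raise ValueError(f"bulk table must span 1-cell..lateN; missing {required}")
    mat = bulk.wide("maternal")
    pat = bulk.wide("paternal")
    maternal_1cell = mat["1-cell"] >= threshold
    reactivated = pat["lateN"] >= threshold
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    stable = cv.fillna(np.inf) <= cv_max
    keep = maternal_1cell & reactivated & stable
    return set(keep.index[keep])


def cell_paternal_hk_ratio(adata: ad.AnnData, hk: set[str], cross: str
                           ) -> pd.Series:
    """Per-cell ratio of paternal housekeeping counts to all counts.

    Computed on raw counts (the ratio is invariant to per-cell scaling).
    Cells with zero total counts are excluded (logged).
    """
    pat_sp = paternal_species(cross)
    var = adata.var
    num_cols = ((~var["is_marker"]) & (var["species"] == pat_sp)
                & var["pair_id"].isin(hk)).to_numpy()
    X = np.asarray(adata.X)
    total = X.sum(axis=1)
    zero = total == 0
    if zero.any():
        log.info("excluding %d zero-count cells", int(zero.sum()))
    with np.errstate(invalid="ignore"):
        ratio = X[:, num_cols].sum(axis=1) / total
    out = pd.Series(ratio, index=adata.obs_names, name="paternal_hk_ratio")
    return out[~zero]


@dataclass
class TypeComparison:
    """Per-lineage summary and pairwise t-test results."""

    summary: pd.DataFrame    # lineage, n, mean, median
    pairwise: pd.DataFrame   # lineage_a, lineage_b, t, p, p_adj, note


def compare_types(ratios: pd.Series, labels: pd.Series,
                  equal_var: bool = False) -> TypeComparison:
    """Two-sample t-tests between every pair of lineages, Bonferroni-adjusted.

    Welch's unequal-variance form by default (``equal_var=True`` switches to
    the pooled-variance Student form). Lineages with fewer than two cells are
    summarized but excluded from testing; pairs where both groups are constant
    are reported as no-variance cases with undefined t.
    """
    labels = labels.reindex(ratios.index)
    groups = {lin: ratios[labels == lin].to_numpy()
              for lin in labels.dropna().unique()}
    summary = pd.DataFrame(
        [(lin, len(v), float(np.mean(v)) if len(v) else np.nan,
          float(np.median(v)) if len(v) else np.nan)
         for lin, v in groups.items()],
        columns=["lineage", "n", "mean", "median"])
    testable = [lin for lin, v in groups.items() if len(v) >= 2]
    pairs = list(combinations(sorted(testable), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        if np.ptp(va) == 0 and np.ptp(vb) == 0:
            rows.append((a, b, np.nan, np.nan, np.nan, "no-variance"))
            continue
        t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
        rows.append((a, b, float(t), float(p), min(1.0, float(p) * m), ""))
    pairwise = pd.DataFrame(
        rows, columns=["lineage_a", "lineage_b", "t", "p", "p_adj", "note"])
    return TypeComparison(summary, pairwise)


def annotate_by_markers(adata: ad.AnnData, marker_sets: dict[str, list[str]]
                        ) -> pd.Series:
    """Predict each cell's lineage from marker expression.

    The prediction is the marker set with the highest mean depth-normalized
    (counts-per-10k) expression; exact ties, including the all-zero case,
    yield 'unassigned'. Marker sets must be disjoint and non-empty.
    """
    seen: set[str] = set()
    for lineage, feats in marker_sets.items():
        if not feats:
            raise ValueError(f"empty marker set for {lineage!r}")
        if overlap := seen & set(feats):
            raise ValueError(f"marker sets overlap: {sorted(overlap)}")
        seen |= set(feats)
    X = np.asarray(adata.X, dtype=float)
    total = X.sum(axis=1, keepdims=True)
    norm = np.divide(X * 1e4, total, out=np.zeros_like(X), where=total > 0)
    lineages = list(marker_sets)
    scores = np.zeros((adata.n_obs, len(lineages)))
    name_to_col = {n: i for i, n in enumerate(adata.var_names)}
    for j, lineage in enumerate(lineages):
        cols = [name_to_col[f] for f in marker_sets[lineage]]
        scores[:, j] = norm[:, cols].mean(axis=1)
    best = scores.max(axis=1)
    tie = (scores == best[:, None]).sum(axis=1) > 1
    pred = np.array(lineages, dtype=object)[scores.argmax(axis=1)]
    pred[tie] = "unassigned"
    return pd.Series(pred, index=adata.obs_names, name="predicted_lineage")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 8)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    hits = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        hits += abs(r) >= target
        total += 1
    return hits / total


def stiffness_correlation(type_means: pd.Series, stiffness: pd.Series
                          ) -> tuple[float, float]:
    """Spearman correlation of per-lineage reactivation with stiffness.

    Exact permutation p-value for n <= 8 shared lineages, otherwise scipy's
    asymptotic p. Refuses fewer than 4 shared lineages.
    """
    shared = sorted(set(type_means.index) & set(stiffness.index))
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 shared lineages, got {len(shared)}: {shared}")
    x = type_means[shared].to_numpy(dtype=float)
    y = stiffness[shared].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, y)
    if len(shared) <= 8:
        p = _spearman_exact_p(x, y, float(rho))
    return float(rho), float(p)
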