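"""Single-cell count matrices with lineage-resolved reactivation truth.

Each cell draws its lineage from the configured per-type proportions. The
maternal transcript pool (deposits, decayed to the sampled stage) is shared
across lineages; zygotic housekeeping reactivation is gated per lineage by its
configured onset stage and doubles each stage thereafter, so lineages with
earlier onsets show higher paternal housekeeping ratios. One marker gene per
lineage is expressed exclusively in that lineage, making marker-based
annotation testable without graph clustering. Counts are independent Poisson
draws around per-cell expectations scaled to a lognormal library size.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from ..config import SC_STAGES, SimConfig
from ..counts import maternal_species, paternal_species
from .expression import ExpressionProgram
from .genomes import _apportion

_STREAM_CELLS = 104


def _lineage_labels(config: SimConfig, n_cells: int,
                    rng: np.random.Generator) -> list[str]:
    counts = _apportion(
        {k: float(v) for k, v in config.lineage_proportions.items()}, n_cells)
    labels: list[str] = []
    for lineage, c in counts.items():
        labels.extend([lineage] * c)
    order = rng.permutation(n_cells)
    return [labels[i] for i in order]


def simulate_cells(program: ExpressionProgram, config: SimConfig, stage: str,
                   n_cells: int | None = None, cross: str = "forward",
                   seed: int | None = None, deterministic: bool = False
                   ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a single-cell sample at one of the profiled stages.

    Returns the cell x allelic-gene AnnData (with per-cell expectations in
    ``layers['expected']``) and a truth frame with the lineage, embryo, and
    expected paternal housekeeping ratio of every cell. With
    ``deterministic=True`` the Poisson draw is replaced by the expectation.
    """
    if stage not in SC_STAGES:
        raise ValueError(f"stage must be one of {SC_STAGES}, got {stage!r}")
    if n_cells is None:
        n_cells = sum(config.lineage_proportions.values())
    rng = np.random.default_rng(
        [config.seed, _STREAM_CELLS, SC_STAGES.index(stage)]
        if seed is None else seed)

    s_idx = config.stage_idx(stage)
    decay = (1.0 - config.decay_rate) ** s_idx
    mat_sp = maternal_species(cross)
    pat_sp = paternal_species(cross)
    lineages = list(config.lineage_proportions)

    truth = program.truth
    pair_ids = list(truth.index)
    features = [f"{p}.{al}" for p in pair_ids for al in "AB"]
    marker_features = [f"marker_{lin}" for lin in lineages]
    var = pd.DataFrame({
        "pair_id": [p for p in pair_ids for _ in "AB"] + marker_features,
        "species": [al for _ in pair_ids for al in "AB"] + ["A"] * len(lineages),
        "is_marker": [False] * (2 * len(pair_ids)) + [True] * len(lineages),
        "marker_lineage": [""] * (2 * len(pair_ids)) + lineages,
    }, index=pd.Index(features + marker_features, name="feature_id"))

    # Lineage-independent expectation components per feature.
    n_feat = len(var)
    base = np.zeros(n_feat)
    hk_cols: dict[str, list[int]] = {"A": [], "B": []}
    pat_hk_cols: list[int] = []
    for j, p in enumerate(pair_ids):
        row = truth.loc[p]
        for k, al in enumerate("AB"):
            col = 2 * j + k
            if al == mat_sp:
                base[col] += row["deposit"] * decay
            if row["klass"] == "housekeeping":
                hk_cols[al].append(col)
                if al == pat_sp:
                    pat_hk_cols.append(col)
            elif row["onset_stage"] is not None:
                onset = config.stage_idx(row["onset_stage"])
                if s_idx >= onset:
                    level = (config.zygotic_init if s_idx == onset
                             else config.zygotic_level)
                    base[col] += level * row[f"cis_{al}_{cross}"]

    # Per-lineage expectations: housekeeping reactivation gated by onset.
    profiles = {}
    for lineage in lineages:
        prof = base.copy()
        onset = config.stage_idx(config.lineage_onsets[lineage])
        if s_idx >= onset:
            rate = config.hk_reactivation_level * 2.0 ** (s_idx - onset)
            for al in "AB":
                cis = truth.loc[[pair_ids[c // 2] for c in hk_cols[al]],
                                f"cis_{al}_{cross}"].to_numpy()
                prof[hk_cols[al]] += rate * cis
        prof[n_feat - len(lineages) + lineages.index(lineage)] = config.marker_level
        profiles[lineage] = prof

    labels = _lineage_labels(config, n_cells, rng)
    expected = np.stack([profiles[lin] for lin in labels])
    lib = rng.lognormal(np.log(config.cell_library_size)
                        - config.cell_library_sigma ** 2 / 2,
                        config.cell_library_sigma, n_cells)
    expected = expected / expected.sum(axis=1, keepdims=True) * lib[:, None]
    if deterministic:
        X = expected.copy()
    else:
        X = rng.poisson(expected).astype(np.int64)

    obs = pd.DataFrame({
        "stage": stage,
        "lineage": labels,
        "embryo": rng.integers(0, 3, n_cells),
    }, index=pd.Index([f"{stage}:c{i:05d}" for i in range(n_cells)], name="cell_id"))

    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.layers["expected"] = expected
    with np.errstate(invalid="ignore"):
        ratio = expected[:, pat_hk_cols].sum(axis=1) / expected.sum(axis=1)
    truth_df = obs.copy()
    truth_df["expected_paternal_hk_ratio"] = ratio
    return adata, truth_df
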