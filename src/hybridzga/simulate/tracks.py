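"""Coverage-track and stiffness-table generators.

Coverage tracks emulate an activity-linked chromatin signal (e.g. H3K27ac):
per-base signal over each gene body equals a uniform background plus the
gene's zygotic activity at the sampled stage, with plain background over the
2-kb flanks. Stiffness tables emulate the measured mechanics of embryonic
lineages: stiffness decreases with reactivation-onset lateness, placing
endoderm and notochord on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig
from .expression import ExpressionProgram
from .genomes import GenomePair

_STREAM_STIFFNESS = 105

FLANK = 2000


def _zygotic_activity(program: ExpressionProgram, pair_id: str, allele: str,
                      cross: str, stage: str) -> float:
    """Zygotic (non-deposit) component of a gene copy's abundance."""
    config = program.config
    row = program.truth.loc[pair_id]
    if row["onset_stage"] is None:
        return 0.0
    s, onset = config.stage_idx(stage), config.stage_idx(row["onset_stage"])
    if s < onset:
        return 0.0
    level = config.zygotic_init if s == onset else config.zygotic_level
    return float(level * row[f"cis_{allele}_{cross}"])


def generate_coverage_tracks(program: ExpressionProgram, gp: GenomePair,
                             stage: str, cross: str = "forward",
                             background: float = 1.0
                             ) -> dict[str, pd.DataFrame]:
    """Per-species bedGraph frames (chrom, start, end, value), 0-based half-open."""
    if stage not in program.config.stages:
        raise ValueError(f"unknown stage {stage!r}")
    tracks: dict[str, pd.DataFrame] = {}
    for species in "AB":
        rows = []
        for pair_id in gp.pair_ids:
            model = gp.model_for_pair(pair_id, species)
            chrom_len = len(gp.genome(species)[model.chrom])
            lo = max(0, model.start - FLANK)
            hi = min(chrom_len, model.end + FLANK)
            activity = _zygotic_activity(program, pair_id, species, cross, stage)
            if lo < model.start:
                rows.append((model.chrom, lo, model.start, background))
            rows.append((model.chrom, model.start, model.end,
                         background + activity))
            if model.end < hi:
                rows.append((model.chrom, model.end, hi, background))
        tracks[species] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "value"])
    return tracks


def generate_stiffness_table(config: SimConfig) -> pd.DataFrame:
    """Per-lineage stiffness values (kPa-like arbitrary units).

    Stiffness decreases by 0.3 per onset-stage rank, with a small seeded
    jitter (+/- 0.05) that cannot reorder distinct onset ranks; the lineages
    with the earliest housekeeping reactivation (endoderm, then notochord by
    default) therefore carry the two largest values.
    """
    rng = np.random.default_rng([config.seed, _STREAM_STIFFNESS])
    lineages = list(config.lineage_onsets)
    onset_idx = np.array([config.stage_idx(config.lineage_onsets[lin])
                          for lin in lineages], dtype=float)
    latest = onset_idx.max() if len(onset_idx) else 0.0
    values = 2.0 + 0.3 * (latest - onset_idx) + rng.uniform(-0.05, 0.05,
                                                            len(lineages))
    return pd.DataFrame({"lineage": lineages, "stiffness": values})
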