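"""Staged expression program for reciprocal crosses.

Abundance of each allele at each stage decomposes into a maternally deposited
component, carried by the maternal allele only and decaying geometrically per
stage, and a zygotic component that switches on at the gene class's onset
stage (at a low initiation level) and plateaus one stage later. Allelic cis
strengths implement the configured quadrant composition: species-dominant
pairs favor the same species' allele in both crosses, while maternal- or
paternal-dominant pairs favor whichever allele was inherited from that parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import CROSSES, ConfigError, SimConfig
from ..counts import ParentCountMatrix, maternal_species, paternal_species
from .genomes import GenomePair


def _cis_strength(quadrant: str, allele: str, cross: str, effect_log2: float) -> float:
    e = 2.0 ** (effect_log2 / 2.0)
    if quadrant == "unbiased":
        return 1.0
    if quadrant == "A_dominant":
        favored = "A"
    elif quadrant == "B_dominant":
        favored = "B"
    elif quadrant == "maternal_dominant":
        favored = maternal_species(cross)
    elif quadrant == "paternal_dominant":
        favored = paternal_species(cross)
    else:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    return e if allele == favored else 1.0 / e


@dataclass
class ExpressionProgram:
    """Expected transcript abundance per (pair, allele, cross, stage).

    ``abundance`` maps cross -> {allele -> DataFrame (pairs x stages)};
    ``truth`` records per pair the class, onset stage, deposit, and cis
    strengths actually used, and ``transcript_lengths`` the spliced lengths
    used to weight read sampling.
    """

    config: SimConfig
    truth: pd.DataFrame
    abundance: dict[str, dict[str, pd.DataFrame]]
    transcript_lengths: pd.Series

    @property
    def stages(self) -> tuple[str, ...]:
        return self.config.stages

    @property
    def pair_ids(self) -> list[str]:
        return list(self.truth.index)

    def get(self, pair_id: str, allele: str, cross: str, stage: str) -> float:
        return float(self.abundance[cross][allele].loc[pair_id, stage])

    def allele_table(self, cross: str) -> pd.DataFrame:
        """Long-form abundance: pair_id, allele, stage, abundance."""
        frames = []
        for allele in ("A", "B"):
            df = self.abundance[cross][allele].stack().rename("abundance").reset_index()
            df.columns = ["pair_id", "stage", "abundance"]
            df.insert(1, "allele", allele)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def truth_paternal_fraction(self, cross: str) -> pd.Series:
        """Closed-form paternal share of total abundance per stage."""
        pat = self.abundance[cross][paternal_species(cross)].sum(axis=0)
        mat = self.abundance[cross][maternal_species(cross)].sum(axis=0)
        total = pat + mat
        with np.errstate(invalid="ignore"):
            frac = pat / total
        return frac.fillna(0.0)

    def expected_parent_counts(self, cross: str, reads_per_stage: float = 1e6
                               ) -> ParentCountMatrix:
        """Noise-free expected read counts per gene copy and stage.

        Reads are apportioned per stage proportionally to abundance x
        transcript length, mirroring the read simulator's sampling weights but
        with the multinomial replaced by its expectation (zero-noise mode).
        """
        mat_sp, pat_sp = maternal_species(cross), paternal_species(cross)
        lengths = self.transcript_lengths
        mat_w = self.abundance[cross][mat_sp].mul(lengths, axis=0)
        pat_w = self.abundance[cross][pat_sp].mul(lengths, axis=0)
        total = mat_w.sum(axis=0) + pat_w.sum(axis=0)
        scale = reads_per_stage / total.replace(0.0, np.nan)
        rows = []
        for stage in self.stages:
            s = scale[stage]
            if np.isnan(s):
                s = 0.0
            for pair_id in self.pair_ids:
                rows.append((pair_id, stage,
                             mat_w.loc[pair_id, stage] * s,
                             pat_w.loc[pair_id, stage] * s))
        data = pd.DataFrame(rows, columns=["pair_id", "stage", "maternal", "paternal"])
        return ParentCountMatrix(cross, data, {s: 0 for s in self.stages})


def generate_expression_program(config: SimConfig, gp: GenomePair
                                ) -> ExpressionProgram:
    """Build the closed-form expression program for both crosses."""
    classes = gp.classes
    stages = list(config.stages)
    n_stages = len(stages)
    decay = (1.0 - config.decay_rate) ** np.arange(n_stages)

    onset_idx: dict[str, int | None] = {}
    for klass in config.class_fractions:
        stage = config.onset_stage_by_class.get(klass)
        if klass != "maternal_only" and stage is None:
            raise ConfigError(f"no onset stage configured for class {klass!r}")
        onset_idx[klass] = None if stage is None else config.stage_idx(stage)

    truth_rows = []
    per_allele = {
        cross: {al: np.zeros((len(classes), n_stages)) for al in "AB"}
        for cross in CROSSES
    }
    for i, (pair_id, row) in enumerate(classes.iterrows()):
        klass, quadrant = row["klass"], row["quadrant"]
        deposit = (config.maternal_deposit
                   if klass in ("maternal_only", "housekeeping") else 0.0)
        oi = onset_idx.get(klass)
        zyg = np.zeros(n_stages)
        if oi is not None:
            zyg[oi] = config.zygotic_init
            zyg[oi + 1:] = config.zygotic_level
        cis = {}
        for cross in CROSSES:
            for allele in "AB":
                c = _cis_strength(quadrant, allele, cross, config.ase_effect_log2)
                cis[(allele, cross)] = c
                ab = zyg * c
                if allele == maternal_species(cross):
                    ab = ab + deposit * decay
                per_allele[cross][allele][i] = ab
        truth_rows.append({
            "pair_id": pair_id, "klass": klass, "quadrant": quadrant,
            "onset_stage": None if oi is None else stages[oi],
            "deposit": deposit,
            "cis_A_forward": cis[("A", "forward")],
            "cis_B_forward": cis[("B", "forward")],
            "cis_A_reverse": cis[("A", "reverse")],
            "cis_B_reverse": cis[("B", "reverse")],
        })

    truth = pd.DataFrame(truth_rows).set_index("pair_id")
    abundance = {
        cross: {
            al: pd.DataFrame(per_allele[cross][al], index=classes.index,
                             columns=stages)
            for al in "AB"
        }
        for cross in CROSSES
    }
    lengths = pd.Series(gp.exonic_lengths(), name="length").reindex(classes.index)
    return ExpressionProgram(config, truth, abundance, lengths)
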