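"""Bulk temporal analysis of zygotic genome activation.

Quantifies expression (FPKM), tracks the paternal read fraction across the
stage series, detects de-novo activation of paternal gene copies against the
expression threshold, locates the minor and major activation waves, assigns
genes to wave modules, and measures the intronic read ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EXPRESSED_FPKM
from .counts import ParentCountMatrix
from .simulate.genomes import GenomePair


@dataclass
class FPKMTable:
    """FPKM per gene copy and stage: 1e9 * c / (L * N).

    ``c`` is the read count of the gene copy, ``L`` the summed exon length in
    bp and ``N`` the total gene-assigned read count of the sample. Stages with
    N = 0 are flagged and carry NaN rather than silent zeros.
    """

    data: pd.DataFrame  # columns: pair_id, stage, origin, fpkm
    stages: list[str]
    flagged_stages: list[str] = field(default_factory=list)

    def wide(self, origin: str) -> pd.DataFrame:
        sub = self.data[self.data["origin"] == origin]
        return (sub.pivot(index="pair_id", columns="stage", values="fpkm")
                .reindex(columns=self.stages))

    def get(self, pair_id: str, origin: str, stage: str) -> float:
        sel = self.data[(self.data["pair_id"] == pair_id)
                        & (self.data["origin"] == origin)
                        & (self.data["stage"] == stage)]
        return float(sel["fpkm"].iloc[0])


def fpkm(counts: ParentCountMatrix, gene_lengths: dict[str, int] | pd.Series,
         stages: list[str] | None = None) -> FPKMTable:
    """Compute FPKM for both parental copies of every gene."""
    lengths = pd.Series(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    stages = stages or counts.stages
    totals = counts.stage_totals().sum(axis=1)
    rows = []
    flagged = []
    for stage in stages:
        sub = counts.data[counts.data["stage"] == stage]
        n_total = float(totals.get(stage, 0.0))
        if n_total == 0:
            flagged.append(stage)
        for origin in ("maternal", "paternal"):
            c = sub.set_index("pair_id")[origin].reindex(lengths.index,
                                                         fill_value=0)
            if n_total == 0:
                val = pd.Series(np.nan, index=lengths.index)
            else:
                val = 1e9 * c / (lengths * n_total)
            for pair_id, v in val.items():
                rows.append((pair_id, stage, origin, v))
    data = pd.DataFrame(rows, columns=["pair_id", "stage", "origin", "fpkm"])
    return FPKMTable(data, list(stages), flagged)


def paternal_ratio(counts: ParentCountMatrix) -> pd.DataFrame:
    """Per-stage paternal share of unambiguous gene-assigned reads."""
    totals = counts.stage_totals()
    if totals.empty:
        raise ValueError("counts cover no stage")
    out = totals.copy()
    denom = out["maternal"] + out["paternal"]
    with np.errstate(invalid="ignore"):
        out["ratio"] = out["paternal"] / denom
    out["flagged"] = denom == 0
    return out.reset_index()


@dataclass
class DenovoReport:
    """First-expression stages of paternal gene copies."""

    first_stage: pd.Series          # pair_id -> stage label (NaN if never)
    per_stage: pd.DataFrame         # stage, n_denovo, ratio
    threshold: float
    n_ever_expressed: int


def denovo_paternal(table: FPKMTable, threshold: float = EXPRESSED_FPKM
                    ) -> DenovoReport:
    """First stage at which each paternal copy reaches the FPKM threshold.

    A gene is first expressed at stage t when its paternal FPKM is >= the
    threshold at t and below it at every earlier stage; genes never reaching
    the threshold are excluded from the per-stage ratio denominator.
    """
    wide = table.wide("paternal")
    if list(wide.columns) != list(table.stages):
        raise ValueError("stages must be ordered and complete")
    arr = wide.to_numpy()
    expressed = np.nan_to_num(arr) >= threshold
    ever = expressed.any(axis=1)
    first_idx = expressed.argmax(axis=1)
    first = pd.Series(
        [table.stages[i] if ok else np.nan for i, ok in zip(first_idx, ever)],
        index=wide.index, name="first_stage")
    n_ever = int(ever.sum())
    counts = pd.Series(0, index=table.stages, dtype=int)
    vc = first[ever].value_counts() if n_ever else pd.Series(dtype=int)
    counts.update(vc)
    per_stage = pd.DataFrame({
        "stage": table.stages,
        "n_denovo": counts.to_numpy(),
        "ratio": counts.to_numpy() / n_ever if n_ever else np.nan,
    })
    return DenovoReport(first, per_stage, threshold, n_ever)


@dataclass
class WaveReport:
    """Ranked stage transitions with the minor/major wave labels."""

    transitions: pd.DataFrame  # from_stage, to_stage, activation, delta_ratio
    minor: tuple[str, str] | None
    major: tuple[str, str] | None
    single_wave: bool


def top_two_transitions(scores: np.ndarray) -> tuple[int | None, int | None]:
    """Indices of the two largest positive scores, earlier one first."""
    order = np.argsort(scores, kind="stable")[::-1]
    positive = [int(i) for i in order if scores[i] > 0]
    if not positive:
        return None, None
    if len(positive) == 1:
        return positive[0], None
    i, j = positive[0], positive[1]
    return (i, j) if i < j else (j, i)


def detect_waves(denovo: DenovoReport, ratio: pd.DataFrame) -> WaveReport:
    """Locate the minor and major activation waves.

    A transition's activation score is the number of paternal genes first
    expressed at its left stage: those genes switch on there and their output
    surges across the transition (the paternal-ratio change is reported
    alongside as corroboration). The two transitions with the largest scores
    are the waves; the earlier is labeled minor and the later major.
    """
    stages = list(denovo.per_stage["stage"])
    if len(stages) < 3:
        raise ValueError("need at least 3 stages to detect waves")
    counts = denovo.per_stage.set_index("stage")["n_denovo"]
    rseries = ratio.set_index("stage")["ratio"].reindex(stages)
    rows = []
    for i in range(len(stages) - 1):
        a, b = stages[i], stages[i + 1]
        rows.append((a, b, int(counts[a]),
                     float(rseries[b] - rseries[a])))
    transitions = pd.DataFrame(
        rows, columns=["from_stage", "to_stage", "activation", "delta_ratio"])
    scores = transitions["activation"].to_numpy(dtype=float)
    # break activation ties by the corroborating ratio change
    eps_rank = transitions["delta_ratio"].rank(method="first").to_numpy()
    i, j = top_two_transitions(np.where(scores > 0, scores + 1e-9 * eps_rank, 0.0))
    minor = (transitions.loc[i, "from_stage"], transitions.loc[i, "to_stage"]) \
        if i is not None else None
    major = (transitions.loc[j, "from_stage"], transitions.loc[j, "to_stage"]) \
        if j is not None else None
    return WaveReport(transitions, minor, major, single_wave=major is None)


def temporal_modules(table: FPKMTable, waves: WaveReport,
                     threshold: float = EXPRESSED_FPKM) -> pd.Series:
    """Assign zygotically expressed paternal genes to wave modules.

    A gene belongs to the minor (major) module when its largest consecutive-
    stage FPKM increase falls on the minor (major) wave transition; genes with
    no positive increase, or whose maximal rise lies elsewhere, are 'other'.
    Genes never reaching the threshold are skipped.
    """
    wide = table.wide("paternal")
    arr = np.nan_to_num(wide.to_numpy())
    ever = (arr >= threshold).any(axis=1)
    diffs = np.diff(arr, axis=1)
    out = {}
    for row, pair_id in enumerate(wide.index):
        if not ever[row]:
            continue
        d = diffs[row]
        if d.max() <= 0:
            out[pair_id] = "other"
            continue
        k = int(d.argmax())
        trans = (table.stages[k], table.stages[k + 1])
        if waves.minor is not None and trans == tuple(waves.minor):
            out[pair_id] = "minor"
        elif waves.major is not None and trans == tuple(waves.major):
            out[pair_id] = "major"
        else:
            out[pair_id] = "other"
    return pd.Series(out, name="module", dtype=object)


def intronic_ratio(sidecar: pd.DataFrame, gp: GenomePair, read_length: int
                   ) -> float:
    """Fraction of gene-assigned reads overlapping an intron.

    Reads from spliced transcripts never cover intronic bases; pre-mRNA reads
    are intronic when their interval overlaps any intron by at least one base
    (junction-spanning reads count as intronic).
    """
    n_total = len(sidecar)
    if n_total == 0:
        return float("nan")
    pre = sidecar[sidecar["template"] == "premrna"]
    n_intronic = 0
    for (pair_id, allele), grp in pre.groupby(["pair_id", "allele"]):
        model = gp.model_for_pair(pair_id, allele)
        introns = model.introns
        if not introns:
            continue
        span = model.end - model.start
        # intron intervals in pre-mRNA (transcription-orientation) coordinates
        if model.strand == "+":
            iv = [(s - model.start, e - model.start) for s, e in introns]
        else:
            iv = [(span - (e - model.start), span - (s - model.start))
                  for s, e in introns]
        starts = grp["start"].to_numpy()
        hit = np.zeros(len(starts), dtype=bool)
        for s, e in iv:
            hit |= (starts < e) & (starts + read_length > s)
        n_intronic += int(hit.sum())
    return n_intronic / n_total


def intronic_ratio_by_stage(sidecars: dict[str, pd.DataFrame], gp: GenomePair,
                            read_length: int) -> pd.DataFrame:
    rows = [(stage, intronic_ratio(sc, gp, read_length))
            for stage, sc in sidecars.items()]
    return pd.DataFrame(rows, columns=["stage", "intronic_ratio"])
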