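"""Study-design constants and configuration objects.

The developmental stage series, lineage panel, gene-class vocabulary and the
default simulation parameters together define the conditions every analysis
module in this package assumes: reciprocal crosses between two deeply diverged
ascidian species, maternal transcript decay during cleavage, zygotic genome
activation in two waves (a minor wave of early developmental genes and a major
wave of housekeeping-gene reactivation), and lineage-dependent reactivation
timing in single cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# The 11-stage bulk sampling series, in developmental order.
STAGES: tuple[str, ...] = (
    "1-cell", "2-cell", "4-cell", "8-cell", "16-cell", "32-cell",
    "64-cell", "112-cell", "midG", "earN", "lateN",
)

CROSSES: tuple[str, str] = ("forward", "reverse")

# Gene expression classes used by the synthetic program.
CLASSES: tuple[str, ...] = (
    "maternal_only", "early_zygotic", "minor_wave", "housekeeping",
    "zygotic_only_ase",
)

# Allele-specific-expression quadrant categories.
QUADRANTS: tuple[str, ...] = (
    "A_dominant", "B_dominant", "maternal_dominant", "paternal_dominant",
)

# Annotated cell lineages, ordered endoderm -> epidermis as in the single-cell
# panel; the 64-cell-stage per-type cell counts follow the same order.
LINEAGES: tuple[str, ...] = (
    "endoderm", "notochord", "mesenchyme_a", "mesenchyme_b", "nerve_cord",
    "muscle", "germ", "neural", "epidermis",
)
LINEAGE_CELL_COUNTS: dict[str, int] = dict(
    zip(LINEAGES, (40, 43, 32, 187, 259, 150, 70, 20, 43))
)

SC_STAGES: tuple[str, ...] = ("64-cell", "112-cell", "earN")

# Per-stage detected-gene windows applied when filtering raw cell matrices.
STAGE_GENE_WINDOWS: dict[str, tuple[int, int]] = {
    "64-cell": (1000, 7000),
    "112-cell": (2000, 7000),
    "earN": (500, 4500),
}

EXPRESSED_FPKM = 0.1  # minimum FPKM for a gene copy to count as expressed


def stage_index(stage: str, stages: tuple[str, ...] = STAGES) -> int:
    try:
        return stages.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {stages}")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _default_class_fractions() -> dict[str, float]:
    return {
        "maternal_only": 0.30,
        "early_zygotic": 0.05,
        "minor_wave": 0.22,
        "housekeeping": 0.37,
        "zygotic_only_ase": 0.06,
    }


def _default_ase_composition() -> dict[str, int]:
    # Late-gene quadrant counts from the reciprocal-cross study: C. robusta-
    # dominant, C. savignyi-dominant, maternal-dominant, paternal-dominant.
    return {
        "A_dominant": 138,
        "B_dominant": 106,
        "maternal_dominant": 90,
        "paternal_dominant": 7,
    }


def _default_onsets_by_class() -> dict[str, str]:
    return {
        "early_zygotic": "8-cell",
        "minor_wave": "16-cell",
        "housekeeping": "64-cell",
        "zygotic_only_ase": "midG",
    }


def _default_lineage_onsets() -> dict[str, str]:
    return {
        "endoderm": "32-cell",
        "notochord": "64-cell",
        "mesenchyme_a": "112-cell",
        "mesenchyme_b": "112-cell",
        "nerve_cord": "112-cell",
        "muscle": "earN",
        "germ": "earN",
        "neural": "earN",
        "epidermis": "earN",
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic hybrid-embryo data generator.

    Defaults encode the study conditions: ~14.3% +/- 3.9% orthologous sequence
    divergence between the two parental species, maternal deposits decaying
    during cleavage, early zygotic genes from the 8-cell stage, a minor
    activation wave at 16->32-cell, housekeeping reactivation at 64->112-cell,
    and a late-activated zygotic-only class carrying the allele-specific
    expression quadrant structure.
    """

    seed: int = 0
    n_gene_pairs: int = 120
    divergence_mean: float = 0.143
    divergence_sd: float = 0.039
    gene_length: int = 900          # exonic (spliced transcript) length, bp
    n_exons: int = 3
    intron_length: int = 200
    upstream_length: int = 1000
    flank_length: int = 2500        # chromosome flank on each side of a gene
    read_length: int = 150
    error_rate: float = 0.005       # per-base substitution error
    stages: tuple[str, ...] = STAGES
    decay_rate: float = 0.10        # maternal deposit decay per stage
    maternal_deposit: float = 500.0
    zygotic_init: float = 2.0       # zygotic level at the onset stage
    zygotic_level: float = 10.0     # plateau level from one stage after onset
    premrna_fraction: float = 0.0   # fraction of reads drawn from pre-mRNA
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    ase_composition: dict[str, int] = field(default_factory=_default_ase_composition)
    ase_effect_log2: float = 2.0    # |log2 allele ratio| of biased pairs
    onset_stage_by_class: dict[str, str] = field(default_factory=_default_onsets_by_class)
    lineage_onsets: dict[str, str] = field(default_factory=_default_lineage_onsets)
    lineage_proportions: dict[str, int] = field(
        default_factory=lambda: dict(LINEAGE_CELL_COUNTS))
    identity_window: int = 100
    # single-cell parameters
    cell_library_size: float = 2000.0   # mean counts per cell
    cell_library_sigma: float = 0.3     # lognormal sigma of library size
    hk_reactivation_level: float = 2.0  # per-hk-gene rate at the onset stage
    marker_level: float = 50.0          # marker-gene expected counts
    # upstream sequence structure of species-biased pairs
    biased_upstream_extra_divergence: float = 0.25
    biased_upstream_window: tuple[int, int] = (100, 300)  # bp upstream of CDS

    def __post_init__(self) -> None:
        self.validate()

    # -- derived helpers -------------------------------------------------
    @property
    def exon_length(self) -> int:
        return self.gene_length // self.n_exons

    @property
    def gene_span(self) -> int:
        return self.n_exons * self.exon_length + (self.n_exons - 1) * self.intron_length

    def stage_idx(self, stage: str) -> int:
        return stage_index(stage, self.stages)

    def validate(self) -> None:
        if self.n_gene_pairs < 0:
            raise ConfigError("n_gene_pairs must be >= 0")
        for name in ("gene_length", "n_exons", "upstream_length", "read_length",
                     "flank_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.intron_length < 0:
            raise ConfigError("intron_length must be >= 0")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions must sum to 1, got {total}")
        if unknown := set(self.class_fractions) - set(CLASSES):
            raise ConfigError(f"unknown gene classes: {sorted(unknown)}")
        lo = self.divergence_mean - self.divergence_sd
        hi = self.divergence_mean + self.divergence_sd
        if not (0.0 < lo and hi < 1.0):
            raise ConfigError(
                "divergence_mean +/- divergence_sd must lie within (0, 1)")
        if self.upstream_length % self.identity_window != 0:
            raise ConfigError(
                "upstream_length must be divisible by identity_window")
        if len(self.stages) == 0:
            raise ConfigError("stages must be non-empty")
        for cls, stage in self.onset_stage_by_class.items():
            if stage not in self.stages:
                raise ConfigError(
                    f"onset stage {stage!r} for class {cls!r} not in stages")
        for lineage, stage in self.lineage_onsets.items():
            if stage not in self.stages:
                raise ConfigError(
                    f"onset stage {stage!r} for lineage {lineage!r} not in stages")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be in [0, 1)")
        if self.flank_length < max(self.upstream_length, 2000):
            raise ConfigError(
                "flank_length must cover the upstream window and 2-kb flanks")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Thresholds and labels shared by the analysis stages."""

    seed: int = 0
    expressed_threshold: float = EXPRESSED_FPKM
    ase_delta: float = 1.0          # log2 dominance threshold
    ase_epsilon: float = 0.1        # pseudocount for log ratios
    motif_pvalue: float = 1e-4
    kmer_size: int = 21
    min_diagnostic: int = 2
    margin: int = 2
    cv_max: float = 1.0             # housekeeping stability cutoff
    stages: tuple[str, ...] = STAGES
    crosses: tuple[str, str] = CROSSES

    def __post_init__(self) -> None:
        for name in ("expressed_threshold", "ase_delta", "ase_epsilon",
                     "motif_pvalue"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.stages) == 0:
            raise ConfigError("stages must be non-empty")
        if self.kmer_size % 2 == 0 or not (11 <= self.kmer_size <= 31):
            raise ConfigError("kmer_size must be odd and within [11, 31]")
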