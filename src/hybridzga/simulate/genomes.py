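"""Paired parental genomes with controlled orthologous divergence.

Each ortholog pair occupies its own chromosome, present in both species at
identical coordinates: an ancestral sequence is drawn uniformly over ACGT and
the second species' copy is derived by substituting each site independently
with a per-pair divergence probability (substitutions only, no indels, so
ortholog coordinates stay aligned). Gene structure (exons, introns, strand)
is shared between the species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._seq import decode, encode, revcomp
from ..config import QUADRANTS, ConfigError, SimConfig

# Independent RNG streams derived from the user seed.
_STREAM_CLASSES = 101
_STREAM_GENOME = 102


@dataclass(frozen=True)
class GeneModel:
    """A gene's placement on its chromosome.

    Exon intervals are 0-based half-open, sorted and non-overlapping; they are
    identical between the two species. ``cds_start`` is the genomic coordinate
    at which translation starts in transcription orientation (for minus-strand
    genes it equals the half-open end of the gene span).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e) or s < prev_end:
                raise ValueError(f"exons must be sorted, non-overlapping: {self.exons}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_start(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def upstream_interval(self, length: int) -> tuple[int, int]:
        """Genomic half-open interval of the ``length`` bp 5' of the CDS start."""
        return self.upstream_subinterval(0, length)

    def upstream_subinterval(self, lo: int, hi: int) -> tuple[int, int]:
        """Genomic interval of bases ``lo``..``hi`` upstream of the CDS start."""
        if self.strand == "+":
            return (self.start - hi, self.start - lo)
        return (self.end + lo, self.end + hi)

    def spliced_transcript(self, chrom_seq: str) -> str:
        """Transcript sequence in transcription orientation."""
        parts = "".join(chrom_seq[s:e] for s, e in self.exons)
        return parts if self.strand == "+" else revcomp(parts)

    def premrna(self, chrom_seq: str) -> str:
        seq = chrom_seq[self.start:self.end]
        return seq if self.strand == "+" else revcomp(seq)

    def transcript_to_genome(self, start: int, length: int) -> list[tuple[int, int]]:
        """Map a spliced-transcript interval back to genomic blocks."""
        # Work in plus-orientation transcript coordinates.
        if self.strand == "-":
            start = self.exonic_length - (start + length)
        blocks: list[tuple[int, int]] = []
        remaining_start, remaining = start, length
        for s, e in self.exons:
            ex_len = e - s
            if remaining <= 0:
                break
            if remaining_start < ex_len:
                b0 = s + remaining_start
                take = min(ex_len - remaining_start, remaining)
                blocks.append((b0, b0 + take))
                remaining -= take
                remaining_start = 0
            else:
                remaining_start -= ex_len
        return blocks


@dataclass
class GenomePair:
    """Two parental genomes plus shared gene models and truth divergence."""

    species_a: dict[str, str]
    species_b: dict[str, str]
    gene_models: dict[str, GeneModel]
    ortholog_map: dict[str, tuple[str, str]]
    truth_divergence: dict[str, float]
    classes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.ortholog_map)

    def genome(self, species: str) -> dict[str, str]:
        if species == "A":
            return self.species_a
        if species == "B":
            return self.species_b
        raise ValueError(f"species must be 'A' or 'B', got {species!r}")

    def model_for_pair(self, pair_id: str, species: str) -> GeneModel:
        gene_a, gene_b = self.ortholog_map[pair_id]
        return self.gene_models[gene_a if species == "A" else gene_b]

    def transcript(self, pair_id: str, species: str) -> str:
        model = self.model_for_pair(pair_id, species)
        return model.spliced_transcript(self.genome(species)[model.chrom])

    def transcripts(self, species: str) -> dict[str, str]:
        """Spliced transcripts of one species keyed by pair id."""
        return {p: self.transcript(p, species) for p in self.ortholog_map}

    def exonic_lengths(self) -> dict[str, int]:
        return {
            p: self.model_for_pair(p, "A").exonic_length for p in self.ortholog_map
        }


def _apportion(weights: dict[str, float], total: int) -> dict[str, int]:
    """Integer apportionment by largest remainder (Hamilton method)."""
    if total == 0 or not weights:
        return {k: 0 for k in weights}
    wsum = sum(weights.values())
    quotas = {k: total * w / wsum for k, w in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = total - sum(counts.values())
    order = sorted(weights, key=lambda k: (quotas[k] - counts[k]), reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def assign_classes(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-pair class (and ASE quadrant) assignment.

    Returns a frame indexed by pair id with columns ``klass`` and ``quadrant``
    (quadrant is ``unbiased`` for non-ASE classes). Both the genome generator
    and the expression program derive this same table from the config seed, so
    upstream sequence structure and expression effects stay consistent.
    """
    n = config.n_gene_pairs
    rng = np.random.default_rng([config.seed, _STREAM_CLASSES])
    pair_ids = [f"g{i:04d}" for i in range(n)]
    counts = _apportion(config.class_fractions, n)
    labels: list[str] = []
    for klass in config.class_fractions:
        labels.extend([klass] * counts[klass])
    labels = list(np.array(labels, dtype=object)[rng.permutation(n)]) if n else []
    quadrants = ["unbiased"] * n
    ase_idx = [i for i, k in enumerate(labels) if k == "zygotic_only_ase"]
    qcounts = _apportion(
        {q: float(c) for q, c in config.ase_composition.items()}, len(ase_idx)
    )
    qlabels: list[str] = []
    for q in QUADRANTS:
        qlabels.extend([q] * qcounts.get(q, 0))
    qlabels.extend(["unbiased"] * (len(ase_idx) - len(qlabels)))
    perm = rng.permutation(len(ase_idx))
    for j, i in enumerate(ase_idx):
        quadrants[i] = qlabels[perm[j]]
    return pd.DataFrame(
        {"klass": labels, "quadrant": quadrants},
        index=pd.Index(pair_ids, name="pair_id"),
    )


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator,
            lo: int = 0, hi: int | None = None) -> None:
    """Substitute each site in ``codes[lo:hi]`` with probability ``rate``."""
    if rate <= 0:
        return
    hi = len(codes) if hi is None else hi
    span = hi - lo
    mask = rng.random(span) < rate
    idx = np.nonzero(mask)[0] + lo
    if idx.size:
        codes[idx] = (codes[idx] + rng.integers(1, 4, idx.size)) % 4


def _sample_divergence(config: SimConfig, rng: np.random.Generator,
                       n: int) -> np.ndarray:
    """Per-pair divergence ~ Normal(mean, sd) truncated to (0.01, 0.5)."""
    if config.divergence_sd == 0:
        return np.clip(np.full(n, config.divergence_mean), 0.01, 0.5)
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(config.divergence_mean, config.divergence_sd, todo.size)
        ok = (draw > 0.01) & (draw < 0.5)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_genome_pair(config: SimConfig) -> GenomePair:
    """Generate the two parental genomes for every ortholog pair.

    Species A carries the ancestral sequence; species B substitutes each site
    independently with the pair's divergence probability. Species-biased ASE
    pairs additionally receive extra substitutions in the configured upstream
    window of species B, emulating diverged cis-regulatory elements.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    classes = assign_classes(config)
    n = config.n_gene_pairs
    div = _sample_divergence(config, rng, n)

    exon_len = config.exon_length
    last_exon = config.gene_length - (config.n_exons - 1) * exon_len
    species_a: dict[str, str] = {}
    species_b: dict[str, str] = {}
    gene_models: dict[str, GeneModel] = {}
    ortholog_map: dict[str, tuple[str, str]] = {}
    truth_divergence: dict[str, float] = {}

    for i, pair_id in enumerate(classes.index):
        chrom = f"chr{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        exons = []
        pos = config.flank_length
        for j in range(config.n_exons):
            length = exon_len if j < config.n_exons - 1 else last_exon
            exons.append((pos, pos + length))
            pos += length + config.intron_length
        gene_end = exons[-1][1]
        chrom_len = gene_end + config.flank_length

        ancestor = rng.integers(0, 4, chrom_len, dtype=np.uint8)
        derived = ancestor.copy()
        _mutate(derived, div[i], rng)

        model = GeneModel(f"{pair_id}", chrom, strand, tuple(exons))
        if classes.loc[pair_id, "quadrant"] in ("A_dominant", "B_dominant"):
            lo_bp, hi_bp = config.biased_upstream_window
            w0, w1 = model.upstream_subinterval(lo_bp, hi_bp)
            _mutate(derived, config.biased_upstream_extra_divergence, rng, w0, w1)

        gene_a, gene_b = f"{pair_id}.A", f"{pair_id}.B"
        gene_models[gene_a] = GeneModel(gene_a, chrom, strand, tuple(exons))
        gene_models[gene_b] = GeneModel(gene_b, chrom, strand, tuple(exons))
        ortholog_map[pair_id] = (gene_a, gene_b)
        truth_divergence[pair_id] = float(div[i])
        species_a[chrom] = decode(ancestor)
        species_b[chrom] = decode(derived)

    return GenomePair(species_a, species_b, gene_models, ortholog_map,
                      truth_divergence, classes)


def implant_motif(gp: GenomePair, pair_ids: list[str], motif: str,
                  species: str = "A", upstream_offset: int = 150) -> GenomePair:
    """Write ``motif`` into the upstream region of the given pairs.

    The motif is placed so that its 3' end lies ``upstream_offset`` bp
    upstream of the CDS start, on the coding strand of the chosen species
    only. Returns a new GenomePair sharing everything except the modified
    chromosome sequences.
    """
    genome = dict(gp.genome(species))
    m = len(motif)
    for pair_id in pair_ids:
        model = gp.model_for_pair(pair_id, species)
        lo, hi = model.upstream_subinterval(upstream_offset, upstream_offset + m)
        if lo < 0 or hi > len(genome[model.chrom]):
            raise ConfigError(f"upstream window out of range for {pair_id}")
        seq = genome[model.chrom]
        insert = motif if model.strand == "+" else revcomp(motif)
        genome[model.chrom] = seq[:lo] + insert + seq[hi:]
    kwargs = dict(
        species_a=gp.species_a, species_b=gp.species_b,
        gene_models=gp.gene_models, ortholog_map=gp.ortholog_map,
        truth_divergence=gp.truth_divergence, classes=gp.classes,
    )
    kwargs["species_a" if species == "A" else "species_b"] = genome
    return GenomePair(**kwargs)
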