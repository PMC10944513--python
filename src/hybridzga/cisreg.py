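"""Upstream cis-regulatory sequence analyses.

Covers extraction of the 1-kb regulatory window 5' of the CDS start,
percent-identity profiles over 100-bp windows (needle-style global alignment
or ungapped columnwise comparison), between-group identity tests, PWM motif
scanning with exact p-values computed by dynamic programming over the
discretized score distribution, differential motif presence between alleles,
and meta-gene coverage matrices over scaled gene bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from ._seq import revcomp
from .simulate.genomes import GeneModel

# EMBOSS-needle-like scoring for DNA: EDNAFULL match/mismatch with
# affine gaps (first gap base 10, each further base 0.5).
NEEDLE_MATCH = 5.0
NEEDLE_MISMATCH = -4.0
NEEDLE_GAP_OPEN = 10.0
NEEDLE_GAP_EXTEND = 0.5


def extract_upstream(genome: dict[str, str], model: GeneModel,
                     length: int = 1000) -> str:
    """Sequence immediately 5' of the CDS start, strand-corrected.

    The returned string is oriented so its last base abuts the start codon.
    Minus-strand genes are reverse-complemented. Raises when the chromosome
    does not extend ``length`` bp upstream of the gene.
    """
    chrom_seq = genome[model.chrom]
    lo, hi = model.upstream_interval(length)
    if lo < 0 or hi > len(chrom_seq):
        raise ValueError(
            f"gene {model.gene_id!r} lacks {length} bp of upstream flank")
    seq = chrom_seq[lo:hi].upper()
    return seq if model.strand == "+" else revcomp(seq)


def extract_upstream_window(genome: dict[str, str], model: GeneModel,
                            lo: int = 100, hi: int = 300) -> str:
    """Bases ``lo``..``hi`` upstream of the CDS start, strand-corrected."""
    up = extract_upstream(genome, model, hi)
    return up[: hi - lo]


def _needle_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment with needle-like scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NEEDLE_MATCH
    aligner.mismatch_score = NEEDLE_MISMATCH
    aligner.open_gap_score = -(NEEDLE_GAP_OPEN + NEEDLE_GAP_EXTEND)
    aligner.extend_gap_score = -NEEDLE_GAP_EXTEND
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.shape[1]


def window_identity(seq_a: str, seq_b: str, window: int = 100,
                    method: str = "align") -> np.ndarray:
    """Percent identity per window, indexed from the start codon outward.

    Window 1 covers bases 1..window upstream of the start codon (the 3' end
    of the input sequences), window 2 the next ``window`` bases, and so on.
    ``method='align'`` aligns each window pair globally (needle-style
    scoring); ``method='ungapped'`` compares columns directly. Windows where
    either sequence is more than half N are returned as NaN.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("upstream sequences must have equal length")
    if len(seq_a) % window != 0:
        raise ValueError("sequence length must be divisible by the window size")
    n_windows = len(seq_a) // window
    out = np.empty(n_windows)
    for i in range(1, n_windows + 1):
        hi = len(seq_a) - (i - 1) * window
        lo = hi - window
        wa, wb = seq_a[lo:hi].upper(), seq_b[lo:hi].upper()
        if wa.count("N") > window // 2 or wb.count("N") > window // 2:
            out[i - 1] = np.nan
        elif method == "align":
            out[i - 1] = _needle_identity(wa, wb)
        elif method == "ungapped":
            out[i - 1] = 100.0 * sum(x == y for x, y in zip(wa, wb)) / window
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def compare_identity(profiles_a: np.ndarray, profiles_b: np.ndarray
                     ) -> pd.DataFrame:
    """One-tailed Wilcoxon rank-sum test per window (A lower than B).

    Exact p-values when the combined sample is small (n <= 20, no ties),
    otherwise the tie-corrected normal approximation. Windows where all
    values are tied yield NaN with a flag.
    """
    profiles_a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    profiles_b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if profiles_a.shape[0] < 3 or profiles_b.shape[0] < 3:
        raise ValueError("need at least 3 profiles per group")
    if profiles_a.shape[1] != profiles_b.shape[1]:
        raise ValueError("profiles must cover the same windows")
    rows = []
    for w in range(profiles_a.shape[1]):
        a = profiles_a[:, w]
        b = profiles_b[:, w]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        pooled = np.concatenate([a, b])
        if len(a) == 0 or len(b) == 0 or np.ptp(pooled) == 0:
            rows.append((w + 1, np.nan, True))
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        _, p = stats.mannwhitneyu(a, b, alternative="less", method=method)
        rows.append((w + 1, float(p), False))
    return pd.DataFrame(rows, columns=["window", "p", "all_tied"])


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix with an exact score-distribution p-value table.

    ``probs`` is the pseudocount-smoothed 4 x w probability matrix (rows
    A, C, G, T; columns sum to 1); log-odds are in bits against the
    background. P-values are exact under the 0-order background model,
    computed by dynamic programming over integer scores at ``resolution``
    bits per unit.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    resolution: float = 1e-3
    _int_scores: np.ndarray = field(init=False, repr=False)
    _pv_offset: int = field(init=False, repr=False)
    _pv_table: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("probability matrix must have 4 rows (A,C,G,T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0):
            raise ValueError("PWM columns must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("background must sum to 1")
        self.log_odds = np.log2(self.probs / self.background[:, None])
        self._int_scores = np.round(self.log_odds / self.resolution).astype(int)
        self._build_pvalue_table()

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray,
                    pseudocount: float = 0.1,
                    background: np.ndarray | None = None, **kwargs) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        probs = (counts + pseudocount * bg[:, None]) / (
            counts.sum(axis=0) + pseudocount)
        return cls(motif_id, probs, bg, **kwargs)

    def _build_pvalue_table(self) -> None:
        lo = int(self._int_scores.min(axis=0).sum())
        hi = int(self._int_scores.max(axis=0).sum())
        dist = np.zeros(hi - lo + 1)
        dist[-lo if lo < 0 else 0] = 0.0
        # DP over columns: distribution of the integer score of a random w-mer
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(self.width):
            col = self._int_scores[:, j]
            new_lo = cur_lo + int(col.min())
            new_hi = cur_lo + len(cur) - 1 + int(col.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                shift = cur_lo + int(col[b]) - new_lo
                new[shift:shift + len(cur)] += self.background[b] * cur
            cur, cur_lo = new, new_lo
        assert math.isclose(cur.sum(), 1.0, abs_tol=1e-9)
        # tail probabilities: P(score_int >= s)
        self._pv_table = np.cumsum(cur[::-1])[::-1]
        self._pv_offset = cur_lo

    def int_score(self, kmer: str) -> int:
        return int(sum(self._int_scores[_BASE_IDX[c], j]
                       for j, c in enumerate(kmer.upper())))

    def score(self, kmer: str) -> float:
        return float(sum(self.log_odds[_BASE_IDX[c], j]
                         for j, c in enumerate(kmer.upper())))

    def pvalue(self, kmer: str) -> float:
        """Exact P(random w-mer scores >= this k-mer) under the background."""
        s = self.int_score(kmer) - self._pv_offset
        if s < 0:
            return 1.0
        if s >= len(self._pv_table):
            return 0.0
        return float(self._pv_table[s])


def read_jaspar(text: str) -> list[PWM]:
    """Parse motifs from JASPAR PFM text (``>ID name`` plus 4 count rows)."""
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is not None:
            if len(rows) != 4:
                raise ValueError(f"motif {motif_id!r} needs 4 rows, got {len(rows)}")
            pwms.append(PWM.from_counts(motif_id, np.array(rows)))
        rows, motif_id = [], None

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            motif_id = line[1:].split()[0]
        else:
            cleaned = line
            for ch in "ACGTacgt[]":
                cleaned = cleaned.replace(ch, " ")
            rows.append([float(x) for x in cleaned.split()])
    flush()
    return pwms


def scan_motifs(sequences: dict[str, str] | str, pwms: list[PWM] | PWM,
                p_threshold: float = 1e-4, both_strands: bool = True
                ) -> pd.DataFrame:
    """Scan sequences with PWMs, emitting hits below the p-value threshold.

    Offsets are 0-based within the scanned sequence and always refer to the
    forward strand; windows containing N are skipped. Regions shorter than a
    motif produce no hits for it.
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    if isinstance(pwms, PWM):
        pwms = [pwms]
    rows = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        for pwm in pwms:
            w = pwm.width
            strands = [("+", seq)]
            if both_strands:
                strands.append(("-", revcomp(seq)))
            for strand, s in strands:
                for off in range(len(s) - w + 1):
                    kmer = s[off:off + w]
                    if any(c not in _BASE_IDX for c in kmer):
                        continue
                    p = pwm.pvalue(kmer)
                    if p < p_threshold:
                        fwd_off = off if strand == "+" else len(s) - w - off
                        rows.append((seq_id, pwm.motif_id, fwd_off, strand,
                                     pwm.score(kmer), p))
    return pd.DataFrame(rows, columns=["seq_id", "motif_id", "offset",
                                       "strand", "score", "pvalue"])


def differential_hits(hits_a: pd.DataFrame, hits_b: pd.DataFrame,
                      pair_ids: list[str],
                      motif_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-motif presence asymmetry between the two alleles of each pair.

    ``hits_a``/``hits_b`` are scan_motifs outputs whose seq_id column holds
    pair ids. Each (motif, pair) combination is categorized as A_only,
    B_only, both, or neither.
    """
    if motif_ids is None:
        motif_ids = sorted(set(hits_a.get("motif_id", pd.Series(dtype=object)))
                           | set(hits_b.get("motif_id", pd.Series(dtype=object))))
    present_a = set(map(tuple, hits_a[["seq_id", "motif_id"]].to_numpy().tolist())) \
        if len(hits_a) else set()
    present_b = set(map(tuple, hits_b[["seq_id", "motif_id"]].to_numpy().tolist())) \
        if len(hits_b) else set()
    rows = []
    for motif in motif_ids:
        for pair in pair_ids:
            in_a = (pair, motif) in present_a
            in_b = (pair, motif) in present_b
            category = ("both" if in_a and in_b else
                        "A_only" if in_a else
                        "B_only" if in_b else "neither")
            rows.append((motif, pair, category))
    out = pd.DataFrame(rows, columns=["motif_id", "pair_id", "category"])
    return out


def metagene_matrix(track: pd.DataFrame, gene_models: dict[str, GeneModel],
                    up: int = 2000, down: int = 2000, body_bins: int = 100,
                    flank_bin: int = 100) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene signal matrix over scaled gene bodies with fixed-width flanks.

    ``track`` is a bedGraph frame (chrom, start, end, value; 0-based
    half-open). Rows are oriented TSS-left regardless of strand; the gene
    body is rescaled to ``body_bins`` mean-per-bin values and each flank is
    binned at ``flank_bin`` bp. Genes whose locus is not covered by the track
    give all-NaN rows. Also returns the column-wise mean profile.
    """
    if up % flank_bin or down % flank_bin:
        raise ValueError("flank lengths must be divisible by the bin width")
    dense: dict[str, np.ndarray] = {}
    for chrom, sub in track.groupby("chrom"):
        arr = np.full(int(sub["end"].max()), np.nan)
        for start, end, value in sub[["start", "end", "value"]].to_numpy():
            arr[int(start):int(end)] = value
        dense[chrom] = arr

    n_up, n_down = up // flank_bin, down // flank_bin
    n_cols = n_up + body_bins + n_down
    rows = {}
    for gene_id, model in gene_models.items():
        lo, hi = model.start - up, model.end + down
        arr = dense.get(model.chrom)
        if arr is None or lo < 0 or hi > len(arr):
            rows[gene_id] = np.full(n_cols, np.nan)
            continue
        window = arr[lo:hi]
        left = window[:up].reshape(n_up, flank_bin).mean(axis=1)
        right = window[up + (model.end - model.start):].reshape(
            n_down, flank_bin).mean(axis=1)
        body = window[up:up + (model.end - model.start)]
        if len(body) >= body_bins:
            edges = np.floor(np.linspace(0, len(body), body_bins + 1)).astype(int)
            body_binned = np.array([body[edges[i]:edges[i + 1]].mean()
                                    for i in range(body_bins)])
        else:  # short gene: nearest-position sampling
            pick = np.floor(np.linspace(0, len(body) - 1, body_bins)).astype(int)
            body_binned = body[pick].astype(float)
        profile = np.concatenate([left, body_binned, right])
        if model.strand == "-":
            profile = profile[::-1]
        rows[gene_id] = profile
    cols = ([f"up{i}" for i in range(n_up)]
            + [f"body{i}" for i in range(body_bins)]
            + [f"down{i}" for i in range(n_down)])
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return matrix, matrix.mean(axis=0)
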