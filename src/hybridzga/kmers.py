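"""Parental-origin read assignment via species-diagnostic k-mers.

In crosses between species whose orthologs differ at ~14% of sites, nearly
every transcript k-mer (k around 21) is private to one species. Indexing the
canonical (strand-collapsed) k-mers found in exactly one species' transcript
set lets each read be assigned a parental species by counting diagnostic
k-mer matches, with a margin rule housing the ambiguous complement, and a
gene by plurality over the matched k-mers' pair ids.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode
from .counts import ParentCountMatrix, maternal_species

_CHUNK = 50_000


def kmer_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes along each row of a base-code matrix.

    Returns (codes, valid): uint64 codes of shape (n, L-k+1) and a boolean
    mask marking windows free of non-ACGT bases.
    """
    if mat.ndim == 1:
        mat = mat[None, :]
    n, L = mat.shape
    m = L - k + 1
    if m <= 0:
        return (np.zeros((n, 0), np.uint64), np.zeros((n, 0), bool))
    mask = np.uint64((1 << (2 * k)) - 1)
    codes = np.zeros((n, m), dtype=np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    base = (mat & 3).astype(np.uint64)
    for j in range(L):
        acc = ((acc << np.uint64(2)) | base[:, j]) & mask
        if j >= k - 1:
            codes[:, j - k + 1] = acc
    ok = (mat < 4).astype(np.int32)
    cs = np.concatenate([np.zeros((n, 1), np.int32), np.cumsum(ok, axis=1)], axis=1)
    valid = (cs[:, k:] - cs[:, :-k]) == k
    return codes, valid


def canonical_kmer_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-collapsed k-mer codes: min(forward, reverse-complement)."""
    if mat.ndim == 1:
        mat = mat[None, :]
    fwd, valid = kmer_codes(mat, k)
    rc_mat = np.where(mat < 4, 3 - mat, mat)[:, ::-1]
    rc, _ = kmer_codes(rc_mat, k)
    rc = rc[:, ::-1]
    return np.minimum(fwd, rc), valid


@dataclass
class DiagnosticIndex:
    """Canonical k-mers private to one species' transcript set.

    ``codes`` is sorted; ``species`` holds 0 for A / 1 for B, ``pair_idx``
    the owning ortholog pair (or -1 when the k-mer occurs in several pairs of
    the same species and is therefore species- but not gene-diagnostic).
    """

    k: int
    codes: np.ndarray
    species: np.ndarray
    pair_idx: np.ndarray
    pair_ids: list[str]
    n_shared: int
    checksum: str = ""

    def __len__(self) -> int:
        return len(self.codes)

    def swapped(self) -> "DiagnosticIndex":
        """The index with species labels A and B exchanged."""
        return DiagnosticIndex(self.k, self.codes,
                               (1 - self.species).astype(self.species.dtype),
                               self.pair_idx, self.pair_ids, self.n_shared,
                               self.checksum)


def _species_kmers(transcripts: dict[str, str], k: int,
                   pair_order: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Unique canonical k-mers of one species with per-code pair ownership."""
    code_blocks, pair_blocks = [], []
    for pair_id, seq in transcripts.items():
        if len(seq) < k:
            warnings.warn(f"transcript {pair_id!r} shorter than k={k}; skipped")
            continue
        codes, valid = canonical_kmer_codes(encode(seq), k)
        codes = codes[valid]
        code_blocks.append(codes)
        pair_blocks.append(np.full(codes.size, pair_order[pair_id], np.int32))
    if not code_blocks:
        return np.zeros(0, np.uint64), np.zeros(0, np.int32)
    codes = np.concatenate(code_blocks)
    pairs = np.concatenate(pair_blocks)
    order = np.lexsort((pairs, codes))
    codes, pairs = codes[order], pairs[order]
    uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
    last = first + counts - 1
    owner = np.where(pairs[first] == pairs[last], pairs[first], -1).astype(np.int32)
    return uniq, owner


def build_index(transcripts_a: dict[str, str], transcripts_b: dict[str, str],
                k: int = 21) -> DiagnosticIndex:
    """Build the diagnostic k-mer index from both species' transcript sets.

    K-mers present in both species are excluded (and counted in
    ``n_shared``); the remainder map to exactly one species.
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and within [11, 31]")
    if not transcripts_a or not transcripts_b:
        raise ValueError("transcript sets must be non-empty")
    pair_ids = sorted(set(transcripts_a) | set(transcripts_b))
    pair_order = {p: i for i, p in enumerate(pair_ids)}
    codes_a, pairs_a = _species_kmers(transcripts_a, k, pair_order)
    codes_b, pairs_b = _species_kmers(transcripts_b, k, pair_order)
    shared = np.intersect1d(codes_a, codes_b, assume_unique=True)
    keep_a = ~np.isin(codes_a, shared, assume_unique=False)
    keep_b = ~np.isin(codes_b, shared, assume_unique=False)
    codes = np.concatenate([codes_a[keep_a], codes_b[keep_b]])
    species = np.concatenate([
        np.zeros(int(keep_a.sum()), np.int8),
        np.ones(int(keep_b.sum()), np.int8),
    ])
    pair_idx = np.concatenate([pairs_a[keep_a], pairs_b[keep_b]])
    order = np.argsort(codes, kind="stable")
    digest = hashlib.sha1()
    for p in pair_ids:
        digest.update(p.encode())
        digest.update(transcripts_a.get(p, "").encode())
        digest.update(transcripts_b.get(p, "").encode())
    return DiagnosticIndex(k, codes[order], species[order], pair_idx[order],
                           pair_ids, int(shared.size), digest.hexdigest())


def _reads_to_matrix(reads) -> tuple[list[str], list[np.ndarray]]:
    """Normalize supported read inputs to (ids, list of code-row blocks)."""
    from .simulate.reads import ReadSet

    if isinstance(reads, ReadSet):
        return list(reads.ids), [reads.seqs]
    ids, seqs = [], []
    for i, item in enumerate(reads):
        if isinstance(item, tuple):
            rid, seq = item
        else:
            rid, seq = f"read{i}", item
        ids.append(rid)
        seqs.append(seq)
    if not seqs:
        return ids, []
    blocks = [np.stack([encode(s.ljust(max(map(len, seqs)), "N")) for s in seqs])]
    return ids, blocks


def assign_reads(reads, index: DiagnosticIndex, min_diagnostic: int = 2,
                 margin: int = 2) -> pd.DataFrame:
    """Assign each read a parental species and gene.

    A read is called species A when it carries at least ``min_diagnostic``
    A-diagnostic k-mers and at least ``margin`` more of them than
    B-diagnostic ones (symmetrically for B); otherwise it is ambiguous. The
    gene is the ortholog pair holding the plurality of the called species'
    gene-diagnostic matches; ties leave the gene unassigned.

    Returns a frame with read_id, n_a, n_b, species_call, pair_id.
    """
    ids, blocks = _reads_to_matrix(reads)
    n_pairs = len(index.pair_ids)
    out_na = np.zeros(len(ids), np.int32)
    out_nb = np.zeros(len(ids), np.int32)
    out_pair = np.full(len(ids), -1, np.int32)
    row0 = 0
    for block in blocks:
        for lo in range(0, len(block), _CHUNK):
            sub = block[lo:lo + _CHUNK]
            nrows = len(sub)
            codes, valid = canonical_kmer_codes(sub, index.k)
            q = codes.ravel()
            v = valid.ravel()
            pos = np.searchsorted(index.codes, q)
            pos_ok = pos < len(index.codes)
            hit = v & pos_ok
            hit[pos_ok] &= index.codes[pos[pos_ok]] == q[pos_ok]
            rows = np.nonzero(hit)[0] // max(codes.shape[1], 1)
            sp = index.species[pos[hit]]
            pr = index.pair_idx[pos[hit]]
            na = np.bincount(rows[sp == 0], minlength=nrows)
            nb = np.bincount(rows[sp == 1], minlength=nrows)
            call_a = (na >= min_diagnostic) & (na - nb >= margin)
            call_b = (nb >= min_diagnostic) & (nb - na >= margin)
            # plurality vote over gene-diagnostic k-mers of the called species
            called_sp = np.where(call_a, 0, np.where(call_b, 1, -1))
            use = (pr >= 0) & (called_sp[rows] == sp)
            key = rows[use].astype(np.int64) * n_pairs + pr[use]
            votes = np.bincount(key, minlength=nrows * n_pairs)
            votes = votes.reshape(nrows, n_pairs)
            top = votes.max(axis=1)
            tie = (votes == top[:, None]).sum(axis=1) > 1
            gene = np.where((called_sp >= 0) & (top > 0) & ~tie,
                            votes.argmax(axis=1), -1)
            sl = slice(row0 + lo, row0 + lo + nrows)
            out_na[sl] = na
            out_nb[sl] = nb
            out_pair[sl] = gene
        row0 += len(block)

    call = np.full(len(ids), "ambiguous", dtype=object)
    call[(out_na >= min_diagnostic) & (out_na - out_nb >= margin)] = "A"
    call[(out_nb >= min_diagnostic) & (out_nb - out_na >= margin)] = "B"
    pair_col = pd.array(
        [index.pair_ids[i] if i >= 0 else None for i in out_pair], dtype=object)
    return pd.DataFrame({
        "read_id": ids, "n_a": out_na, "n_b": out_nb,
        "species_call": call, "pair_id": pair_col,
    })


def counts_by_parent(assignments: pd.DataFrame, cross: str, stage: str
                     ) -> ParentCountMatrix:
    """Tally unambiguous assignments into maternal/paternal gene counts.

    Ambiguous reads (and reads with a species but no gene) are excluded from
    both numerator and denominator; the ambiguous total is kept per stage.
    """
    mat_sp = maternal_species(cross)
    ok = assignments["species_call"].isin(["A", "B"])
    n_ambiguous = int((~ok).sum())
    usable = assignments[ok & assignments["pair_id"].notna()]
    origin = np.where(usable["species_call"] == mat_sp, "maternal", "paternal")
    tab = (pd.crosstab(usable["pair_id"], origin)
           .reindex(columns=["maternal", "paternal"], fill_value=0)
           .rename_axis(index="pair_id", columns=None))
    data = tab.reset_index().rename(columns={"pair_id": "pair_id"})
    data.insert(1, "stage", stage)
    for col in ("maternal", "paternal"):
        if col not in data:
            data[col] = 0
    return ParentCountMatrix(cross, data[["pair_id", "stage", "maternal",
                                          "paternal"]],
                             {stage: n_ambiguous})
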