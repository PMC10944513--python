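"""Readers and writers for the standard formats the pipeline touches.

Conventions: GTF is 1-based closed (converted to 0-based half-open
internally), BED/bedGraph are 0-based half-open throughout. FASTA/FASTQ go
through Biopython; cell matrices are stored as MatrixMarket plus feature,
barcode, and metadata TSVs; simulation configs round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as scipy_io
from scipy import sparse

from .config import SimConfig
from .counts import ParentCountMatrix
from .kmers import DiagnosticIndex
from .simulate.genomes import GeneModel


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = (SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items())
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ----------------------------------------------------------------------- GTF

def write_gtf(gene_models: dict[str, GeneModel], path,
              source: str = "hybridzga") -> None:
    """Write exon features, 1-based closed coordinates per GTF convention."""
    with open(path, "w") as fh:
        for gene_id, model in gene_models.items():
            for start, end in model.exons:
                attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
                fh.write("\t".join([
                    model.chrom, source, "exon", str(start + 1), str(end),
                    ".", model.strand, ".", attrs]) + "\n")


def read_gtf(path) -> dict[str, GeneModel]:
    """Parse exon features back into gene models (0-based half-open)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 fields, "
                                  f"got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "exon":
                continue
            try:
                interval = (int(start) - 1, int(end))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates")
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split('"')[1]
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            entry = genes.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            entry["exons"].append(interval)
    return {
        gene_id: GeneModel(gene_id, e["chrom"], e["strand"],
                           tuple(sorted(e["exons"])))
        for gene_id, e in genes.items()
    }


# ------------------------------------------------------------------ bedGraph

def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df[["start", "end"]].isna().any().any():
        bad = int(df[["start", "end"]].isna().any(axis=1).idxmax()) + 1
        raise FormatError(f"{path}:{bad}: malformed interval")
    return df


# -------------------------------------------------------------- count tables

def write_parent_counts(pcm: ParentCountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#cross={pcm.cross}\n")
        amb = ",".join(f"{s}:{n}" for s, n in pcm.ambiguous.items())
        fh.write(f"#ambiguous={amb}\n")
        pcm.data.to_csv(fh, sep="\t", index=False)


def read_parent_counts(path) -> ParentCountMatrix:
    cross = None
    ambiguous: dict[str, int] = {}
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            if key == "cross":
                cross = value
            elif key == "ambiguous" and value:
                for item in value.split(","):
                    stage, _, n = item.partition(":")
                    ambiguous[stage] = int(n)
    if cross is None:
        raise FormatError(f"{path}: missing #cross header")
    data = pd.read_csv(path, sep="\t", skiprows=header_lines)
    return ParentCountMatrix(cross, data, ambiguous)


def write_fpkm(table, path) -> None:
    from .dynamics import FPKMTable  # local import to avoid a cycle

    assert isinstance(table, FPKMTable)
    with open(path, "w") as fh:
        fh.write(f"#stages={','.join(table.stages)}\n")
        fh.write(f"#flagged={','.join(table.flagged_stages)}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def read_fpkm(path):
    from .dynamics import FPKMTable

    meta: dict[str, str] = {}
    with open(path) as fh:
        n_header = 0
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    if "stages" not in meta:
        raise FormatError(f"{path}: missing #stages header")
    data = pd.read_csv(path, sep="\t", skiprows=n_header)
    flagged = meta.get("flagged", "")
    return FPKMTable(data, meta["stages"].split(","),
                     flagged.split(",") if flagged else [])


# ------------------------------------------------------------ k-mer index TSV

def write_index(index: DiagnosticIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={index.k}\n")
        fh.write(f"#checksum={index.checksum}\n")
        fh.write(f"#n_shared={index.n_shared}\n")
        fh.write(f"#pairs={','.join(index.pair_ids)}\n")
        fh.write("kmer\tspecies\tpair_idx\n")
        for code, sp, pr in zip(index.codes, index.species, index.pair_idx):
            fh.write(f"{code:x}\t{'AB'[sp]}\t{pr}\n")


def read_index(path) -> DiagnosticIndex:
    meta: dict[str, str] = {}
    with open(path) as fh:
        n_header = 0
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    for key in ("k", "checksum", "n_shared", "pairs"):
        if key not in meta:
            raise FormatError(f"{path}: missing #{key} header")
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    codes = np.array([int(c, 16) for c in df["kmer"]], dtype=np.uint64)
    species = np.array([0 if s == "A" else 1 for s in df["species"]], np.int8)
    return DiagnosticIndex(
        int(meta["k"]), codes, species,
        df["pair_idx"].to_numpy(np.int32),
        meta["pairs"].split(",") if meta["pairs"] else [],
        int(meta["n_shared"]), meta["checksum"])


# --------------------------------------------------------------- cell matrix

def write_cell_matrix(adata: ad.AnnData, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(np.asarray(adata.X))
    scipy_io.mmwrite(str(out_dir / "matrix.mtx"), X)
    adata.var.to_csv(out_dir / "features.tsv", sep="\t")
    adata.obs.to_csv(out_dir / "metadata.tsv", sep="\t")


def read_cell_matrix(in_dir) -> ad.AnnData:
    in_dir = Path(in_dir)
    X = scipy_io.mmread(str(in_dir / "matrix.mtx")).toarray()
    var = pd.read_csv(in_dir / "features.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(in_dir / "metadata.tsv", sep="\t", index_col=0)
    if "is_marker" in var:
        var["is_marker"] = var["is_marker"].astype(bool)
    if "marker_lineage" in var:
        var["marker_lineage"] = var["marker_lineage"].fillna("")
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


# ---------------------------------------------------------------------- YAML

def save_sim_config(config: SimConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["stages"] = list(data["stages"])
    data["biased_upstream_window"] = list(data["biased_upstream_window"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    if "biased_upstream_window" in data:
        data["biased_upstream_window"] = tuple(data["biased_upstream_window"])
    return SimConfig(**data)
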