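"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython, VCF reading through pysam, tables through
pandas TSV with a ``#``-prefixed provenance header (config hash + seed) that
readers skip.  All writers produce byte-identical output for identical
inputs.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_TABLE_COLUMNS = ["gene_id", "genome", "scaffold", "rank", "strand"]
HITS_COLUMNS = ["query", "subject", "bitscore", "evalue"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_gene_table(path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} lacks columns {sorted(missing)}")
    return df[GENE_TABLE_COLUMNS]


def read_gene_table_gff3(path) -> pd.DataFrame:
    """GFF3 subset reader: gene features ordered into 0-based ranks per scaffold.

    Only ``gene`` features are used; the gene id comes from the ``ID``
    attribute.  GFF3 1-based starts are used for ordering only; the returned
    table carries scaffold, rank, strand.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _, ftype, start, _, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            rows.append((gene_id, seqid, int(start), strand))
    df = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "strand"])
    df = df.sort_values(["scaffold", "start"], kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("scaffold").cumcount()
    df["genome"] = "unknown"
    return df[GENE_TABLE_COLUMNS]


def read_hits_table(path) -> pd.DataFrame:
    df = read_table(path)
    if set(HITS_COLUMNS) <= set(df.columns):
        return df[HITS_COLUMNS]
    # 12-column tabular homology dialect (qseqid sseqid pident length mismatch
    # gapopen qstart qend sstart send evalue bitscore), headerless
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != 12:
        raise ValueError(f"hits table {path} is neither 4-column TSV nor 12-column tabular")
    out = df[[0, 1, 11, 10]].copy()
    out.columns = HITS_COLUMNS
    return out


def read_trace_log(path) -> pd.DataFrame:
    """Tab-separated MCMC log: a header of statistic names, one row per sample."""
    df = read_table(path)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"trace log {path} is empty")
    return df


def write_trace_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path) -> np.ndarray:
    """0/1 matrix TSV (haplotypes x sites), '.' or -1 for missing."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", na_values=["."])
    mat = df.to_numpy(dtype=float)
    mat = np.where(np.isnan(mat), -1, mat)
    return mat.astype(np.int8)


def write_haplotypes_tsv(h: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(h, dtype=int)).to_csv(path, sep="\t", header=False, index=False)


def write_vcf(h: np.ndarray, path, chrom: str = "locus1", positions=None) -> None:
    """Minimal phased biallelic VCF for an (n, L) 0/1 haplotype matrix.

    Haplotypes are paired into diploid sample columns (n must be even); only
    segregating sites are emitted.
    """
    h = np.asarray(h)
    n, L = h.shape
    if n % 2 != 0:
        raise ValueError("VCF output pairs haplotypes into diploids; n must be even")
    if positions is None:
        positions = np.arange(1, L + 1)
    samples = [f"ind{k:02d}" for k in range(n // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(L):
            col = h[:, j]
            if not ((col == 1).any() and (col == 0).any()):
                continue
            gts = []
            for k in range(0, n, 2):
                a = "." if col[k] < 0 else str(int(col[k]))
                b = "." if col[k + 1] < 0 else str(int(col[k + 1]))
                gts.append(f"{a}|{b}")
            fh.write(f"{chrom}\t{int(positions[j])}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf_haplotypes(path) -> np.ndarray:
    """Phased biallelic SNPs from a VCF into an (n_haplotypes, S) 0/1 matrix."""
    import pysam

    cols: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            col: list[int] = []
            for sample in rec.samples.values():
                gt = sample["GT"]
                for allele in gt:
                    col.append(MISSING_VCF if allele is None else int(allele))
            cols.append(col)
    if not cols:
        raise ValueError(f"no biallelic SNP records in {path}")
    return np.array(cols, dtype=np.int8).T


MISSING_VCF = -1


def read_newick(path_or_string: str):
    """Parse a newick topology (Biopython tree)."""
    from Bio import Phylo

    p = Path(path_or_string)
    if p.exists():
        return Phylo.read(str(p), "newick")
    return Phylo.read(_io.StringIO(path_or_string), "newick")


def newick_leaf_names(tree) -> list[str]:
    return sorted(t.name for t in tree.get_terminals())
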