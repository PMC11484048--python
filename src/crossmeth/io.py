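"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, VCF reading via pysam, tabular formats via pandas.
Internally everything is 0-based half-open; VCF and GTF are converted to/from
their 1-based conventions at this boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------- BED


def read_bed(path, names=("chrom", "start", "end", "name", "score", "strand")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- VCF (SNPs)


def write_snp_vcf(snps, contig_lengths: dict[str, int], path) -> None:
    """Write SNP records (chrom, pos0, ref, alt) as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, n in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in snps:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def read_snp_vcf(path) -> list[tuple[str, int, str, str]]:
    """Read single-base substitutions from a VCF; other records are skipped."""
    import pysam

    out = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt != rec.ref:
                    out.append((rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


# ---------------------------------------------------------------- SV BED


def write_sv_bed(svs, path) -> None:
    """SV records (chrom, start0, end0, type, length, sequence) to BED."""
    with open(path, "w") as fh:
        for chrom, s, e, typ, length, seq in svs:
            fh.write(f"{chrom}\t{s}\t{e}\t{typ}\t{length}\t{seq}\n")


def read_sv_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, s, e, typ, length, seq = line.rstrip("\n").split("\t")
            out.append((chrom, int(s), int(e), typ, int(length), seq))
    return out


# ---------------------------------------------------------------- methylation call sets


@dataclass
class MethylationCallSet:
    """Per-sample per-CpG methylation calls on one reference.

    ``df`` columns: chrom, pos0, strand, coverage, n_meth. ``stranded`` is
    True when forward and reverse cytosines are still separate rows.
    """

    sample_id: str
    reference: str
    df: pd.DataFrame
    stranded: bool = True

    def __post_init__(self) -> None:
        d = self.df
        if ((d["n_meth"] < 0) | (d["n_meth"] > d["coverage"])).any():
            raise ValueError("n_meth outside [0, coverage]")

    def percent(self) -> np.ndarray:
        return 100.0 * self.df["n_meth"].to_numpy() / self.df["coverage"].to_numpy()


def write_bedgraph(calls: MethylationCallSet, path) -> None:
    """MethylDackel-style bedGraph: chrom start end pct n_meth n_unmeth."""
    d = calls.df
    pct = np.round(100.0 * d["n_meth"] / d["coverage"], 2)
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["pos0"],
            "end": d["pos0"] + 1,
            "pct": pct,
            "n_meth": d["n_meth"],
            "n_unmeth": d["coverage"] - d["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, sample_id: str, reference: str = "", strand_from_name=None) -> MethylationCallSet:
    """Read a MethylDackel bedGraph. Strand is not encoded in this format;
    rows are taken as-is (strand '+'), suitable for already-destranded data
    or for formats where each cytosine appears on its own position."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith(("track", "#"))].reset_index(drop=True)
    df[["start", "end", "n_meth", "n_unmeth"]] = df[["start", "end", "n_meth", "n_unmeth"]].astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos0": df["start"],
            "strand": "+",
            "coverage": df["n_meth"] + df["n_unmeth"],
            "n_meth": df["n_meth"],
        }
    )
    return MethylationCallSet(sample_id, reference, out, stranded=True)


def write_methylkit(calls: MethylationCallSet, path) -> None:
    """methylKit text: chrBase chr base strand coverage freqC freqT (base 1-based)."""
    d = calls.df
    base = d["pos0"] + 1
    freq_c = np.round(100.0 * d["n_meth"] / d["coverage"], 2)
    out = pd.DataFrame(
        {
            "chrBase": d["chrom"].astype(str) + "." + base.astype(str),
            "chr": d["chrom"],
            "base": base,
            "strand": d["strand"].map({"+": "F", "-": "R"}),
            "coverage": d["coverage"],
            "freqC": freq_c,
            "freqT": np.round(100.0 - freq_c, 2),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_methylkit(path, sample_id: str, reference: str = "") -> MethylationCallSet:
    df = pd.read_csv(path, sep="\t")
    n_meth = np.rint(df["coverage"] * df["freqC"] / 100.0).astype(int)
    out = pd.DataFrame(
        {
            "chrom": df["chr"],
            "pos0": df["base"] - 1,
            "strand": df["strand"].map({"F": "+", "R": "-"}),
            "coverage": df["coverage"],
            "n_meth": n_meth,
        }
    )
    return MethylationCallSet(sample_id, reference, out, stranded=True)


def write_cytosine_report(calls: MethylationCallSet, path) -> None:
    """Bismark/MethylDackel cytosine report: chrom pos1 strand n_meth n_unmeth context tri."""
    d = calls.df
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "pos1": d["pos0"] + 1,
            "strand": d["strand"],
            "n_meth": d["n_meth"],
            "n_unmeth": d["coverage"] - d["n_meth"],
            "context": "CpG",
            "tri": "CG" + pd.Series("N", index=d.index),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path, sample_id: str, reference: str = "") -> MethylationCallSet:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos1", "strand", "n_meth", "n_unmeth", "context", "tri"],
    )
    df = df[df["context"] == "CpG"]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos0": df["pos1"] - 1,
            "strand": df["strand"],
            "coverage": df["n_meth"] + df["n_unmeth"],
            "n_meth": df["n_meth"],
        }
    ).reset_index(drop=True)
    return MethylationCallSet(sample_id, reference, out, stranded=True)


# ---------------------------------------------------------------- sample sheet


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "sex"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- GTF


def write_gene_gtf(genes: pd.DataFrame, path, source: str = "crossmeth") -> None:
    """Gene rows (chrom, start0, end0, strand, gene_id) as GTF 'gene' features."""
    with open(path, "w") as fh:
        for r in genes.itertuples(index=False):
            attrs = f'gene_id "{r.gene_id}";'
            fh.write(
                f"{r.chrom}\t{source}\tgene\t{r.start0 + 1}\t{r.end0}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_gene_gtf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].strip().rstrip(";").split(";") if kv.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            rows.append((f[0], int(f[3]) - 1, int(f[4]), f[6], gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start0", "end0", "strand", "gene_id"])


# ---------------------------------------------------------------- PAF


@dataclass
class PafRecord:
    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    aln_len: int
    mapq: int
    cs: str | None = None
    tags: dict = field(default_factory=dict)


def read_paf(path) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tags = {}
            cs = None
            for t in f[12:]:
                k, typ, v = t.split(":", 2)
                tags[k] = v
                if k == "cs":
                    cs = v
            out.append(
                PafRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4], f[5],
                    int(f[6]), int(f[7]), int(f[8]), int(f[9]), int(f[10]),
                    int(f[11]), cs=cs, tags=tags,
                )
            )
    return out
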