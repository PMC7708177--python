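"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables are tab-separated; sequences are FASTA (Biopython, 60-column wrap);
feature intervals are GFF3 (1-based inclusive) or BED (0-based half-open).
Internally all intervals are 0-based half-open.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# expression matrices and triad designs


def read_counts(path: str | Path) -> pd.DataFrame:
    """miRNA x sample abundance matrix from TSV (first column = miRNA ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"negative values in expression matrix {path}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="mirna")


@dataclass
class TriadDesign:
    """Sample sheet linking each hybrid group to its parental inbred groups.

    ``table`` has one row per sequencing sample with columns group, role
    (maternal | paternal | hybrid), triad and sample.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("group", "role", "triad", "sample")
    ROLES = ("maternal", "paternal", "hybrid")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        bad = set(self.table["role"]) - set(self.ROLES)
        if bad:
            raise ValueError(f"unknown roles in design table: {sorted(bad)}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TriadDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, columns=list(self.COLUMNS))

    @property
    def triads(self) -> list[str]:
        return sorted(self.table["triad"].unique())

    def samples(self, triad: str, role: str) -> list[str]:
        sel = self.table[(self.table["triad"] == triad) & (self.table["role"] == role)]
        if sel.empty:
            raise KeyError(f"no {role} samples for triad {triad!r}")
        return list(sel["sample"])

    def group(self, triad: str, role: str) -> str:
        sel = self.table[(self.table["triad"] == triad) & (self.table["role"] == role)]
        groups = sel["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"triad {triad!r} role {role!r} maps to groups {groups}")
        return groups[0]


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seqrecords, str(path), "fasta")  # Biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# feature intervals


@dataclass(frozen=True)
class Feature:
    """Stranded genomic interval, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(end must exceed start in half-open coordinates)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_gff3(path: str | Path) -> list[Feature]:
    """GFF3 features (1-based inclusive on disk -> half-open in memory)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand = parts[:7]
            name = "."
            if len(parts) > 8:
                for kv in parts[8].split(";"):
                    if kv.startswith(("ID=", "Name=")):
                        name = kv.split("=", 1)[1]
                        break
            feats.append(
                Feature(chrom, int(start) - 1, int(end), strand, ftype, name)
            )
    return feats


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "heteromir") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\t{source}\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.name}\n"
            )


def read_bed(path: str | Path) -> list[Feature]:
    """BED6 features (already 0-based half-open); column 4 holds the class."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _, strand = line.rstrip("\n").split("\t")[:6]
            feats.append(Feature(chrom, int(start), int(end), strand, name, name))
    return feats


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.ftype}\t0\t{f.strand}\n")


def read_features(path: str | Path) -> list[Feature]:
    """Dispatch on extension: .gff/.gff3 -> GFF3, .bed -> BED."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    if suffix == ".bed":
        return read_bed(path)
    raise ValueError(f"unrecognised feature-file extension: {suffix!r}")


# ---------------------------------------------------------------------------
# qPCR Ct tables and term annotations

CT_COLUMNS = ("sample", "replicate", "target_ct", "reference_ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(CT_COLUMNS))


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene -> term map from TSV with columns gene, term[, label]."""
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        df["label"] = df["term"]
    missing = {"gene", "term"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def md5sum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
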