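"""Standard-format I/O helpers.

All internal coordinates are 0-based, half-open. Conversions to the 1-based
inclusive conventions of GFF3 and 12-column tabular alignment files happen
here and nowhere else, so off-by-one drift cannot creep in stage by stage.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violates its declared format; message carries line/record context."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(records: Iterable[tuple[str, str] | tuple[str, str, str]], path) -> None:
    """Write (id, seq[, description]) tuples as FASTA (60-column wrapped)."""
    out = []
    for rec in records:
        rid, seq = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(out, str(path), "fasta")


def read_fastq(path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred_qualities) from a Phred-33 FASTQ file."""
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations["phred_quality"]
        if len(quals) != len(rec.seq):
            raise FormatError(f"FASTQ record {i} ({rec.id}): quality/sequence length mismatch")
        yield rec.id, str(rec.seq).upper(), quals


def write_fastq(records: Iterable[tuple[str, str, list[int]]], path) -> None:
    out = []
    for rid, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        out.append(rec)
    SeqIO.write(out, str(path), "fastq")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk) and BED (0-based half-open on disk)
# ---------------------------------------------------------------------------

GFF3_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_gff3(features, path, source: str = "eccpipe") -> None:
    """Write features with 0-based half-open ``start``/``end`` as GFF3.

    ``features`` are objects with attributes chrom, start, end, strand, plus
    ``feature_id`` and ``feature_type`` (and optionally extra attributes via
    ``gff_attributes()``).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            extra = getattr(f, "gff_attributes", None)
            if extra is not None:
                attrs += ";" + extra()
            fh.write(
                f"{f.chrom}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame with 0-based half-open start/end.

    Returns columns: chrom, source, type, start, end, strand, feature_id, attributes.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(parts)} fields, expected 9")
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": parts[0],
                    "source": parts[1],
                    "type": parts[2],
                    "start": start1 - 1,
                    "end": end1,
                    "strand": parts[6],
                    "feature_id": attrs.get("ID", ""),
                    "attributes": parts[8],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "source", "type", "start", "end", "strand", "feature_id", "attributes"])


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name]) tuples (0-based half-open) as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED (first three or four columns) as 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            rows.append({"chrom": parts[0], "start": start, "end": end,
                         "name": parts[3] if len(parts) > 3 else ""})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    """Write a per-window value table (chrom, start, end, value) as bedGraph."""
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df


# ---------------------------------------------------------------------------
# Generic TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def dataclass_frame(items, cls=None) -> pd.DataFrame:
    """Convert a list of dataclass instances into a DataFrame."""
    if not items and cls is not None:
        return pd.DataFrame(columns=[f.name for f in dataclasses.fields(cls)])
    return pd.DataFrame([dataclasses.asdict(x) for x in items])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
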