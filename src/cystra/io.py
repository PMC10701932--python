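"""Readers/writers for the standard formats the pipeline touches.

This is the single place where coordinate conventions are normalized:
everything downstream uses 0-based half-open intervals.  GFF3 and
tRNAscan-SE tabular output use 1-based inclusive coordinates and are
converted here, once.
"""

from __future__ import annotations

import io as _io
import os
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase, RNA already mapped to DNA)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"sequence {self.id!r} contains non-DNA symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneAnnotation:
    """One tRNA gene or pseudogene locus.

    Coordinates are 0-based half-open on ``seqid``.  ``anticodon`` is the
    three-letter DNA anticodon (e.g. ``"GCA"``) for genes; it may be empty
    for pseudogenes.
    """

    seqid: str
    start: int
    end: int
    strand: str
    gene_id: str
    isotype: str = ""
    anticodon: str = ""
    category: str = "gene"  # {"gene", "pseudogene"}
    high_confidence: bool = False
    contains_n: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.category not in {"gene", "pseudogene"}:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")
        if self.category == "gene" and self.anticodon and len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon must be 3 nt")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA (U) to DNA (T)."""
    return str(seq).upper().replace("U", "T")


def read_fasta(path: str | os.PathLike | _io.TextIOBase) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and U is mapped to T.  An empty file or a
    duplicated record id is an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, normalize_seq(rec.seq), desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_reads(path: str | os.PathLike) -> list[str]:
    """Read sequences (only) from a FASTA or FASTQ file, normalized to DNA."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [normalize_seq(rec.seq) for rec in SeqIO.parse(p, fmt)]


# ---------------------------------------------------------------------------
# GFF3

_TRNA_TYPES = {"tRNA", "trna"}
_PSEUDO_TYPES = {"pseudogene", "tRNA_pseudogene", "pseudogenic_tRNA"}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, val = part.split("=", 1)
        out[key] = urllib.parse.unquote(val)
    return out


def _isotype_anticodon_from_attrs(attrs: Mapping[str, str]) -> tuple[str, str]:
    """Best-effort extraction of isotype/anticodon from GFF3 attributes.

    Recognizes an explicit ``anticodon=`` attribute and ``tRNA-Xxx-NNN``
    patterns in Name/product/ID (TAIR-style naming).
    """
    isotype = attrs.get("isotype", "")
    anticodon = normalize_seq(attrs.get("anticodon", ""))
    for key in ("Name", "product", "ID", "gene"):
        val = attrs.get(key, "")
        if "tRNA-" in val:
            bits = val.split("tRNA-", 1)[1].split("-")
            if bits and not isotype:
                isotype = bits[0].strip()
            if len(bits) > 1 and not anticodon:
                cand = normalize_seq(bits[1][:3])
                if len(cand) == 3 and set(cand) <= VALID_BASES:
                    anticodon = cand
    return isotype, anticodon


def read_gff3_trnas(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read tRNA and pseudogene features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Only features of type tRNA / pseudogene (and common synonyms) are kept.
    """
    annotations: list[GeneAnnotation] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in _TRNA_TYPES | _PSEUDO_TYPES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start {start1} > end {end1}")
            attrs = _parse_gff_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("Name") or f"feature_{lineno}"
            if gene_id in seen_ids:
                gene_id = f"{gene_id}.{lineno}"
            seen_ids.add(gene_id)
            isotype, anticodon = _isotype_anticodon_from_attrs(attrs)
            category = "pseudogene" if ftype in _PSEUDO_TYPES else "gene"
            hc = attrs.get("high_confidence", "").lower() in {"1", "true", "yes"}
            annotations.append(
                GeneAnnotation(
                    seqid=seqid,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in "+-" else "+",
                    gene_id=gene_id,
                    isotype=isotype,
                    anticodon=anticodon if category == "gene" else anticodon,
                    category=category,
                    high_confidence=hc,
                )
            )
    return annotations


def write_gff3_trnas(annotations: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    """Write annotations as GFF3 (inverse of :func:`read_gff3_trnas`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            ftype = "tRNA" if a.category == "gene" else "pseudogene"
            attrs = [f"ID={a.gene_id}"]
            if a.isotype:
                name = f"tRNA-{a.isotype}"
                if a.anticodon:
                    name += f"-{a.anticodon}"
                attrs.append(f"Name={name}")
            if a.high_confidence:
                attrs.append("high_confidence=true")
            fh.write(
                "\t".join(
                    [
                        a.seqid,
                        "cystra",
                        ftype,
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# tRNAscan-SE 2.0 tabular output

#: default note substrings mapping a tRNAscan-SE row to the pseudogene category
DEFAULT_PSEUDO_NOTES = ("pseudo",)


def read_trnascan_table(
    path: str | os.PathLike,
    high_confidence_ids: set[str] | None = None,
    pseudo_notes: Sequence[str] = DEFAULT_PSEUDO_NOTES,
) -> list[GeneAnnotation]:
    """Parse tRNAscan-SE 2.0 tab-separated output.

    Rows with begin > end are reverse-strand calls: coordinates are swapped,
    then converted from 1-based inclusive to 0-based half-open.  A row whose
    note column contains one of ``pseudo_notes`` becomes a pseudogene.
    ``high_confidence_ids``, when given (e.g. from an EukHighConfidenceFilter
    run), overrides note-based confidence assignment.
    """
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        for row_idx, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            # three-line header: title row, column row, dashes row
            first = line.split("\t")[0].strip()
            if first in {"Sequence", "Name"} or first.startswith("--"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 6:
                raise ValueError(f"{path}: row {row_idx}: too few columns")
            name, num, begin_s, end_s, isotype, anticodon = fields[:6]
            note = fields[9] if len(fields) > 9 else ""
            try:
                begin, end = int(begin_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_idx}: malformed numeric field") from exc
            if begin > end:
                strand = "-"
                begin, end = end, begin
            else:
                strand = "+"
            category = "gene"
            low = note.lower()
            if any(p in low for p in pseudo_notes):
                category = "pseudogene"
            gene_id = f"{name}.trna{num}"
            if high_confidence_ids is not None:
                hc = gene_id in high_confidence_ids
            else:
                hc = category == "gene" and "not high confidence" not in low
            annotations.append(
                GeneAnnotation(
                    seqid=name,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    gene_id=gene_id,
                    isotype=isotype,
                    anticodon=normalize_seq(anticodon),
                    category=category,
                    high_confidence=hc,
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# BED6

def write_bed(annotations: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    """Write BED6 (0-based half-open), one line per annotation."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.seqid}\t{a.start}\t{a.end}\t{a.gene_id}\t0\t{a.strand}\n")


def read_bed(path: str | os.PathLike) -> list[GeneAnnotation]:
    annotations = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seqid, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            annotations.append(
                GeneAnnotation(
                    seqid=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    gene_id=name,
                )
            )
    return annotations


def gene_sequence(record: SequenceRecord, annotation: GeneAnnotation) -> str:
    """Extract the gene's sequence 5'→3' in transcription orientation.

    '-'-strand genes are reverse-complemented.  If the sequence contains N
    the annotation's ``contains_n`` flag is set (such genes are excluded from
    identity statistics downstream).
    """
    if annotation.end > len(record.seq):
        raise ValueError(f"{annotation.gene_id} extends past end of {record.id}")
    seq = record.seq[annotation.start : annotation.end]
    if "N" in seq:
        annotation.contains_n = True
    return revcomp(seq) if annotation.strand == "-" else seq
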