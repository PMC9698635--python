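"""Canonical records and readers/writers for the external file formats.

The in-memory records every stage consumes live here: :class:`MiRNALocus`
(one annotated miRNA locus in one species), :class:`ReadProfile` (per-region
sRNA-seq read counts) and :class:`GeneRecord` (a protein-coding gene
interval).  Coordinates are stored 1-based inclusive, exactly as GFF3 and
the locus table print them; any half-open arithmetic happens locally at the
point of use.

mature/star/hairpin sequences are normalized to uppercase RNA (T→U) at read
time; genomic FASTA stays DNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

RNA_ALPHABET = set("ACGU")
DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")


class ParseError(ValueError):
    """A named, line-addressed failure while reading an external file."""


def revcomp_dna(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(RNA_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ReadProfile:
    """Per-region sRNA-seq read counts at one miRNA locus.

    ``overlap_reads`` counts reads that straddle the mature/star region
    boundaries rather than mapping precisely to either.
    """

    total_reads: int
    mature_reads: int
    star_reads: int
    overlap_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("total_reads", "mature_reads", "star_reads", "overlap_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mature_reads + self.star_reads > self.total_reads:
            raise ValueError("mature_reads + star_reads exceeds total_reads")
        if self.overlap_reads > self.total_reads:
            raise ValueError("overlap_reads exceeds total_reads")


@dataclass(frozen=True)
class MiRNALocus:
    """One annotated miRNA locus: sequences, coordinates, read profile."""

    locus_id: str
    species: str
    mature_seq: str
    hairpin_seq: str
    chrom: str = "."
    start: int = 1
    end: int = 1
    strand: str = "+"
    star_seq: str | None = None
    read_profile: ReadProfile | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", normalize_rna(self.mature_seq))
        object.__setattr__(self, "hairpin_seq", normalize_rna(self.hairpin_seq))
        if self.star_seq is not None:
            object.__setattr__(self, "star_seq", normalize_rna(self.star_seq))
        for name, seq in (("mature_seq", self.mature_seq),
                          ("hairpin_seq", self.hairpin_seq),
                          ("star_seq", self.star_seq)):
            if seq is not None and (not seq or set(seq) - RNA_ALPHABET):
                raise ValueError(f"{name}: alphabet")
        if not 1 <= self.start <= self.end:
            raise ValueError("coordinates: need 1 <= start <= end")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")
        if self.mature_seq not in self.hairpin_seq:
            raise ValueError("mature/hairpin mismatch")
        if self.star_seq is not None:
            if self.star_seq not in self.hairpin_seq:
                raise ValueError("star/hairpin mismatch")
            m0 = self.hairpin_seq.find(self.mature_seq)
            m1 = m0 + len(self.mature_seq)
            # star must sit somewhere in the hairpin clear of the mature
            ok = any(
                s1 <= m0 or s0 >= m1
                for s0, s1 in _occurrences(self.hairpin_seq, self.star_seq)
            )
            if not ok:
                raise ValueError("star overlaps mature within hairpin")

    @property
    def mature_span_in_hairpin(self) -> tuple[int, int]:
        """0-based half-open position of the mature within the hairpin."""
        i = self.hairpin_seq.find(self.mature_seq)
        return i, i + len(self.mature_seq)


def _occurrences(haystack: str, needle: str) -> Iterable[tuple[int, int]]:
    i = haystack.find(needle)
    while i != -1:
        yield i, i + len(needle)
        i = haystack.find(needle, i + 1)


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene interval (1-based inclusive, as in GFF3)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def tss(self) -> int:
        """Transcription start site (gene-orientation aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination site (gene-orientation aware)."""
        return self.end if self.strand == "+" else self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, rna: bool = False) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; with ``rna=True`` T is normalized to U.
    Record order is preserved.  Malformed headers, empty sequences and
    duplicate ids raise :class:`ParseError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for '{header}' (line {header_line})")
        records.append((header, normalize_rna(seq) if rna else seq.upper()))
        header, chunks = None, []

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}: malformed header at line {line_no}")
                if name in seen:
                    raise ParseError(f"{path}: duplicate id '{name}' at line {line_no}")
                seen.add(name)
                header, header_line = name, line_no
            elif header is None:
                raise ParseError(f"{path}: sequence before header at line {line_no}")
            else:
                chunks.append(line)
        flush(line_no)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read GFF3 rows of one feature type as :class:`GeneRecord` objects.

    Coordinates are kept 1-based inclusive.  Rows with start > end raise a
    record-level :class:`ParseError`; a missing ID attribute gets a
    synthesized id of the form ``<type>_<line>``.
    """
    out: list[GeneRecord] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: expected 9 columns at line {line_no}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            s, e = int(start), int(end)
            if s > e:
                raise ParseError(f"{path}: start > end at line {line_no}")
            m = _ID_RE.search(attrs)
            gene_id = m.group(1) if m else f"{feature_type}_{line_no}"
            out.append(GeneRecord(gene_id, chrom, s, e, strand if strand in "+-" else "+"))
    return out


def write_gff3(path: str | Path, genes: Iterable[GeneRecord], feature_type: str = "gene",
               source: str = "specmir") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{source}\t{feature_type}\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Locus table (PmiREN-style annotation download, one row per locus)
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = [
    "locus_id", "species", "mature_seq", "star_seq", "hairpin_seq",
    "chrom", "start", "end", "strand",
    "total_reads", "mature_reads", "star_reads", "overlap_reads",
]


def read_locus_table(path: str | Path) -> tuple[list[MiRNALocus], list[dict]]:
    """Read a tab-separated miRNA annotation table.

    Returns ``(loci, rejections)``: rows violating a record invariant are
    not silently dropped — each contributes a ``{"locus_id", "row",
    "reason"}`` entry to the rejection report.  Missing/"." star sequences
    and read counts are treated as absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("locus_id", "species", "mature_seq", "hairpin_seq") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    loci: list[MiRNALocus] = []
    rejections: list[dict] = []
    for idx, row in df.iterrows():
        try:
            star = row.get("star_seq", "") or None
            if star in {".", "NA", "-"}:
                star = None
            profile = None
            if row.get("total_reads", "") not in {"", "."}:
                profile = ReadProfile(
                    total_reads=int(row["total_reads"]),
                    mature_reads=int(row.get("mature_reads", 0) or 0),
                    star_reads=int(row.get("star_reads", 0) or 0),
                    overlap_reads=int(row.get("overlap_reads", 0) or 0),
                )
            loci.append(MiRNALocus(
                locus_id=row["locus_id"],
                species=row["species"],
                mature_seq=row["mature_seq"],
                star_seq=star,
                hairpin_seq=row["hairpin_seq"],
                chrom=row.get("chrom", ".") or ".",
                start=int(row.get("start", 1) or 1),
                end=int(row.get("end", 1) or 1),
                strand=row.get("strand", "+") or "+",
                read_profile=profile,
            ))
        except (ValueError, KeyError) as exc:
            rejections.append({"locus_id": row.get("locus_id", f"row{idx}"),
                               "row": int(idx), "reason": str(exc)})
    ids = [l.locus_id for l in loci]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate locus ids {sorted(dupes)}")
    return loci, rejections


def write_locus_table(path: str | Path, loci: Sequence[MiRNALocus]) -> None:
    rows = []
    for l in loci:
        p = l.read_profile
        rows.append({
            "locus_id": l.locus_id, "species": l.species,
            "mature_seq": l.mature_seq, "star_seq": l.star_seq or ".",
            "hairpin_seq": l.hairpin_seq, "chrom": l.chrom,
            "start": l.start, "end": l.end, "strand": l.strand,
            "total_reads": p.total_reads if p else ".",
            "mature_reads": p.mature_reads if p else ".",
            "star_reads": p.star_reads if p else ".",
            "overlap_reads": p.overlap_reads if p else ".",
        })
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotation and expression tables
# ---------------------------------------------------------------------------

def read_go_table(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene<TAB>term TSV -> gene -> set of GO terms."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: expected 2 columns at line {line_no}")
            table.setdefault(parts[0], set()).add(parts[1])
    return table


def write_go_table(path: str | Path, table: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table):
            for term in sorted(table[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Tissue expression TSV: rows = miRNA/gene ids, columns = tissues."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")
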