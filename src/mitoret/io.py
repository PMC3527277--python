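"""Readers and writers for BED, bedGraph, chrom.sizes, TSS tables and reads.

All files are plain text, tab-separated.  BED input is 0-based
half-open; track/browser header lines are skipped.  Parse errors name
the offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .intervals import GenomicInterval, IntervalSet, ReadSet


class BedParseError(ValueError):
    """A malformed line in a BED-family file."""


def _is_header(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_genome(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file (chrom <TAB> length)."""
    genome: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or _is_header(line):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise BedParseError(f"{path}:{lineno}: expected 2 fields")
        try:
            genome[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return genome


def write_genome(genome: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in genome.items())
    )


def _parse_bed_line(line: str, lineno: int, path: str | Path) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: float | None = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(fields[0], start, end, name, score, strand)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path: str | Path, genome: dict[str, int] | None = None) -> IntervalSet:
    """Read BED3/BED6 into a sorted IntervalSet.

    With a genome map, unknown chromosomes raise and intervals are
    clipped to chromosome bounds.
    """
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or _is_header(line):
            continue
        intervals.append(_parse_bed_line(line, lineno, path))
    return IntervalSet(intervals, genome=genome)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in s:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_reads_bed(path: str | Path) -> ReadSet:
    """Read single-end reads from BED6: the 5' position is the start for
    + strand reads and end-1 for - strand reads."""
    reads: list[tuple[str, int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or _is_header(line):
            continue
        iv = _parse_bed_line(line, lineno, path)
        strand = iv.strand if iv.strand in ("+", "-") else "+"
        pos = iv.start if strand == "+" else iv.end - 1
        reads.append((iv.chrom, pos, strand))
    return ReadSet(reads=reads, total_mapped=len(reads))


def write_reads_bed(rs: ReadSet, path: str | Path, read_length: int = 1) -> None:
    """Write reads as BED6; the interval marks the 5' base (or
    read_length bases in the read direction)."""
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(rs.reads):
            if strand == "+":
                start, end = pos, pos + read_length
            else:
                start, end = max(0, pos - read_length + 1), pos + 1
            fh.write(f"{chrom}\t{start}\t{end}\tread{i}\t0\t{strand}\n")


def write_bedgraph(
    per_chrom_coverage: dict[str, "list[int] | object"], path: str | Path
) -> None:
    """Write per-bp coverage arrays as run-length bedGraph (zero runs
    omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(per_chrom_coverage):
            cov = per_chrom_coverage[chrom]
            n = len(cov)
            i = 0
            while i < n:
                j = i + 1
                while j < n and cov[j] == cov[i]:
                    j += 1
                if cov[i] != 0:
                    fh.write(f"{chrom}\t{i}\t{j}\t{cov[i]:g}\n")
                i = j


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read bedGraph into (chrom, start, end, value) records."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or _is_header(line):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise BedParseError(f"{path}:{lineno}: expected 4 fields")
        try:
            out.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: bad record") from exc
    return out


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    position: int
    strand: str = "."


def read_tss_table(path: str | Path) -> list[TssRecord]:
    """Read a TSS table: chrom <TAB> position <TAB> strand <TAB> gene_id
    (BED-like 4-column TSV; header line starting with '#' allowed)."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or _is_header(line):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise BedParseError(f"{path}:{lineno}: expected 4 fields")
        try:
            pos = int(fields[1])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: bad position") from exc
        records.append(TssRecord(fields[3], fields[0], pos, fields[2]))
    return records


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tposition\tstrand\tgene_id\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.gene_id}\n")
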