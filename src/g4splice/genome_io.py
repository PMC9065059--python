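"""Readers and writers for the genomic file formats the pipeline touches.

All public coordinates are 0-based half-open (BED convention). GTF input
(1-based closed) is converted at the boundary and converted back on write,
so round-trips are lossless. Chromosome-name mismatches between a genome
and an annotation are treated as errors by downstream code, never silently
reconciled; :func:`normalize_chrom_names` is the explicit opt-in fixer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
STRANDS = frozenset({"+", "-", "."})


class FormatError(ValueError):
    """Malformed input file; message carries file/line context."""


@dataclass
class GenomeSequence:
    """An in-memory genome: chromosome name -> upper-case sequence string.

    Sequences are normalised to upper case on load; any character outside
    {A, C, G, T, N} is rejected at read time.
    """

    chroms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if not seq:
                raise FormatError(f"chromosome {name!r}: empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r}: disallowed character(s) "
                    f"{sorted(bad)} (alphabet is A,C,G,T,N)"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), clipped to the chromosome."""
        seq = self.chroms[chrom]
        return seq[max(0, start):max(0, end)]


@dataclass(frozen=True)
class Interval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path_or_handle) -> GenomeSequence:
    """Load a (multi-record) FASTA into memory.

    Record names are the header up to the first whitespace; sequence is
    upper-cased. Raises :class:`FormatError` on duplicate names, empty
    records or disallowed characters.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} is empty")
        chroms[rec.id] = seq
    if not chroms:
        raise FormatError("no FASTA records found")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with _open_write(path) as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _open_write(path):
    if hasattr(path, "write"):
        return _nullcontext(path)
    return open(path, "w")


class _nullcontext:
    def __init__(self, obj):
        self.obj = obj

    def __enter__(self):
        return self.obj

    def __exit__(self, *exc):
        return False


def _lines(path_or_handle) -> Iterator[tuple[int, str]]:
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
        close = False
    else:
        handle = open(path_or_handle)
        close = True
    try:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line
    finally:
        if close:
            handle.close()


def _int(value: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what} {value!r}") from None


def read_intervals(path, format: str = "bed6",
                   columns: dict[str, int] | None = None) -> list[Interval]:
    """Read intervals from BED3/BED6/bedGraph or a declared-column TSV.

    ``format``: one of ``bed3``, ``bed6``, ``bedgraph``, ``tsv_spec``
    (``columns`` maps field names chrom/start/end[/strand/label/score]
    to 0-based column indices). Strand is "." when the format lacks one.
    Input order is preserved.
    """
    out: list[Interval] = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        try:
            if format == "bed3":
                iv = Interval(f[0], _int(f[1], lineno, "start"),
                              _int(f[2], lineno, "end"))
            elif format == "bed6":
                strand = f[5] if len(f) > 5 else "."
                score = None
                if len(f) > 4 and f[4] not in (".", ""):
                    score = float(f[4])
                iv = Interval(f[0], _int(f[1], lineno, "start"),
                              _int(f[2], lineno, "end"), strand,
                              f[3] if len(f) > 3 else "", score)
            elif format == "bedgraph":
                iv = Interval(f[0], _int(f[1], lineno, "start"),
                              _int(f[2], lineno, "end"), ".", "", float(f[3]))
            elif format == "tsv_spec":
                if columns is None:
                    raise FormatError("tsv_spec requires a column map")
                iv = Interval(
                    f[columns["chrom"]],
                    _int(f[columns["start"]], lineno, "start"),
                    _int(f[columns["end"]], lineno, "end"),
                    f[columns["strand"]] if "strand" in columns else ".",
                    f[columns["label"]] if "label" in columns else "",
                    float(f[columns["score"]]) if "score" in columns else None,
                )
            else:
                raise ValueError(f"unknown interval format {format!r}")
        except FormatError as e:
            raise FormatError(f"line {lineno}: {e}") from None
        except IndexError:
            raise FormatError(
                f"line {lineno}: too few columns for format {format}") from None
        out.append(iv)
    return out


def write_intervals(intervals: Iterable[Interval], path, format: str = "bed6") -> None:
    """Write BED3/BED6/bedGraph, tab-separated, newline-terminated, no header."""
    with _open_write(path) as fh:
        for iv in intervals:
            if format == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif format == "bed6":
                score = "0" if iv.score is None else f"{iv.score:g}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{iv.label or '.'}\t{score}\t{iv.strand}\n")
            elif format == "bedgraph":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{0.0 if iv.score is None else iv.score:g}\n")
            else:
                raise ValueError(f"unknown interval format {format!r}")


def read_variants(path) -> list[tuple[str, int, str]]:
    """Read a variant TSV: chrom, pos (0-based), class."""
    out = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 2:
            raise FormatError(f"line {lineno}: need at least chrom, pos")
        out.append((f[0], _int(f[1], lineno, "pos"), f[2] if len(f) > 2 else ""))
    return out


# --- gene models -----------------------------------------------------------

def read_gene_models(path, format: str = "bed12"):
    """Read transcript models from BED12 or GTF (exon features).

    Returns a list of :class:`g4splice.splice_annot.GeneModel` with exons
    sorted by genomic coordinate and the transcript->gene mapping retained.
    """
    from .splice_annot import GeneModel  # deferred: avoid import cycle

    models: list[GeneModel] = []
    if format == "bed12":
        for lineno, line in _lines(path):
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"line {lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], _int(f[1], lineno, "start"), _int(f[2], lineno, "end")
            name, strand = f[3], f[5]
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: unknown strand {strand!r}")
            n = _int(f[9], lineno, "blockCount")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n or len(starts) != n:
                raise FormatError(
                    f"line {lineno}: blockCount {n} does not match "
                    f"{len(sizes)} sizes / {len(starts)} starts")
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            if exons[-1][1] != end:
                raise FormatError(f"line {lineno}: blocks do not span thickEnd")
            gene = name.rsplit(".", 1)[0] if "." in name else name
            models.append(GeneModel(gene_id=gene, transcript_id=name,
                                    chrom=chrom, strand=strand, exons=exons))
    elif format == "gtf":
        by_tx: dict[str, dict] = {}
        order: list[str] = []
        for lineno, line in _lines(path):
            f = line.split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = _parse_gtf_attrs(f[8])
            tx = attrs.get("transcript_id")
            if tx is None:
                raise FormatError(f"line {lineno}: exon without transcript_id")
            if f[6] not in ("+", "-"):
                raise FormatError(f"line {lineno}: unknown strand {f[6]!r}")
            # GTF is 1-based closed; convert to 0-based half-open
            exon = (_int(f[3], lineno, "start") - 1, _int(f[4], lineno, "end"))
            rec = by_tx.setdefault(tx, {
                "chrom": f[0], "strand": f[6],
                "gene": attrs.get("gene_id", tx), "exons": []})
            if tx not in order:
                order.append(tx)
            rec["exons"].append(exon)
        for tx in order:
            rec = by_tx[tx]
            models.append(GeneModel(gene_id=rec["gene"], transcript_id=tx,
                                    chrom=rec["chrom"], strand=rec["strand"],
                                    exons=sorted(rec["exons"])))
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return models


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def write_gene_models_bed12(models, path) -> None:
    with _open_write(path) as fh:
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - start) for s, _ in m.exons) + ","
            fh.write(f"{m.chrom}\t{start}\t{end}\t{m.transcript_id}\t0\t"
                     f"{m.strand}\t{start}\t{end}\t0\t{len(m.exons)}\t"
                     f"{sizes}\t{starts}\n")


def normalize_chrom_names(names: Iterable[str], style: str) -> dict[str, str]:
    """Explicit "chr" prefix normaliser. style: "add_chr" or "strip_chr"."""
    out = {}
    for n in names:
        if style == "add_chr":
            out[n] = n if n.startswith("chr") else "chr" + n
        elif style == "strip_chr":
            out[n] = n[3:] if n.startswith("chr") else n
        else:
            raise ValueError(f"unknown style {style!r}")
    return out
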