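"""Splice-site anchors, strand context and exon/intron descriptors.

Junction coordinates follow the 0-based half-open convention of the rest
of the package: an acceptor (3'ss) junction is the coordinate of the
first exonic base in transcription order, a donor (5'ss) junction the
coordinate just past the last exonic base. On the minus strand the two
are mirrored genomically (acceptor at the exon's right edge).

"Template" / "non-template" strand context: a motif lies on the
non-template (coding, mRNA-like) strand when its strand equals the
gene's transcription strand; such G4s appear in the transcript as RNA
G4s. Motifs on the opposite (template) strand do not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .genome_io import GenomeSequence, Interval, reverse_complement

ACCEPTOR = "acceptor_3ss"
DONOR = "donor_5ss"

MICROEXON_MAX = 30  # exons shorter than this (nt) are microexons


@dataclass(frozen=True)
class GeneModel:
    """One transcript: sorted, non-overlapping exons on one strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __init__(self, gene_id, transcript_id, chrom, strand, exons):
        exons = tuple(tuple(e) for e in exons)
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(self, "transcript_id", transcript_id)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "strand", strand)
        object.__setattr__(self, "exons", exons)
        if strand not in ("+", "-"):
            raise ValueError(f"{transcript_id}: unknown strand {strand!r}")
        if not exons:
            raise ValueError(f"{transcript_id}: no exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{transcript_id}: overlapping/unsorted exon blocks")
            if s2 == e1:
                raise ValueError(f"{transcript_id}: zero-length intron")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class SpliceSite:
    """An oriented exon/intron junction anchor."""

    site_id: str
    kind: str  # ACCEPTOR | DONOR
    chrom: str
    junction: int
    strand: str  # gene transcription strand
    exon_id: str = ""
    exon_length: int = 0
    intron_id: str = ""
    intron_length: int = 0  # intron on the site's intronic side
    canonical: bool | None = None
    exon_position_group: str | None = None
    is_microexon: bool = False

    def window(self, flank: int) -> tuple[int, int]:
        """Genomic window [junction - flank, junction + flank)."""
        return self.junction - flank, self.junction + flank

    def signed_offset(self, pos: int) -> int:
        """Offset of genomic base ``pos`` in transcription orientation.

        Offset 0 is the first base genomically at/after the junction for
        plus-strand genes and just before it for minus-strand genes, so
        negative offsets are always transcription-upstream of the junction.
        """
        if self.strand == "+":
            return pos - self.junction
        return self.junction - 1 - pos


def _is_canonical(genome: GenomeSequence, chrom: str, strand: str,
                  intron: tuple[int, int]) -> bool:
    a, b = intron
    if strand == "+":
        return genome.fetch(chrom, a, a + 2) == "GT" and \
            genome.fetch(chrom, b - 2, b) == "AG"
    return reverse_complement(genome.fetch(chrom, b - 2, b)) == "GT" and \
        reverse_complement(genome.fetch(chrom, a, a + 2)) == "AG"


def _site_id(chrom: str, junction: int, kind: str, strand: str) -> str:
    tag = "a" if kind == ACCEPTOR else "d"
    return f"{chrom}:{junction}:{tag}:{strand}"


def _sites_for_exon(model: GeneModel, i: int,
                    genome: GenomeSequence | None) -> list[SpliceSite]:
    """Acceptor and donor of exon index ``i`` (genomic order)."""
    s, e = model.exons[i]
    exon_len = e - s
    introns = model.introns
    out = []
    if model.strand == "+":
        specs = [(ACCEPTOR, s, i - 1), (DONOR, e, i)]
    else:  # transcription right-to-left
        specs = [(ACCEPTOR, e, i), (DONOR, s, i - 1)]
    for kind, junction, intron_idx in specs:
        if not 0 <= intron_idx < len(introns):
            continue
        intron = introns[intron_idx]
        canonical = None
        if genome is not None:
            canonical = _is_canonical(genome, model.chrom, model.strand, intron)
        out.append(SpliceSite(
            site_id=_site_id(model.chrom, junction, kind, model.strand),
            kind=kind, chrom=model.chrom, junction=junction,
            strand=model.strand,
            exon_id=f"{model.transcript_id}:exon{i + 1}",
            exon_length=exon_len,
            intron_id=f"{model.transcript_id}:intron{intron_idx + 1}",
            intron_length=intron[1] - intron[0],
            canonical=canonical,
            is_microexon=exon_len < MICROEXON_MAX))
    return out


def extract_internal_splice_sites(
        models: Sequence[GeneModel],
        genome: GenomeSequence | None = None,
        keep_noncanonical: bool = False,
        collapse_duplicates: bool = True) -> list[SpliceSite]:
    """Acceptor + donor of every internal exon of every transcript.

    Transcripts with fewer than three exons have no internal exon and
    contribute nothing. With a genome attached, sites whose intronic-side
    intron is not GT..AG on the gene strand are dropped unless
    ``keep_noncanonical`` (then retained with ``canonical=False``).
    Duplicate junctions shared by transcripts are collapsed to one site
    (keyed by chrom, junction, kind, strand) unless ``collapse_duplicates``
    is False.
    """
    sites: list[SpliceSite] = []
    for m in models:
        if m.n_exons < 3:
            continue
        for i in range(1, m.n_exons - 1):
            sites.extend(_sites_for_exon(m, i, genome))
    if genome is not None and not keep_noncanonical:
        sites = [s for s in sites if s.canonical]
    if collapse_duplicates:
        seen: dict[tuple, SpliceSite] = {}
        for s in sites:
            seen.setdefault((s.chrom, s.junction, s.kind, s.strand), s)
        sites = list(seen.values())
    return sites


def classify_strand_context(hit, site: SpliceSite) -> str:
    """"non_template" iff the motif strand equals the gene strand."""
    if hit.chrom != site.chrom:
        raise ValueError(
            f"chromosome mismatch: hit on {hit.chrom}, site on {site.chrom}")
    return "non_template" if hit.strand == site.strand else "template"


def _longest_transcript(models: Iterable[GeneModel]) -> GeneModel:
    # largest summed exon length; ties broken by transcript id
    return sorted(models, key=lambda m: (-m.exonic_length, m.transcript_id))[0]


def assign_exon_position_groups(
        models: Sequence[GeneModel],
        genome: GenomeSequence | None = None) -> list[SpliceSite]:
    """Per-gene exon position groups over the longest transcript.

    Only genes whose longest transcript has nine or more exons are
    labelled: exons 1-4 in transcription order get first1..first4, the
    last four get last4..last1 (last1 = final exon) and the remainder
    are "middle". Genes below nine exons yield sites with group None.
    Terminal junctions (first exon's donor, last exon's acceptor) are
    included here, unlike the default internal-site set.
    """
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    out: list[SpliceSite] = []
    for gene in sorted(by_gene):
        m = _longest_transcript(by_gene[gene])
        n = m.n_exons
        for i in range(n):  # genomic order
            t = i if m.strand == "+" else n - 1 - i  # transcription order, 0-based
            group = None
            if n >= 9:
                if t < 4:
                    group = f"first{t + 1}"
                elif t >= n - 4:
                    group = f"last{n - t}"
                else:
                    group = "middle"
            for site in _sites_for_exon(m, i, genome):
                out.append(replace(site, exon_position_group=group))
    return out


def site_window(site: SpliceSite, flank: int,
                chrom_length: int | None = None) -> tuple[Interval, Interval]:
    """(intronic-side, exonic-side) flank intervals around the junction.

    Windows are clipped at chromosome ends only; they may run into
    neighbouring features. Offsets within them are signed in
    transcription orientation via :meth:`SpliceSite.signed_offset`.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    j = site.junction
    lo = max(0, j - flank)
    hi = j + flank if chrom_length is None else min(chrom_length, j + flank)
    left = Interval(site.chrom, lo, j, site.strand) if j > lo else None
    right = Interval(site.chrom, j, hi, site.strand) if hi > j else None
    # which side is intronic depends on kind and strand
    intronic_is_left = (site.kind == ACCEPTOR) == (site.strand == "+")
    if intronic_is_left:
        return left, right
    return right, left


def write_sites_bed(sites: Iterable[SpliceSite], path) -> None:
    """BED6+ export: extra columns kind, intron length, exon length,
    canonical, exon position group."""
    from .genome_io import _open_write
    with _open_write(path) as fh:
        for s in sites:
            fh.write("\t".join([
                s.chrom, str(s.junction), str(s.junction + 1), s.site_id,
                "0", s.strand, s.kind, str(s.intron_length),
                str(s.exon_length), str(s.canonical),
                s.exon_position_group or "none"]) + "\n")
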