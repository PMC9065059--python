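"""Splice-site strength scoring from positional frequency matrices.

A site's strength is the log-odds of its junction window under a
positional frequency matrix (PFM) versus a uniform background:

    score = sum_i log2( (f(b_i, i) + eps) / 0.25 )       [bits]

Matrix windows default to the classic donor 9-mer (3 exonic + 6
intronic) and acceptor 23-mer (20 intronic + 3 exonic); the width and
the junction offset are read from the matrix file itself. Scored sites
are stratified into quantile bins (quartiles by default, deciles for
heatmaps), bin 1 = weakest.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome_io import GenomeSequence, reverse_complement
from .splice_annot import ACCEPTOR, DONOR, SpliceSite

logger = logging.getLogger(__name__)

BASES = "ACGT"
DEFAULT_PSEUDOCOUNT = 1e-3

#: (exonic, intronic) window halves in transcription order, by site kind
DEFAULT_WINDOWS = {DONOR: (3, 6), ACCEPTOR: (20, 3)}


@dataclass
class PositionalFrequencyMatrix:
    """Per-position base frequencies for one splice-site kind.

    ``freqs`` has shape (width, 4), columns ordered A, C, G, T; each row
    sums to 1. ``junction_offset`` is the row index of the first
    intronic base for donors / first exonic base for acceptors, i.e. of
    the base at transcription offset 0 from the junction.
    """

    kind: str
    freqs: np.ndarray
    junction_offset: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("PFM must be positions x 4 (A,C,G,T)")
        if (self.freqs < 0).any():
            raise ValueError("PFM frequencies must be >= 0")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PFM column must sum to 1 (+/- 1e-6)")
        if not 0 <= self.junction_offset <= len(self.freqs):
            raise ValueError("junction_offset outside matrix")

    @property
    def width(self) -> int:
        return len(self.freqs)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


def read_pfm(path, kind: str) -> PositionalFrequencyMatrix:
    """Read a PFM TSV: header row A C G T, one row per position, plus a
    metadata line ``#junction_offset=K``."""
    offset = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key == "junction_offset":
                offset = int(val)
            continue
        body.append(line)
    if offset is None:
        raise ValueError(f"{path}: missing '#junction_offset=K' line")
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    freqs = df[list(BASES)].to_numpy(float)
    return PositionalFrequencyMatrix(kind, freqs, offset)


def write_pfm(pfm: PositionalFrequencyMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#junction_offset={pfm.junction_offset}\n")
        fh.write("\t".join(BASES) + "\n")
        for row in pfm.freqs:
            fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def score_window(window: str, pfm: PositionalFrequencyMatrix,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Log2-odds score of one window (gene-strand sequence, matrix-aligned).

    Returns NaN for windows containing N or of the wrong width.
    """
    if len(window) != pfm.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {pfm.width}")
    score = 0.0
    for i, b in enumerate(window):
        j = BASES.find(b)
        if j < 0:
            return float("nan")
        score += np.log2((pfm.freqs[i, j] + pseudocount) / 0.25)
    return float(score)


def site_pfm_window(site: SpliceSite, genome: GenomeSequence,
                    pfm: PositionalFrequencyMatrix) -> str:
    """Gene-strand sequence aligned to the matrix for one site.

    The matrix row at ``junction_offset`` corresponds to the base at
    transcription offset 0 from the junction.
    """
    j = site.junction
    k = pfm.junction_offset
    w = pfm.width
    if site.strand == "+":
        seq = genome.fetch(site.chrom, j - k, j - k + w)
    else:
        seq = reverse_complement(genome.fetch(site.chrom, j + k - w, j + k))
    return seq


@dataclass(frozen=True)
class SpliceStrengthScore:
    site_id: str
    score: float  # bits
    quantile_bin: int = 0  # 1 = weakest


def score_sites(sites, genome: GenomeSequence,
                pfms: dict[str, PositionalFrequencyMatrix],
                pseudocount: float = DEFAULT_PSEUDOCOUNT
                ) -> list[SpliceStrengthScore]:
    """Score every site against the matrix of its kind; sites whose
    window is incomplete or contains N are dropped with a warning."""
    out = []
    n_dropped = 0
    for s in sites:
        pfm = pfms[s.kind]
        window = site_pfm_window(s, genome, pfm)
        if len(window) != pfm.width:
            n_dropped += 1
            continue
        score = score_window(window, pfm, pseudocount)
        if np.isnan(score):
            n_dropped += 1
            continue
        out.append(SpliceStrengthScore(s.site_id, score))
    if n_dropped:
        logger.warning("dropped %d site(s) with undefined strength score",
                       n_dropped)
    return out


def assign_quantiles(scores: list[SpliceStrengthScore],
                     n_bins: int = 4) -> list[SpliceStrengthScore]:
    """Stratify scores into near-equal quantile bins (1 = weakest).

    Rank-based: tied scores share the lower bin; with all-distinct
    scores the bin sizes differ by at most one. Affine transformations
    of the scores leave the binning unchanged.
    """
    if len(scores) < n_bins:
        raise ValueError(
            f"need at least {n_bins} scored sites, got {len(scores)}")
    vals = np.array([s.score for s in scores])
    ranks = rankdata(vals, method="min")  # ties -> lower bin
    bins = ((ranks - 1) * n_bins // len(vals)).astype(int) + 1
    if np.all(vals == vals[0]):
        warnings.warn("all strength scores equal; every site in bin 1")
    return [SpliceStrengthScore(s.site_id, s.score, int(b))
            for s, b in zip(scores, bins)]


def uniform_pfm(kind: str, width: int, junction_offset: int
                ) -> PositionalFrequencyMatrix:
    return PositionalFrequencyMatrix(
        kind, np.full((width, 4), 0.25), junction_offset)


def consensus_pfm(kind: str, consensus: str, junction_offset: int,
                  strength: float = 0.91) -> PositionalFrequencyMatrix:
    """A synthetic PFM concentrated on a consensus sequence.

    Each position puts ``strength`` on the consensus base and splits the
    remainder over the other three. Used for fixtures and the synthetic
    annotation generator; not derived from any measured matrix.
    """
    rows = []
    rest = (1.0 - strength) / 3.0
    for b in consensus.upper():
        row = [rest] * 4
        row[BASES.index(b)] = strength
        rows.append(row)
    return PositionalFrequencyMatrix(kind, np.array(rows), junction_offset)
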