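"""Association statistics linking G4 presence to splicing outcomes.

A splicing node (one quantified alternative-splicing event, Whippet-style)
is called differentially included when |dPSI| >= 0.1 and the posterior
probability >= 0.9 (both thresholds inclusive, recorded on the node). A
node is G4-associated when either of its boundaries lies within 100 bp of
a G4 motif midpoint or 45 bp of a G4-seq peak midpoint. The association
between the two labels is a 2x2 contingency per node type and direction:
odds ratio (Haldane 0.5 correction when a cell is empty), Yates-corrected
chi-squared, Bonferroni adjustment over the strata tested in one run.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeSequence, Interval
from .splice_annot import SpliceSite, site_window

logger = logging.getLogger(__name__)

NODE_TYPES = ("CE", "AA", "AD", "RI", "TS", "TE", "other")

DEFAULT_DPSI = 0.1
DEFAULT_PROB = 0.9
MOTIF_ASSOC_DIST = 100  # bp, node boundary to G4 motif midpoint
PEAK_ASSOC_DIST = 45  # bp, node boundary to G4-seq peak midpoint


@dataclass(frozen=True)
class SplicingNode:
    node_id: str
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    node_type: str
    delta_psi: float
    probability: float
    differential: bool = False
    direction: str = "none"  # included | excluded | none
    g4_associated: bool = False
    dpsi_threshold: float = DEFAULT_DPSI
    prob_threshold: float = DEFAULT_PROB


@dataclass
class AssociationResult:
    """2x2 contingency: G4 presence x differential inclusion."""

    a: int  # G4+, differential
    b: int  # G4+, non-differential
    c: int  # G4-, differential
    d: int  # G4-, non-differential
    odds_ratio: float = float("nan")
    log_or: float = float("nan")
    log_or_se: float = float("nan")
    chi2: float = float("nan")
    p: float = float("nan")
    p_adj: float = float("nan")
    m: int = 1  # family size for Bonferroni
    haldane: bool = False
    testable: bool = True
    stratum: str = ""

    def log_or_ci(self, z: float = 1.959964) -> tuple[float, float]:
        return (self.log_or - z * self.log_or_se,
                self.log_or + z * self.log_or_se)


def classify_nodes(psi_table: pd.DataFrame,
                   dpsi_threshold: float = DEFAULT_DPSI,
                   prob_threshold: float = DEFAULT_PROB) -> list[SplicingNode]:
    """Build splicing nodes from a PSI table.

    Expected columns: gene, node, chrom, start, end, strand, type,
    delta_psi, probability. Thresholds are applied inclusively (>=).
    """
    cols = psi_table.columns
    get = lambda name, default: (psi_table[name] if name in cols
                                 else pd.Series([default] * len(psi_table)))
    dpsi_arr = psi_table["delta_psi"].to_numpy(float)
    prob_arr = psi_table["probability"].to_numpy(float)
    bad = np.flatnonzero((dpsi_arr < -1) | (dpsi_arr > 1))
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"row {i} (node {psi_table.iloc[i].get('node', '?')}): "
            f"delta_psi {dpsi_arr[i]} outside [-1, 1]")
    bad = np.flatnonzero((prob_arr < 0) | (prob_arr > 1))
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"row {i} (node {psi_table.iloc[i].get('node', '?')}): "
            f"probability {prob_arr[i]} outside [0, 1]")
    nodes = []
    rows = zip(psi_table["node"], get("gene", ""), psi_table["chrom"],
               psi_table["start"], psi_table["end"], get("strand", "."),
               get("type", "other"), dpsi_arr, prob_arr)
    for node, gene, chrom, start, end, strand, ntype, dpsi, prob in rows:
        differential = bool(abs(dpsi) >= dpsi_threshold
                            and prob >= prob_threshold)
        direction = "none"
        if differential:
            direction = "included" if dpsi > 0 else "excluded"
        nodes.append(SplicingNode(
            node_id=str(node), gene=str(gene), chrom=str(chrom),
            start=int(start), end=int(end), strand=str(strand),
            node_type=str(ntype), delta_psi=float(dpsi),
            probability=float(prob), differential=differential,
            direction=direction, dpsi_threshold=dpsi_threshold,
            prob_threshold=prob_threshold))
    return nodes


def label_g4_association(nodes: list[SplicingNode], motif_hits,
                         peak_hits=(), motif_dist: int = MOTIF_ASSOC_DIST,
                         peak_dist: int = PEAK_ASSOC_DIST,
                         orientation: str | None = None
                         ) -> list[SplicingNode]:
    """Set ``g4_associated`` on each node.

    A node is associated when the nearer of its two boundaries is within
    ``motif_dist`` of a motif midpoint or ``peak_dist`` of a peak
    midpoint. ``orientation`` restricts motifs/peaks to those on the
    node's own strand ("non_template") or the opposite one ("template").
    """
    if orientation not in (None, "non_template", "template"):
        raise ValueError(f"invalid orientation {orientation!r}")

    def mids(hits, node_strand):
        sel = []
        for h in hits:
            hs = getattr(h, "strand", ".")
            if orientation == "non_template" and hs != node_strand:
                continue
            if orientation == "template" and hs == node_strand:
                continue
            sel.append((h.chrom, (h.start + h.end) / 2.0))
        return sel

    out = []
    for node in nodes:
        associated = False
        for hits, dist in ((motif_hits, motif_dist), (peak_hits, peak_dist)):
            for chrom, mid in mids(hits, node.strand):
                if chrom != node.chrom:
                    continue
                if min(abs(mid - node.start), abs(mid - node.end)) <= dist:
                    associated = True
                    break
            if associated:
                break
        out.append(replace(node, g4_associated=associated))
    return out


def association_from_counts(a: int, b: int, c: int, d: int, m: int = 1,
                            stratum: str = "") -> AssociationResult:
    """Odds ratio + Yates chi-squared for one 2x2 table.

    Haldane correction (add 0.5 to every cell) is applied to the odds
    ratio iff any cell is zero, and flagged. The chi-squared test is
    only run when both margins are non-empty.
    """
    res = AssociationResult(a, b, c, d, m=m, stratum=stratum)
    haldane = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if haldane
                      else (a, b, c, d))
    aa, bb, cc, dd = float(aa), float(bb), float(cc), float(dd)
    res.haldane = haldane
    res.odds_ratio = (aa * dd) / (bb * cc)
    # CI uses Gart's adjusted logit (0.5 added to every cell always):
    # the plain Woolf interval is slightly anticonservative at moderate
    # cell counts, the adjusted one holds its nominal coverage
    ga, gb, gc, gd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    res.log_or = math.log((ga * gd) / (gb * gc))
    res.log_or_se = math.sqrt(1 / ga + 1 / gb + 1 / gc + 1 / gd)
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        res.testable = False
        return res
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    res.chi2 = float(chi2)
    res.p = float(p)
    res.p_adj = min(1.0, m * res.p)
    return res


def association_test(nodes: list[SplicingNode],
                     strata: str = "type_direction",
                     family_size: int | None = None
                     ) -> dict[str, AssociationResult]:
    """G4 x differential-inclusion association per stratum.

    ``strata="type_direction"`` tests one 2x2 per (node type, direction)
    with controls = non-differential nodes of the same type;
    ``strata="overall"`` tests differential-vs-not over all nodes. The
    Bonferroni family size m defaults to the number of testable strata.
    """
    groups: dict[str, tuple[list, list]] = {}
    if strata == "overall":
        cases = [n for n in nodes if n.differential]
        ctrls = [n for n in nodes if not n.differential]
        groups["overall"] = (cases, ctrls)
    elif strata == "type_direction":
        for t in sorted({n.node_type for n in nodes}):
            of_type = [n for n in nodes if n.node_type == t]
            ctrls = [n for n in of_type if not n.differential]
            for d in ("included", "excluded"):
                cases = [n for n in of_type if n.direction == d]
                if cases:
                    groups[f"{t}:{d}"] = (cases, ctrls)
    else:
        raise ValueError(f"unknown strata {strata!r}")
    m = family_size if family_size is not None else max(1, len(groups))
    out = {}
    for name, (cases, ctrls) in groups.items():
        a = sum(n.g4_associated for n in cases)
        c = len(cases) - a
        b = sum(n.g4_associated for n in ctrls)
        d = len(ctrls) - b
        out[name] = association_from_counts(a, b, c, d, m=m, stratum=name)
        if not out[name].testable:
            logger.warning("stratum %s untestable (empty margin)", name)
    return out


# --- GC-matched length controls -------------------------------------------

def gc_content(genome: GenomeSequence, iv: Interval) -> float:
    seq = genome.fetch(iv.chrom, iv.start, iv.end)
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def gc_matched_controls(short_introns: list[Interval],
                        long_introns: list[Interval],
                        genome: GenomeSequence,
                        tol: float = 0.01, seed: int | None = None,
                        min_pairs: int = 10
                        ) -> list[tuple[Interval, Interval, float]]:
    """Greedy GC matching of short (<500 nt) to long (>500 nt) introns.

    Short introns are processed in seeded random order; each takes the
    available long intron with nearest GC, without replacement. Pairs
    with |dGC| > tol are discarded. Fails below ``min_pairs`` matches.
    """
    rng = np.random.default_rng(seed)
    shorts = list(short_introns)
    rng.shuffle(shorts)
    pool = sorted((gc_content(genome, iv), i)
                  for i, iv in enumerate(long_introns))
    gcs = [p[0] for p in pool]
    idxs = [p[1] for p in pool]
    pairs = []
    for s in shorts:
        if not gcs:
            break
        g = gc_content(genome, s)
        i = bisect_left(gcs, g)
        cands = [k for k in (i - 1, i) if 0 <= k < len(gcs)]
        k = min(cands, key=lambda k: abs(gcs[k] - g))
        if abs(gcs[k] - g) <= tol:
            pairs.append((s, long_introns[idxs[k]], abs(gcs[k] - g)))
            del gcs[k], idxs[k]
    if len(pairs) < min_pairs:
        raise ValueError(
            f"only {len(pairs)} GC-matched pairs (need >= {min_pairs})")
    return pairs


# --- length comparisons ----------------------------------------------------

def length_comparisons(sites: list[SpliceSite], motif_hits,
                       flank: int = 100) -> pd.DataFrame:
    """Intron/exon length by G4 presence in the intronic flank window.

    A site carries a G4 when a motif midpoint lies in its intronic-side
    ``flank`` window; sub-split by strand context (non-template = motif
    strand equals gene strand). Returns one row per (site kind, group)
    with n, median lengths, and Mann-Whitney U / KS p-values of the
    group's intron lengths against the no-G4 group of the same kind.
    """
    mids: dict[str, list[tuple[float, str]]] = {}
    for h in motif_hits:
        mids.setdefault(h.chrom, []).append(((h.start + h.end) / 2.0, h.strand))
    for v in mids.values():
        v.sort()

    site_flags = []  # (site, has_any, has_nt, has_t)
    for s in sites:
        intronic, _ = site_window(s, flank)
        has_nt = has_t = False
        if intronic is not None:
            for mid, strand in mids.get(s.chrom, ()):
                if intronic.start <= mid < intronic.end:
                    if strand == s.strand:
                        has_nt = True
                    else:
                        has_t = True
        site_flags.append((s, has_nt or has_t, has_nt, has_t))

    rows = []
    for kind in sorted({s.kind for s in sites}):
        of_kind = [f for f in site_flags if f[0].kind == kind]
        without = [f[0] for f in of_kind if not f[1]]
        groups = {
            "no_g4": without,
            "g4_any": [f[0] for f in of_kind if f[1]],
            "g4_non_template": [f[0] for f in of_kind if f[2]],
            "g4_template": [f[0] for f in of_kind if f[3]],
        }
        ref = [s.intron_length for s in without]
        for name, members in groups.items():
            if not members:
                continue
            ilens = [s.intron_length for s in members]
            elens = [s.exon_length for s in members]
            mwu_p = ks_p = float("nan")
            if name != "no_g4" and ref and ilens:
                mwu_p = float(stats.mannwhitneyu(
                    ilens, ref, alternative="two-sided").pvalue)
                ks_p = float(stats.ks_2samp(ilens, ref).pvalue)
            rows.append({
                "kind": kind, "group": name, "n": len(members),
                "median_intron_length": float(np.median(ilens)),
                "median_exon_length": float(np.median(elens)),
                "mwu_p_vs_no_g4": mwu_p, "ks_p_vs_no_g4": ks_p})
    return pd.DataFrame(rows)


# --- sQTL adjusted enrichment ----------------------------------------------

@dataclass
class BinTrack:
    """Uniform bins over [-L, +L) relative to the junction."""

    edges: np.ndarray  # length n_bins + 1
    sqtl_count: np.ndarray
    snp_count: np.ndarray
    g4_bp: np.ndarray
    e_sqtl: np.ndarray
    e_snp: np.ndarray
    adjusted: np.ndarray  # e_sqtl / e_snp; NaN where undefined

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.edges[:-1], "bin_end": self.edges[1:],
            "sqtl_count": self.sqtl_count, "snp_count": self.snp_count,
            "g4_bp": self.g4_bp, "e_sqtl": self.e_sqtl,
            "e_snp": self.e_snp, "adjusted": self.adjusted})


def sqtl_adjusted_enrichment(g4_hits, sqtls, snps, sites: list[SpliceSite],
                             L: int = 500, w: int = 25) -> BinTrack:
    """SNP-adjusted sQTL enrichment inside G4s, binned around junctions.

    Per bin: in-G4 variant density = variants of the class falling
    inside G4 base pairs in that bin over the G4 base pairs in that bin;
    the enrichment e is that density relative to the class's mean
    per-bp density over the whole +/-L track (all variants of the
    class, G4 or not), and the adjusted enrichment is e_sqtl / e_snp.
    Variants and G4 bp are accumulated per site, in transcription
    orientation, so a variant near two junctions contributes to both.
    Bins with no G4 bp or zero SNP enrichment report NaN (logged).
    Doubling both variant sets everywhere leaves the track unchanged.
    """
    if (2 * L) % w != 0:
        raise ValueError("window [-L, L) must divide evenly into bins")
    n_bins = (2 * L) // w
    edges = np.arange(-L, L + 1, w)

    # binary G4 coverage per chromosome
    sizes: dict[str, int] = {}
    for s in sites:
        sizes[s.chrom] = max(sizes.get(s.chrom, 0), s.junction + L + 1)
    for h in g4_hits:
        sizes[h.chrom] = max(sizes.get(h.chrom, 0), h.end + 1)
    cov = {c: np.zeros(n + 1, dtype=np.int32) for c, n in sizes.items()}
    for h in g4_hits:
        cov[h.chrom][h.start] += 1
        cov[h.chrom][h.end] -= 1
    cov = {c: (np.cumsum(a[:-1]) > 0) for c, a in cov.items()}

    def positions(variants):
        by: dict[str, np.ndarray] = {}
        tmp: dict[str, list[int]] = {}
        for v in variants:
            chrom, pos = (v.chrom, v.start) if hasattr(v, "chrom") else v[:2]
            tmp.setdefault(chrom, []).append(pos)
        for c, ps in tmp.items():
            by[c] = np.sort(np.array(ps))
        return by

    sq_pos = positions(sqtls)
    sn_pos = positions(snps)
    sqtl_in_g4 = np.zeros(n_bins)
    snp_in_g4 = np.zeros(n_bins)
    sqtl_total = 0  # all class variants in the track, G4 or not
    snp_total = 0
    g4_bp = np.zeros(n_bins)
    track_bp = 0
    for s in sites:
        c = cov.get(s.chrom)
        if c is None:
            continue
        j = s.junction
        lo, hi = max(0, j - L), min(len(c), j + L)
        if lo >= hi:
            continue
        track_bp += hi - lo
        window = np.zeros(2 * L, dtype=bool)
        window[lo - (j - L):hi - (j - L)] = c[lo:hi]
        if s.strand == "-":
            window = window[::-1]
        g4_bp += window.reshape(n_bins, w).sum(axis=1)
        for pos_by, counter, which in ((sq_pos, sqtl_in_g4, "sq"),
                                       (sn_pos, snp_in_g4, "sn")):
            ps = pos_by.get(s.chrom)
            if ps is None:
                continue
            i0 = np.searchsorted(ps, j - L, side="left")
            i1 = np.searchsorted(ps, j + L, side="left")
            if which == "sq":
                sqtl_total += i1 - i0
            else:
                snp_total += i1 - i0
            for p in ps[i0:i1]:
                if not c[p]:
                    continue
                off = s.signed_offset(int(p))
                if -L <= off < L:
                    counter[(off + L) // w] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        d_sq = np.where(g4_bp > 0, sqtl_in_g4 / np.maximum(g4_bp, 1), np.nan)
        d_sn = np.where(g4_bp > 0, snp_in_g4 / np.maximum(g4_bp, 1), np.nan)
        mean_sq = sqtl_total / track_bp if track_bp else np.nan
        mean_sn = snp_total / track_bp if track_bp else np.nan
        e_sqtl = d_sq / mean_sq
        e_snp = d_sn / mean_sn
        adjusted = np.where(e_snp > 0, e_sqtl / e_snp, np.nan)
    if np.isnan(adjusted).any():
        logger.warning("%d bin(s) with undefined adjusted enrichment",
                       int(np.isnan(adjusted).sum()))
    return BinTrack(edges=edges, sqtl_count=sqtl_in_g4, snp_count=snp_in_g4,
                    g4_bp=g4_bp, e_sqtl=e_sqtl, e_snp=e_snp,
                    adjusted=adjusted)
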