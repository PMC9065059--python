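"""Seeded synthetic-data generators with machine-readable planted truth.

Every input class the pipeline consumes can be generated here with known
structure: a first-order Markov genome, multi-exon gene models with
GT-AG introns and PFM-shaped splice sites, consensus G4 motifs planted
near junctions at controlled rate/offset/strand bias, peak and variant
tracks with planted enrichment inside G4s, PSI tables with a planted
odds ratio, and per-factor binding with group-dependent occupancy.
Planting overwrites background sequence (never inserts), so coordinates
stay stable and the truth records can be compared against scanner and
statistics output directly.

Defaults are the desk-scale bundle: a 5 Mb genome (5 chromosomes),
300 genes, ~1500 internal junctions, G4 planting rate 0.3 at mean
offset 50 nt into the intron with a 2:1 non-template:template bias,
planted odds ratio 2 between G4 presence and differential exclusion,
and 89% of differential cassette nodes skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, Interval, reverse_complement
from .motif_scan import MotifHit
from .splice_annot import (ACCEPTOR, DONOR, GeneModel, SpliceSite,
                           extract_internal_splice_sites)
from .splice_strength import PositionalFrequencyMatrix, consensus_pfm

BASES = "ACGT"

#: synthetic splice-site consensus windows (documented fixtures, not
#: measured matrices): donor 9-mer = 3 exonic + 6 intronic, acceptor
#: 23-mer = 20 intronic (polypyrimidine tract + CAG) + 3 exonic.
DONOR_CONSENSUS = "CAGGTAAGT"
DONOR_JUNCTION_OFFSET = 3
ACCEPTOR_CONSENSUS = "T" * 17 + "CAG" + "GTC"
ACCEPTOR_JUNCTION_OFFSET = 20


def default_donor_pfm(strength: float = 0.91) -> PositionalFrequencyMatrix:
    return consensus_pfm(DONOR, DONOR_CONSENSUS, DONOR_JUNCTION_OFFSET,
                         strength)


def default_acceptor_pfm(strength: float = 0.91) -> PositionalFrequencyMatrix:
    return consensus_pfm(ACCEPTOR, ACCEPTOR_CONSENSUS,
                         ACCEPTOR_JUNCTION_OFFSET, strength)


@dataclass
class SynthConfig:
    """Knobs of the synthetic bundle; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 5
    chrom_length: int = 1_000_000
    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.full((4, 4), 0.25))
    # genes
    n_genes: int = 300
    exon_count_range: tuple[int, int] = (4, 8)  # inclusive
    exon_length_logn: tuple[float, float] = (math.log(140), 0.35)
    intron_length_logn: tuple[float, float] = (math.log(1000), 0.8)
    min_exon: int = 25
    min_intron: int = 80
    weak_site_fraction: float = 0.25  # sites drawn from uniform background
    pfm_strength: float = 0.91
    # G4 planting
    plant_rate: float = 0.3  # per splice site
    plant_rate_long_intron: float | None = None  # length-coupled if set
    long_intron_threshold: int = 500
    offset_mean: float = 50.0  # nt from junction into the intron
    offset_sd: float = 15.0
    nt_template_ratio: float = 2.0  # non-template : template
    run_length_range: tuple[int, int] = (3, 5)
    loop_length_range: tuple[int, int] = (1, 7)
    n_runs: int = 4
    # peaks
    peak_overlap_prob: float = 0.8
    peak_jitter: int = 20
    # variants
    snp_rate: float = 0.002  # background per bp, in +/-500 windows
    sqtl_uplift: float = 2.0  # inside G4 bp within +/- uplift_range
    uplift_range: int = 100
    # psi
    psi_base_rate: float = 0.15  # P(differential | no G4)
    planted_or: float = 2.0
    dpsi_threshold: float = 0.1
    prob_threshold: float = 0.9
    dpsi_effect: float = 0.3
    excluded_fraction: float = 0.89
    # eclip
    eclip_p_bind_g4: float = 0.6
    eclip_p_bind_no_g4: float = 0.3


def _rngs(config: SynthConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n)]


# --- genome ----------------------------------------------------------------

def generate_genome(config: SynthConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeSequence, dict]:
    """First-order Markov genome; realised dinucleotide frequencies track
    the transition matrix. Identical-row matrices reduce to i.i.d.
    sampling and are generated vectorised."""
    rng = rng or np.random.default_rng(config.seed)
    T = np.asarray(config.transition_matrix, dtype=float)
    if T.shape != (4, 4) or (T < 0).any() or \
            not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be 4x4 with rows summing to 1")
    stationary = _stationary(T)
    chroms = {}
    for ci in range(config.n_chroms):
        n = config.chrom_length
        if np.allclose(T, T[0]):  # zeroth-order: i.i.d.
            idx = rng.choice(4, size=n, p=T[0])
        else:
            idx = np.empty(n, dtype=np.int8)
            cum = T.cumsum(axis=1)
            u = rng.random(n)
            state = int(rng.choice(4, p=stationary))
            idx[0] = state
            for i in range(1, n):
                state = int(np.searchsorted(cum[state], u[i], side="right"))
                idx[i] = state
        chroms[f"chr{ci + 1}"] = "".join(BASES[i] for i in idx)
    truth = {"transition_matrix": T.tolist(), "seed": config.seed}
    return GenomeSequence(chroms), truth


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    v = np.abs(v)
    return v / v.sum()


# --- annotation ------------------------------------------------------------

def _sample_window(pfm: PositionalFrequencyMatrix,
                   rng: np.random.Generator, weak: bool) -> str:
    if weak:
        return "".join(rng.choice(list(BASES), size=pfm.width))
    out = []
    for row in pfm.freqs:
        out.append(BASES[rng.choice(4, p=row)])
    return "".join(out)


def generate_annotation(genome: GenomeSequence, config: SynthConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[GenomeSequence, list[GeneModel], list[SpliceSite]]:
    """Place non-overlapping multi-exon genes and carve their splice sites.

    Introns are forced GT..AG by overwriting the genome at the
    boundaries; donor/acceptor windows are drawn from the synthetic
    consensus PFMs (a ``weak_site_fraction`` of sites instead gets
    uniform background, giving a controllable strength distribution).
    Returns the modified genome, the models and the internal-site truth.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.chroms.items()}
    chrom_names = sorted(seqs)
    margin = 800  # keep +/-500 windows and PFM windows on-chromosome
    cursors = {c: margin for c in chrom_names}
    donor_pfm = default_donor_pfm(config.pfm_strength)
    acceptor_pfm = default_acceptor_pfm(config.pfm_strength)
    models: list[GeneModel] = []
    mu_e, sd_e = config.exon_length_logn
    mu_i, sd_i = config.intron_length_logn
    attempts = 0
    gi = 0
    while gi < config.n_genes:
        attempts += 1
        if attempts > 100 * config.n_genes:
            raise RuntimeError(
                f"cannot place {config.n_genes} genes without overlap")
        chrom = min(chrom_names, key=lambda c: cursors[c])  # most room left
        n_exons = int(rng.integers(config.exon_count_range[0],
                                   config.exon_count_range[1] + 1))
        exon_lens = np.maximum(
            config.min_exon,
            rng.lognormal(mu_e, sd_e, size=n_exons).astype(int))
        intron_lens = np.maximum(
            config.min_intron,
            rng.lognormal(mu_i, sd_i, size=n_exons - 1).astype(int))
        span = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(500, 2000))
        start = cursors[chrom] + gap
        if start + span > len(seqs[chrom]) - margin:
            continue  # resample lengths; attempt budget above bounds this
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursors[chrom] = pos
        tx = f"g{gi + 1:04d}.t1"
        model = GeneModel(gene_id=f"g{gi + 1:04d}", transcript_id=tx,
                          chrom=chrom, strand=strand, exons=exons)
        _write_splice_signals(seqs[chrom], model, donor_pfm, acceptor_pfm,
                              rng, config.weak_site_fraction)
        models.append(model)
        gi += 1
    new_genome = GenomeSequence(
        {c: bytes(b).decode("ascii") for c, b in seqs.items()})
    sites = extract_internal_splice_sites(models, new_genome)
    return new_genome, models, sites


def _write(seq: bytearray, start: int, s: str) -> None:
    seq[start:start + len(s)] = s.encode("ascii")


def _write_splice_signals(seq: bytearray, model: GeneModel,
                          donor_pfm, acceptor_pfm,
                          rng: np.random.Generator, weak_frac: float) -> None:
    for a, b in model.introns:
        weak_d = rng.random() < weak_frac
        weak_a = rng.random() < weak_frac
        dwin = _sample_window(donor_pfm, rng, weak_d)
        awin = _sample_window(acceptor_pfm, rng, weak_a)
        if model.strand == "+":
            # donor junction at a: window covers [a-3, a+6)
            _write(seq, a - donor_pfm.junction_offset, dwin)
            # acceptor junction at b: window covers [b-20, b+3)
            _write(seq, b - acceptor_pfm.junction_offset, awin)
            _write(seq, a, "GT")
            _write(seq, b - 2, "AG")
        else:
            # transcription right-to-left: donor junction at b, acceptor at a
            _write(seq, b + donor_pfm.junction_offset - donor_pfm.width,
                   reverse_complement(dwin))
            _write(seq, a + acceptor_pfm.junction_offset - acceptor_pfm.width,
                   reverse_complement(awin))
            _write(seq, b - 2, "AC")
            _write(seq, a, "CT")


# --- G4 planting -----------------------------------------------------------

#: bases cleared on each side of a planted motif so that scanning
#: recovers exactly the planted span (no chaining with background runs:
#: a gap of 8 > MAX_LOOP breaks any chain)
PLANT_BUFFER = 8
#: minimum offset keeps buffer + motif clear of junction dinucleotides
MIN_PLANT_OFFSET = PLANT_BUFFER + 4


def _g4_sequence(rng: np.random.Generator, config: SynthConfig) -> str:
    r0, r1 = config.run_length_range
    l0, l1 = config.loop_length_range
    parts = []
    for k in range(config.n_runs):
        parts.append("G" * int(rng.integers(r0, r1 + 1)))
        if k < config.n_runs - 1:
            loop_len = int(rng.integers(l0, l1 + 1))
            while True:  # no G (would extend runs) and no C-run seeds
                loop = "".join(rng.choice(list("ACT"), size=loop_len))
                if "CC" not in loop:
                    break
            parts.append(loop)
    return "".join(parts)


def plant_g4s(genome: GenomeSequence, sites: list[SpliceSite],
              config: SynthConfig, rng: np.random.Generator | None = None
              ) -> tuple[GenomeSequence, list[MotifHit], dict[str, dict]]:
    """Overwrite consensus G4s into the intronic flank of selected sites.

    Each site is selected with ``plant_rate`` (optionally length-coupled:
    ``plant_rate_long_intron`` applies to introns above
    ``long_intron_threshold``). The motif's proximal edge sits at a
    drawn offset (>= 3 nt, so junction dinucleotides are never touched)
    into the intron; strand is non-template with probability
    r / (1 + r). Returns the modified genome, the truth hits, and a per-
    site record {site_id: {strand_context, hit, offset}}.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.chroms.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    truth: list[MotifHit] = []
    per_site: dict[str, dict] = {}
    p_nt = config.nt_template_ratio / (1.0 + config.nt_template_ratio)
    for site in sites:
        rate = config.plant_rate
        if (config.plant_rate_long_intron is not None
                and site.intron_length > config.long_intron_threshold):
            rate = config.plant_rate_long_intron
        if rng.random() >= rate:
            continue
        context = "non_template" if rng.random() < p_nt else "template"
        strand = site.strand if context == "non_template" else \
            ("+" if site.strand == "-" else "-")
        placed = None
        buf = PLANT_BUFFER
        for _ in range(50):
            motif = _g4_sequence(rng, config)
            offset = max(MIN_PLANT_OFFSET,
                         int(round(rng.normal(config.offset_mean,
                                              config.offset_sd))))
            # stay inside the intron: never reach the far junction's AG/GT
            if offset + len(motif) + buf > site.intron_length - 3:
                continue
            intronic_is_left = (site.kind == ACCEPTOR) == (site.strand == "+")
            if intronic_is_left:
                end = site.junction - offset
                start = end - len(motif)
            else:
                start = site.junction + offset
                end = start + len(motif)
            if start - buf < 0 or end + buf > len(seqs[site.chrom]):
                continue
            if any(s0 < end + buf and e0 > start - buf
                   for s0, e0 in occupied[site.chrom]):
                continue
            placed = (start, end, motif, offset)
            break
        if placed is None:
            continue
        start, end, motif, offset = placed
        written = motif if strand == "+" else reverse_complement(motif)
        # buffer of A/T on both sides: background runs cannot chain into
        # the planted span, so the scanner recovers it exactly
        pad_l = "".join(rng.choice(list("AT"), size=buf))
        pad_r = "".join(rng.choice(list("AT"), size=buf))
        _write(seqs[site.chrom], start - buf, pad_l + written + pad_r)
        occupied[site.chrom].append((start - buf, end + buf))
        hit = MotifHit(chrom=site.chrom, start=start, end=end, strand=strand,
                       kind="g4", n_g_runs=min(config.n_runs, 6),
                       matched_sequence=written)
        truth.append(hit)
        per_site[site.site_id] = {
            "strand_context": context, "hit": hit, "offset": offset}
    new_genome = GenomeSequence(
        {c: bytes(b).decode("ascii") for c, b in seqs.items()})
    return new_genome, truth, per_site


# --- PSI table -------------------------------------------------------------

def generate_psi_table(flags, config: SynthConfig,
                       rng: np.random.Generator | None = None,
                       sites: list[SpliceSite] | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Cassette-node PSI table with a planted odds ratio.

    ``flags`` is a boolean per node (G4-flanked or not). Differential
    exclusion is Bernoulli with baseline odds multiplied by
    ``planted_or`` when flagged; differential nodes draw |dPSI| >=
    threshold and probability >= threshold, others stay below. When
    ``sites`` is given, node coordinates come from the sites (aligned
    with flags); otherwise synthetic coordinates are emitted.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    flags = np.asarray(list(flags), dtype=bool)
    p0 = config.psi_base_rate
    odds0 = p0 / (1 - p0)
    odds1 = odds0 * config.planted_or
    p1 = odds1 / (1 + odds1)
    rows = []
    delta = config.dpsi_threshold
    for i, flag in enumerate(flags):
        p = p1 if flag else p0
        differential = rng.random() < p
        if differential:
            mag = delta + rng.random() * config.dpsi_effect
            sign = -1.0 if rng.random() < config.excluded_fraction else 1.0
            dpsi = float(np.clip(sign * mag, -1, 1))
            prob = float(config.prob_threshold
                         + rng.random() * (1 - config.prob_threshold))
        else:
            dpsi = float((rng.random() * 2 - 1) * delta * 0.99)
            prob = float(rng.random())
        if sites is not None:
            s = sites[i]
            chrom, strand = s.chrom, s.strand
            start, end = s.junction, s.junction + s.exon_length
            node_id = s.site_id
        else:
            chrom, strand = "chr1", "+"
            start = 1000 + 500 * i
            end = start + 120
            node_id = f"node{i + 1}"
        rows.append({
            "gene": f"gene{i // 3 + 1}", "node": node_id, "chrom": chrom,
            "start": start, "end": end, "strand": strand, "type": "CE",
            "psi_a": 0.5, "psi_b": 0.5 + dpsi, "delta_psi": dpsi,
            "probability": prob, "g4_flag": bool(flag)})
    df = pd.DataFrame(rows)
    truth = {"planted_or": config.planted_or, "base_rate": p0,
             "n_nodes": len(flags), "n_flagged": int(flags.sum())}
    return df, truth


# --- variant / peak / eclip tracks -----------------------------------------

def generate_variants(g4_hits, sites: list[SpliceSite], config: SynthConfig,
                      rng: np.random.Generator | None = None, L: int = 500
                      ) -> tuple[list[tuple[str, int, str]],
                                 list[tuple[str, int, str]], dict]:
    """Background SNPs plus sQTLs with planted uplift inside G4 bp.

    Both classes share the background rate over the +/-L windows; sQTLs
    get extra (uplift - 1) x base density restricted to G4-covered base
    pairs within ``uplift_range`` of the junction.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
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
    sqtls: list[tuple[str, int, str]] = []
    snps: list[tuple[str, int, str]] = []
    for s in sites:
        lo = max(0, s.junction - L)
        hi = min(sizes[s.chrom], s.junction + L)
        width = hi - lo
        for out, cls in ((snps, "snp"), (sqtls, "sqtl")):
            n_bg = rng.poisson(config.snp_rate * width)
            for p in rng.integers(lo, hi, size=n_bg):
                out.append((s.chrom, int(p), cls))
        # uplift: extra sQTLs on qualifying bp only
        qual = np.flatnonzero(cov[s.chrom][lo:hi]) + lo
        qual = qual[np.abs(qual - s.junction) <= config.uplift_range]
        if len(qual):
            n_extra = rng.poisson(
                (config.sqtl_uplift - 1.0) * config.snp_rate * len(qual))
            for p in rng.choice(qual, size=n_extra):
                sqtls.append((s.chrom, int(p), "sqtl"))
    truth = {"uplift": config.sqtl_uplift, "range": config.uplift_range,
             "base_rate": config.snp_rate}
    return sqtls, snps, truth


def generate_peaks(motif_hits, config: SynthConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[list[Interval], dict]:
    """Per-motif overlapping peaks with jittered boundaries."""
    rng = rng or np.random.default_rng(config.seed + 5)
    peaks = []
    for h in motif_hits:
        if rng.random() >= config.peak_overlap_prob:
            continue
        jl = int(rng.integers(0, config.peak_jitter + 1))
        jr = int(rng.integers(0, config.peak_jitter + 1))
        peaks.append(Interval(h.chrom, max(0, h.start - jl), h.end + jr,
                              h.strand, "peak"))
    truth = {"overlap_prob": config.peak_overlap_prob,
             "n_motifs": sum(1 for _ in motif_hits)}
    return peaks, truth


def generate_eclip(sites_g4: list[SpliceSite], sites_no_g4: list[SpliceSite],
                   config: SynthConfig,
                   rng: np.random.Generator | None = None,
                   region: tuple[int, int] = (-100, 100), w: int = 10,
                   p_bind_g4: np.ndarray | float | None = None,
                   p_bind_no_g4: np.ndarray | float | None = None
                   ) -> tuple[list[Interval], dict]:
    """Per-site, per-bin Bernoulli binding, emitted as peak intervals.

    ``p_bind_*`` may be a scalar or a per-bin array; defaults come from
    the config. A bound bin gets one peak covering its central 4 bp.
    """
    rng = rng or np.random.default_rng(config.seed + 6)
    lo, hi = region
    n_bins = (hi - lo) // w
    def as_arr(p, default):
        if p is None:
            p = default
        return np.broadcast_to(np.asarray(p, dtype=float), (n_bins,))
    pg = as_arr(p_bind_g4, config.eclip_p_bind_g4)
    pn = as_arr(p_bind_no_g4, config.eclip_p_bind_no_g4)
    peaks: list[Interval] = []
    for sites, probs in ((sites_g4, pg), (sites_no_g4, pn)):
        for s in sites:
            bound = rng.random(n_bins) < probs
            for b in np.flatnonzero(bound):
                off = lo + b * w + w // 2
                if s.strand == "+":
                    g = s.junction + off
                else:
                    g = s.junction - 1 - off - 3
                if g >= 0:
                    peaks.append(Interval(s.chrom, g, g + 4, ".", "eclip"))
    truth = {"p_bind_g4": pg.tolist(), "p_bind_no_g4": pn.tolist(),
             "region": region, "w": w}
    return peaks, truth


# --- whole bundle ----------------------------------------------------------

@dataclass
class SynthBundle:
    config: SynthConfig
    genome: GenomeSequence
    models: list[GeneModel]
    sites: list[SpliceSite]
    g4_truth: list[MotifHit]
    per_site_g4: dict[str, dict]
    psi_table: pd.DataFrame
    peaks: list[Interval]
    sqtls: list
    snps: list
    truth: dict


def generate_bundle(config: SynthConfig) -> SynthBundle:
    """The full deterministic desk-scale bundle from one master seed."""
    r_gen, r_ann, r_g4, r_psi, r_var, r_peak = _rngs(config, 6)
    genome, g_truth = generate_genome(config, r_gen)
    genome, models, sites = generate_annotation(genome, config, r_ann)
    genome, g4_truth, per_site = plant_g4s(genome, sites, config, r_g4)
    flags = [s.site_id in per_site for s in sites]
    psi, psi_truth = generate_psi_table(flags, config, r_psi, sites=sites)
    sqtls, snps, var_truth = generate_variants(g4_truth, sites, config, r_var)
    peaks, peak_truth = generate_peaks(g4_truth, config, r_peak)
    return SynthBundle(
        config=config, genome=genome, models=models, sites=sites,
        g4_truth=g4_truth, per_site_g4=per_site, psi_table=psi,
        peaks=peaks, sqtls=sqtls, snps=snps,
        truth={"genome": g_truth, "psi": psi_truth,
               "variants": var_truth, "peaks": peak_truth})
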