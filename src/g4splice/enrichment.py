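"""Positional metaprofiles and overlap/density summaries around anchors.

The central object is the median-normalised metaprofile: for each signed
offset (transcription orientation, negative = upstream of the junction)
the number of anchor sites at which a feature registers, divided by the
median count over a fixed 1 kb normalisation window — so the flat
background sits at enrichment 1 regardless of the display width.
Registration is "coverage" by default (a position counts when any
feature base pair overlaps it); "start" and "midpoint" anchor modes are
available since published motif profiles do not always state which
convention they use.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .splice_annot import ACCEPTOR

logger = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """Per-offset counts and normalised enrichment around a set of anchors."""

    description: str
    offsets: np.ndarray  # signed, transcription orientation
    counts: np.ndarray  # number of sites with a feature at that offset
    n_per_offset: np.ndarray  # sites whose window covered that offset
    enrichment: np.ndarray  # counts / norm_constant (NaN if undefined)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_sites: int
    norm_constant: float  # median count over the normalisation window

    def to_dataframe(self, stratum: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "offset": self.offsets, "count": self.counts,
            "n": self.n_per_offset, "enrichment": self.enrichment,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi})
        df["stratum"] = stratum if stratum is not None else self.description
        return df


@dataclass
class DensitySummary:
    label: str
    density: float  # occurrences per bp
    bootstrap_sd: float
    n_boot: int
    n_sites: int = 0


def _chrom_arrays(features, chrom_sizes: dict[str, int],
                  mode: str) -> dict[str, np.ndarray]:
    """Binary per-position indicator of feature presence, per chromosome."""
    marks: dict[str, np.ndarray] = {
        c: np.zeros(n + 1, dtype=np.int32) for c, n in chrom_sizes.items()}
    for f in features:
        arr = marks.get(f.chrom)
        if arr is None:
            continue
        size = len(arr) - 1
        if mode == "coverage":
            s, e = max(0, f.start), min(size, f.end)
            if s < e:
                arr[s] += 1
                arr[e] -= 1
        else:
            pos = f.start if mode == "start" else int((f.start + f.end) // 2)
            if 0 <= pos < size:
                arr[pos] += 1
                arr[pos + 1] -= 1
    return {c: (np.cumsum(a[:-1]) > 0).astype(np.int8)
            for c, a in marks.items()}


def _infer_sizes(sites, features, pad: int) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for s in sites:
        sizes[s.chrom] = max(sizes.get(s.chrom, 0), s.junction + pad)
    for f in features:
        sizes[f.chrom] = max(sizes.get(f.chrom, 0), f.end + pad)
    return sizes


def positional_profile(sites, features, W: int = 100,
                       mode: str = "coverage", norm_window: int = 1000,
                       chrom_sizes: dict[str, int] | None = None,
                       description: str = "profile") -> MetaProfile:
    """Metaprofile of ``features`` around the junctions of ``sites``.

    Counts per signed offset are computed over the full normalisation
    half-width (``norm_window`` / 2 each side, 1 kb total by default)
    and normalised by the median count over that window; the returned
    profile is then cut down to the display half-width ``W``. Windows
    running off a chromosome end contribute only their covered offsets.
    Per-offset 95% CIs are Wilson score intervals on count / n, scaled
    by the same normalisation constant.
    """
    if mode not in ("coverage", "start", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    half = max(W, norm_window // 2)
    if chrom_sizes is None:
        chrom_sizes = _infer_sizes(sites, features, half + 1)
    ind = _chrom_arrays(features, chrom_sizes, mode)
    width = 2 * half
    counts = np.zeros(width, dtype=np.int64)
    n_per = np.zeros(width, dtype=np.int64)
    for s in sites:
        arr = ind.get(s.chrom)
        if arr is None:
            continue
        j = s.junction
        lo, hi = j - half, j + half
        clo, chi = max(0, lo), min(len(arr), hi)
        if clo >= chi:
            continue
        window = np.zeros(width, dtype=np.int8)
        covered = np.zeros(width, dtype=np.int8)
        window[clo - lo:chi - lo] = arr[clo:chi]
        covered[clo - lo:chi - lo] = 1
        if s.strand == "-":
            window = window[::-1]
            covered = covered[::-1]
        counts += window
        n_per += covered
    offsets = np.arange(-half, half)
    norm_sel = (offsets >= -norm_window // 2) & (offsets < norm_window // 2)
    median = float(np.median(counts[norm_sel]))
    if median <= 0:
        logger.warning("zero median count in normalisation window; "
                       "enrichment undefined")
        enrichment = np.full(width, np.nan)
        ci_lo = np.full(width, np.nan)
        ci_hi = np.full(width, np.nan)
    else:
        enrichment = counts / median
        with np.errstate(invalid="ignore", divide="ignore"):
            p_lo, p_hi = proportion_confint(
                counts, np.maximum(n_per, 1), alpha=0.05, method="wilson")
        ci_lo = np.asarray(p_lo) * n_per / median
        ci_hi = np.asarray(p_hi) * n_per / median
    sel = (offsets >= -W) & (offsets < W)
    return MetaProfile(
        description=description, offsets=offsets[sel], counts=counts[sel],
        n_per_offset=n_per[sel], enrichment=enrichment[sel],
        ci_lo=ci_lo[sel], ci_hi=ci_hi[sel],
        n_sites=len(sites), norm_constant=median)


def strata_profiles(sites, features, labels, **kwargs
                    ) -> dict[str, MetaProfile]:
    """Independent metaprofiles per stratum label (aligned with sites).

    Empty strata are omitted (logged); every profile shares the same
    offsets and records its own n.
    """
    sites = list(sites)
    labels = list(labels)
    if len(labels) != len(sites):
        raise ValueError("labels must align with sites")
    out: dict[str, MetaProfile] = {}
    for lab in sorted(set(map(str, labels))):
        group = [s for s, l in zip(sites, labels) if str(l) == lab]
        if not group:
            logger.info("stratum %s empty; omitted", lab)
            continue
        out[lab] = positional_profile(
            group, features, description=str(lab), **kwargs)
    return out


def nearest_distance(sites, features) -> list[float | None]:
    """Signed distance (bp) from each junction to the nearest feature
    midpoint, in transcription orientation (positive = downstream).

    Ties between equidistant features are broken toward the intronic
    side of the site. Sites on a chromosome without features get None.
    """
    mids: dict[str, np.ndarray] = {}
    feats = list(features)
    for c in {f.chrom for f in feats}:
        mids[c] = np.sort(np.array(
            [(f.start + f.end) / 2.0 for f in feats if f.chrom == c]))
    out: list[float | None] = []
    for s in sites:
        m = mids.get(s.chrom)
        if m is None or len(m) == 0:
            out.append(None)
            continue
        j = s.junction
        i = int(np.searchsorted(m, j))
        cands = [m[k] for k in (i - 1, i) if 0 <= k < len(m)]
        # signed, transcription orientation
        dists = [(x - j) if s.strand == "+" else (j - x) for x in cands]
        best = min(abs(d) for d in dists)
        tied = [d for d in dists if abs(d) == best]
        if len(tied) == 2 and tied[0] != tied[1]:
            # intronic side: upstream (negative) for acceptors,
            # downstream (positive) for donors
            want_neg = s.kind == ACCEPTOR
            tied.sort()
            out.append(tied[0] if want_neg else tied[1])
        else:
            out.append(tied[0])
    return out


class _OverlapIndex:
    """Any-overlap membership test over an interval set."""

    def __init__(self, intervals):
        self.by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c, pairs in tmp.items():
            pairs.sort()
            starts = [p[0] for p in pairs]
            maxend = []
            cur = -1
            for _, e in pairs:
                cur = max(cur, e)
                maxend.append(cur)
            self.by_chrom[c] = (starts, maxend)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return False
        starts, maxend = entry
        i = bisect_right(starts, end - 1)  # intervals with start < end
        return i > 0 and maxend[i - 1] > start


def overlap_venn(set_a, set_b, set_c, slop: int = 0,
                 names: tuple[str, str, str] = ("A", "B", "C")
                 ) -> dict[str, dict[str, int]]:
    """Asymmetric three-way overlap counts.

    For each set, every element is assigned to the region named after
    the sets it intersects (>= 1 bp after symmetric ``slop`` expansion),
    e.g. elements of A fall into one of A, A+B, A+C, A+B+C. Counts are
    per set because interval overlap is not an equivalence relation.
    """
    sets = {names[0]: list(set_a), names[1]: list(set_b), names[2]: list(set_c)}
    idx = {n: _OverlapIndex(v) for n, v in sets.items()}
    out: dict[str, dict[str, int]] = {}
    for name, elems in sets.items():
        others = [n for n in names if n != name]
        region_counts: dict[str, int] = {}
        for iv in elems:
            hit = [o for o in others
                   if idx[o].overlaps(iv.chrom, iv.start - slop, iv.end + slop)]
            region = "+".join(sorted([name] + hit, key=list(names).index))
            region_counts[region] = region_counts.get(region, 0) + 1
        out[name] = region_counts
    return out


def density_with_bootstrap(sites, features, flank: int,
                           n_boot: int = 1000, seed: int | None = None,
                           label: str = "density",
                           chrom_sizes: dict[str, int] | None = None
                           ) -> DensitySummary:
    """Feature density in flank windows around junctions, with a
    bootstrap (over sites, with replacement) standard deviation.

    density = total feature occurrences (features overlapping a window)
    over total window bp; windows clipped at chromosome ends.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    # count intervals overlapping [lo, hi) as #(start < hi) - #(end <= lo)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    feats = list(features)
    for c in {f.chrom for f in feats}:
        starts[c] = np.sort(np.array([f.start for f in feats if f.chrom == c]))
        ends[c] = np.sort(np.array([f.end for f in feats if f.chrom == c]))
    counts = np.zeros(len(sites))
    bps = np.zeros(len(sites))
    for i, s in enumerate(sites):
        lo = max(0, s.junction - flank)
        hi = s.junction + flank
        if chrom_sizes is not None:
            hi = min(chrom_sizes.get(s.chrom, hi), hi)
        if s.chrom in starts:
            counts[i] = (np.searchsorted(starts[s.chrom], hi, side="left")
                         - np.searchsorted(ends[s.chrom], lo, side="right"))
        bps[i] = hi - lo
    density = counts.sum() / bps.sum()
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, len(sites), size=(n_boot, len(sites)))
    boots = counts[resamples].sum(axis=1) / bps[resamples].sum(axis=1)
    return DensitySummary(label, float(density), float(boots.std(ddof=1)),
                          n_boot, len(sites))


def profiles_to_tsv(profiles: dict[str, MetaProfile], path) -> None:
    df = pd.concat([p.to_dataframe(stratum=k) for k, p in profiles.items()],
                   ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
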