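"""eCLIP differential-binding profiles around G4-flanked splice sites.

For one RNA-binding protein (factor) replicate, the splice-site region
(default -100..+100 around the junction, 10 bp bins) is summarised as
the fraction of sites in a group whose bin overlaps at least one peak
base pair; the differential profile is that fraction at G4-flanked
sites minus non-flanked sites, with a per-bin 2x2 chi-squared
(bound/unbound x group) Bonferroni-corrected over the profile's bins.
Non-significant differences are masked to exactly zero before Ward
clustering of the concatenated (non-template | template) tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

DEFAULT_REGION = (-100, 100)
DEFAULT_BIN = 10
LOW_POWER_N = 20
DEFAULT_K = 10


@dataclass
class FactorProfile:
    """Binned differential binding of one factor replicate."""

    factor: str
    cell_line: str
    replicate: str
    orientation: str  # "non_template" | "template"
    bin_edges: np.ndarray
    frac_g4: np.ndarray  # bound-site fraction, G4-flanked group
    frac_no_g4: np.ndarray
    differential: np.ndarray  # frac_g4 - frac_no_g4 (unmasked)
    p_adj: np.ndarray  # per-bin Bonferroni-adjusted p
    low_power: bool = False

    @property
    def profile_id(self) -> str:
        return f"{self.factor}:{self.cell_line}:{self.replicate}:{self.orientation}"

    def masked(self, alpha: float = 0.05) -> np.ndarray:
        """Differential with non-significant bins set to exactly 0."""
        out = self.differential.copy()
        out[~(self.p_adj < alpha)] = 0.0
        return out

    @property
    def significant(self) -> bool:
        return bool((self.p_adj < 0.05).any())


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]  # profile id -> cluster 1..k
    k: int
    linkage_matrix: np.ndarray = field(repr=False, default=None)


def _bin_bound(sites, peaks_by_chrom, edges) -> np.ndarray:
    """(n_sites, n_bins) booleans: bin overlaps >= 1 peak bp."""
    n_bins = len(edges) - 1
    out = np.zeros((len(sites), n_bins), dtype=bool)
    for i, s in enumerate(sites):
        entry = peaks_by_chrom.get(s.chrom)
        if entry is None:
            continue
        starts, maxend = entry
        for b in range(n_bins):
            lo, hi = int(edges[b]), int(edges[b + 1])
            if s.strand == "+":
                g_lo, g_hi = s.junction + lo, s.junction + hi
            else:  # transcription orientation: offset t is base junction-1-t
                g_lo, g_hi = s.junction - hi, s.junction - lo
            j = np.searchsorted(starts, g_hi, side="left")
            out[i, b] = j > 0 and maxend[j - 1] > g_lo
    return out


def _peak_index(peaks) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for c, pairs in by.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        maxend = np.maximum.accumulate(np.array([p[1] for p in pairs]))
        out[c] = (starts, maxend)
    return out


def binned_binding_enrichment(sites_g4, sites_no_g4, peaks,
                              factor: str = "", cell_line: str = "",
                              replicate: str = "",
                              orientation: str = "non_template",
                              region: tuple[int, int] = DEFAULT_REGION,
                              w: int = DEFAULT_BIN) -> FactorProfile:
    """Differential bound-site fraction per bin, G4 vs no-G4 group.

    Per-bin significance: chi-squared on (bound, unbound) x group with
    Yates correction, Bonferroni over the profile's bins. Groups under
    20 sites flag the profile low-power.
    """
    lo, hi = region
    if (hi - lo) % w != 0:
        raise ValueError("region must divide evenly into bins")
    edges = np.arange(lo, hi + 1, w)
    n_bins = len(edges) - 1
    idx = _peak_index(peaks)
    bound_g4 = _bin_bound(list(sites_g4), idx, edges)
    bound_no = _bin_bound(list(sites_no_g4), idx, edges)
    n1, n0 = len(bound_g4), len(bound_no)
    frac_g4 = bound_g4.mean(axis=0) if n1 else np.zeros(n_bins)
    frac_no = bound_no.mean(axis=0) if n0 else np.zeros(n_bins)
    p_adj = np.ones(n_bins)
    for b in range(n_bins):
        k1 = int(bound_g4[:, b].sum()) if n1 else 0
        k0 = int(bound_no[:, b].sum()) if n0 else 0
        table = np.array([[k1, n1 - k1], [k0, n0 - k0]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        p_adj[b] = min(1.0, n_bins * p)
    return FactorProfile(
        factor=factor, cell_line=cell_line, replicate=replicate,
        orientation=orientation, bin_edges=edges,
        frac_g4=frac_g4, frac_no_g4=frac_no,
        differential=frac_g4 - frac_no, p_adj=p_adj,
        low_power=min(n1, n0) < LOW_POWER_N)


def mask_and_cluster(profiles: list[FactorProfile], k: int = DEFAULT_K,
                     alpha: float = 0.05) -> ClusterAssignment:
    """Ward clustering of masked differential tracks into k clusters.

    Profiles for one factor replicate are paired across orientations
    (non_template | template concatenated; a missing orientation is
    imputed as zeros). Deterministic: rows sorted by id before linkage.
    """
    paired: dict[str, dict[str, FactorProfile]] = {}
    for p in profiles:
        key = f"{p.factor}:{p.cell_line}:{p.replicate}"
        paired.setdefault(key, {})[p.orientation] = p
    if len(paired) < k:
        raise ValueError(f"need >= {k} profiles, got {len(paired)}")
    ids = sorted(paired)
    n_bins = len(profiles[0].differential)
    rows = []
    for pid in ids:
        parts = []
        for orient in ("non_template", "template"):
            prof = paired[pid].get(orient)
            parts.append(prof.masked(alpha) if prof is not None
                         else np.zeros(n_bins))
        rows.append(np.concatenate(parts))
    X = np.vstack(rows)
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        assignments=dict(zip(ids, (int(x) for x in labels))),
        k=k, linkage_matrix=Z)


def lof_concordance(eclip_profiles: list[FactorProfile],
                    clusters: ClusterAssignment,
                    lof_results: pd.DataFrame,
                    min_replicates: int = 2,
                    alpha: float = 0.05) -> pd.DataFrame:
    """High-confidence factors: concordant eCLIP binding and LoF effect.

    ``lof_results`` columns: factor, cell_line, log_or, p_adj. A factor
    qualifies when (i) it has a significant eCLIP differential profile
    and a significant LoF association (p_adj < alpha) in the same cell
    line, and (ii) at least ``min_replicates`` of its eCLIP replicates
    fall in the same cluster. Returns one row per qualifying factor with
    the direction of the LoF log odds ratio.
    """
    by_factor: dict[str, list[FactorProfile]] = {}
    for p in eclip_profiles:
        by_factor.setdefault(p.factor, []).append(p)
    rows = []
    for factor, profs in sorted(by_factor.items()):
        sig_cells = {p.cell_line for p in profs if p.significant}
        lof = lof_results[(lof_results["factor"] == factor)
                          & (lof_results["p_adj"] < alpha)]
        common = sig_cells & set(lof["cell_line"])
        if not common:
            continue
        # replicate concordance: >= min_replicates replicates in one cluster
        rep_clusters: dict[str, list[int]] = {}
        for p in profs:
            key = f"{p.factor}:{p.cell_line}:{p.replicate}"
            cl = clusters.assignments.get(key)
            if cl is not None:
                rep_clusters.setdefault(key, []).append(cl)
        counts: dict[int, set[str]] = {}
        for key, cls in rep_clusters.items():
            for cl in cls:
                counts.setdefault(cl, set()).add(key)
        if not counts or max(len(v) for v in counts.values()) < min_replicates:
            continue
        sub = lof[lof["cell_line"].isin(common)]
        mean_log_or = float(sub["log_or"].mean())
        rows.append({"factor": factor,
                     "cell_lines": ",".join(sorted(common)),
                     "lof_log_or": mean_log_or,
                     "direction": "positive" if mean_log_or > 0 else "negative"})
    return pd.DataFrame(rows, columns=["factor", "cell_lines",
                                       "lof_log_or", "direction"])
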