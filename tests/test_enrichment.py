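"""Metaprofiles, nearest distances, Venn overlaps, bootstrap densities."""

import numpy as np
import pytest

from g4splice.genome_io import Interval
from g4splice.splice_annot import ACCEPTOR, DONOR, SpliceSite
from g4splice.enrichment import (density_with_bootstrap, nearest_distance,
                                 overlap_venn, positional_profile,
                                 strata_profiles)


def make_sites(n, kind=DONOR, strand="+", spacing=3000, start=2000,
               chrom="c"):
    return [SpliceSite(f"s{i}", kind, chrom, start + i * spacing, strand)
            for i in range(n)]


class TestPositionalProfile:
    def test_planted_spike_and_flat_elsewhere(self):
        sites = make_sites(50)
        feats = [Interval("c", s.junction + 40, s.junction + 60)
                 for s in sites]
        prof = positional_profile(sites, feats, W=100)
        spike = (prof.offsets >= 40) & (prof.offsets < 60)
        assert np.all(prof.counts[spike] == 50)
        assert np.all(prof.counts[~spike] == 0)

    def test_minus_strand_offsets_are_transcriptional(self):
        sites = make_sites(10, strand="-")
        # 20 bp feature ending 40 bp before the junction (genomically
        # left) = transcription-downstream offsets [+40, +60)
        feats = [Interval("c", s.junction - 60, s.junction - 40)
                 for s in sites]
        prof = positional_profile(sites, feats, W=100)
        spike = prof.offsets[prof.counts > 0]
        assert spike.min() == 40 and spike.max() == 59

    def test_uniform_features_enrich_to_one(self, rng):
        sites = make_sites(10_000, spacing=1100)
        # ~30% coverage from randomly placed 15-mers
        span = sites[-1].junction + 2000
        n_feats = int(span * 0.3 / 15)
        feats = [Interval("c", int(p), int(p) + 15)
                 for p in rng.integers(0, span, size=n_feats)]
        prof = positional_profile(sites, feats, W=300)
        assert np.nanmax(np.abs(prof.enrichment - 1)) < 0.1

    def test_median_normalisation_idempotent(self, rng):
        sites = make_sites(200)
        feats = [Interval("c", int(p), int(p) + 20)
                 for p in rng.integers(0, 610_000, size=4000)]
        prof = positional_profile(sites, feats, W=500)
        renorm = prof.counts / np.median(prof.counts)
        np.testing.assert_allclose(renorm, prof.enrichment)
        assert np.median(prof.enrichment) == pytest.approx(1.0)

    def test_coverage_totals_conserved(self):
        """Total profile counts equal summed feature-window overlaps."""
        sites = make_sites(20)
        feats = [Interval("c", s.junction - 37, s.junction + 13)
                 for s in sites]  # disjoint features, one per site
        prof = positional_profile(sites, feats, W=500)
        assert prof.counts.sum() == sum(f.length for f in feats)

    def test_zero_median_gives_nan_enrichment(self):
        sites = make_sites(5)
        prof = positional_profile(sites, [], W=50)
        assert np.isnan(prof.enrichment).all()

    def test_ci_brackets_point_estimate(self):
        sites = make_sites(40)
        feats = [Interval("c", s.junction - 200, s.junction + 200)
                 for s in sites[::2]]
        prof = positional_profile(sites, feats, W=100)
        ok = ~np.isnan(prof.enrichment)
        assert np.all(prof.ci_lo[ok] <= prof.enrichment[ok] + 1e-9)
        assert np.all(prof.ci_hi[ok] >= prof.enrichment[ok] - 1e-9)


class TestStrataProfiles:
    def test_single_stratum_equals_plain_profile(self):
        sites = make_sites(30)
        feats = [Interval("c", s.junction + 10, s.junction + 30)
                 for s in sites]
        plain = positional_profile(sites, feats, W=100)
        (only,) = strata_profiles(sites, feats, ["all"] * 30, W=100).values()
        np.testing.assert_array_equal(plain.counts, only.counts)

    def test_planted_two_to_one_ratio(self):
        sites = make_sites(90)
        labels = ["non_template"] * 60 + ["template"] * 30
        feats = [Interval("c", s.junction + 50, s.junction + 70)
                 for s in sites]
        profs = strata_profiles(sites, feats, labels, W=100)
        nt = profs["non_template"].counts.max()
        t = profs["template"].counts.max()
        assert nt == 60 and t == 30

    def test_empty_stratum_omitted(self):
        sites = make_sites(10)
        profs = strata_profiles(sites, [], ["a"] * 10, W=50)
        assert set(profs) == {"a"}


class TestNearestDistance:
    def test_examples(self):
        site = SpliceSite("s", DONOR, "c", 100, "+")
        assert nearest_distance([site], [Interval("c", 140, 160)]) == [50.0]
        # feature spanning the junction: small distance per midpoint rule
        assert nearest_distance([site], [Interval("c", 95, 105)]) == [0.0]
        # minus-strand gene: lower coordinates are downstream
        msite = SpliceSite("s", DONOR, "c", 100, "-")
        assert nearest_distance([msite], [Interval("c", 40, 60)]) == [50.0]

    def test_missing_chromosome_is_none(self):
        site = SpliceSite("s", DONOR, "c", 100, "+")
        assert nearest_distance([site], [Interval("x", 1, 5)]) == [None]

    def test_tie_broken_toward_intronic_side(self):
        acc = SpliceSite("s", ACCEPTOR, "c", 100, "+")
        don = SpliceSite("s", DONOR, "c", 100, "+")
        feats = [Interval("c", 45, 55), Interval("c", 145, 155)]  # +/-50
        assert nearest_distance([acc], feats) == [-50.0]  # intron upstream
        assert nearest_distance([don], feats) == [50.0]  # intron downstream

    def test_matches_quadratic_oracle(self, rng):
        sites = [SpliceSite(f"s{i}", DONOR, "c", int(j), "+")
                 for i, j in enumerate(rng.integers(0, 10_000, size=150))]
        feats = [Interval("c", int(p), int(p) + int(w))
                 for p, w in zip(rng.integers(0, 10_000, size=80),
                                 rng.integers(5, 40, size=80))]
        got = nearest_distance(sites, feats)
        for s, d in zip(sites, got):
            best = min(abs((f.start + f.end) / 2 - s.junction)
                       for f in feats)
            assert abs(d) == best


class TestOverlapVenn:
    def iv(self, *pairs):
        return [Interval("c", a, b) for a, b in pairs]

    def test_disjoint_sets_only_singletons(self):
        res = overlap_venn(self.iv((0, 10)), self.iv((20, 30)),
                           self.iv((40, 50)))
        assert res == {"A": {"A": 1}, "B": {"B": 1}, "C": {"C": 1}}

    def test_identical_sets_all_triple(self):
        ivs = [(0, 10), (20, 30)]
        res = overlap_venn(self.iv(*ivs), self.iv(*ivs), self.iv(*ivs))
        assert all(v == {"A+B+C": 2} for v in res.values())

    def test_slop_expands_membership(self):
        res = overlap_venn(self.iv((0, 10)), self.iv((12, 20)),
                           self.iv((100, 110)), slop=3)
        assert res["A"] == {"A+B": 1}

    def test_random_sets_match_brute_force(self, rng):
        def rand_set(n):
            return [Interval("c", int(p), int(p) + int(w))
                    for p, w in zip(rng.integers(0, 3000, size=n),
                                    rng.integers(1, 60, size=n))]
        A, B, C = rand_set(40), rand_set(40), rand_set(40)
        res = overlap_venn(A, B, C)

        def brute(elem, other):
            return any(elem.start < o.end and elem.end > o.start
                       for o in other)
        for name, elems, o1, o2 in (("A", A, ("B", B), ("C", C)),
                                    ("B", B, ("A", A), ("C", C)),
                                    ("C", C, ("A", A), ("B", B))):
            counts = {}
            for e in elems:
                members = [name] + [n for n, s in (o1, o2) if brute(e, s)]
                key = "+".join(sorted(members))
                counts[key] = counts.get(key, 0) + 1
            assert {k: v for k, v in res[name].items()} == \
                {"+".join(sorted(k.split("+"))): v
                 for k, v in counts.items()}


class TestDensityBootstrap:
    def test_one_occurrence_per_200bp_window(self):
        sites = make_sites(30, spacing=1000)
        feats = [Interval("c", s.junction + 10, s.junction + 20)
                 for s in sites]
        res = density_with_bootstrap(sites, feats, flank=100, n_boot=100,
                                     seed=1)
        assert res.density == pytest.approx(1 / 200)

    def test_duplicated_sites_same_density_smaller_sd(self):
        sites = make_sites(25, spacing=1000)
        feats = [Interval("c", s.junction + 10, s.junction + 20)
                 for s in sites[::3]]
        one = density_with_bootstrap(sites, feats, 100, n_boot=400, seed=2)
        dup = density_with_bootstrap(sites * 4, feats, 100, n_boot=400,
                                     seed=2)
        assert dup.density == pytest.approx(one.density)
        assert dup.bootstrap_sd < one.bootstrap_sd

    def test_sd_shrinks_with_site_count(self, rng):
        sds = []
        for n in (50, 200, 800):
            sites = make_sites(n, spacing=500)
            feats = [Interval("c", s.junction + 5, s.junction + 15)
                     for s in sites if rng.random() < 0.5]
            sds.append(density_with_bootstrap(sites, feats, 100,
                                              n_boot=300, seed=3).bootstrap_sd)
        assert sds[0] > sds[1] > sds[2]

    def test_deterministic_given_seed(self):
        sites = make_sites(20)
        feats = [Interval("c", s.junction + 5, s.junction + 25)
                 for s in sites]
        a = density_with_bootstrap(sites, feats, 100, seed=9)
        b = density_with_bootstrap(sites, feats, 100, seed=9)
        assert a.bootstrap_sd == b.bootstrap_sd
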