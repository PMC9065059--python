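"""Contingency statistics, G4 association labels, GC matching, sQTL bins."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4splice.genome_io import GenomeSequence, Interval
from g4splice.motif_scan import MotifHit
from g4splice.splice_annot import ACCEPTOR, DONOR, SpliceSite
from g4splice.association_stats import (association_from_counts,
                                        association_test, classify_nodes,
                                        gc_matched_controls,
                                        label_g4_association,
                                        length_comparisons,
                                        sqtl_adjusted_enrichment)
from g4splice.synthetic_data import SynthConfig, generate_psi_table


def psi_frame(rows):
    cols = ["node", "chrom", "start", "end", "delta_psi", "probability"]
    return pd.DataFrame([dict(zip(cols, r)) for r in rows])


class TestClassifyNodes:
    @pytest.mark.parametrize("dpsi,prob,diff,direction", [
        (-0.177, 0.95, True, "excluded"),  # the depolarisation case study
        (0.05, 0.99, False, "none"),
        (0.10, 0.90, True, "included"),  # boundary inclusive
        (-0.10, 0.90, True, "excluded"),
        (0.2, 0.89, False, "none"),
    ])
    def test_thresholds(self, dpsi, prob, diff, direction):
        (node,) = classify_nodes(psi_frame([("n1", "c", 0, 10, dpsi, prob)]))
        assert node.differential is diff
        assert node.direction == direction
        assert node.dpsi_threshold == 0.1 and node.prob_threshold == 0.9

    def test_out_of_range_dpsi_fails_with_row(self):
        with pytest.raises(ValueError, match="row 1"):
            classify_nodes(psi_frame([("a", "c", 0, 1, 0.5, 0.9),
                                      ("b", "c", 0, 1, 1.5, 0.9)]))


def motif(chrom, start, end, strand="+"):
    return MotifHit(chrom, start, end, strand, "g4", 4, "G" * (end - start))


class TestLabelAssociation:
    def node_at(self, start, end, strand="+"):
        return classify_nodes(psi_frame([("n", "c", start, end, 0.2, 0.95)]))[0]

    def test_boundary_within_100_of_motif_midpoint(self):
        node = self.node_at(1000, 1200)
        # midpoint 1090: distance 90 from the start boundary -> associated
        assert label_g4_association(
            [node], [motif("c", 1080, 1100)])[0].g4_associated
        # midpoint 1301: distance 101 from the nearer (end) boundary
        assert not label_g4_association(
            [node], [motif("c", 1300, 1302)])[0].g4_associated
        # exactly 100 is inclusive
        assert label_g4_association(
            [node], [motif("c", 1299, 1301)])[0].g4_associated

    def test_peak_distance_45(self):
        node = self.node_at(1000, 1200)
        peak_near = Interval("c", 1220, 1240)  # midpoint 1230, d=30
        peak_far = Interval("c", 1250, 1260)  # midpoint 1255, d=55
        assert label_g4_association([node], [], [peak_near])[0].g4_associated
        assert not label_g4_association([node], [], [peak_far])[0].g4_associated

    def test_orientation_restriction(self):
        node = self.node_at(1000, 1200)  # node strand '+'
        minus_hit = motif("c", 1010, 1030, "-")
        assert label_g4_association([node], [minus_hit])[0].g4_associated
        assert not label_g4_association(
            [node], [minus_hit], orientation="non_template")[0].g4_associated
        assert label_g4_association(
            [node], [minus_hit], orientation="template")[0].g4_associated

    def test_matches_quadratic_oracle(self, rng):
        nodes = [self.node_at(int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 50_000, 200),
                                 rng.integers(50, 300, 200))]
        hits = [motif("c", int(p), int(p) + 21)
                for p in rng.integers(0, 50_000, 60)]
        labelled = label_g4_association(nodes, hits)
        for n, lab in zip(nodes, labelled):
            expect = any(
                min(abs((h.start + h.end) / 2 - n.start),
                    abs((h.start + h.end) / 2 - n.end)) <= 100
                for h in hits)
            assert lab.g4_associated == expect


class TestAssociationTest:
    def test_or_eight_and_yates_chi2_formula(self):
        res = association_from_counts(10, 5, 2, 8)
        assert res.odds_ratio == pytest.approx(8.0)
        # independent hand formula for Yates-corrected chi-squared
        a, b, c, d = 10, 5, 2, 8
        n = a + b + c + d
        expected = (n * (abs(a * d - b * c) - n / 2) ** 2
                    / ((a + b) * (c + d) * (a + c) * (b + d)))
        assert res.chi2 == pytest.approx(expected)
        assert res.p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_haldane_correction_on_zero_cell(self):
        res = association_from_counts(0, 5, 2, 8)
        assert res.haldane
        assert res.odds_ratio == pytest.approx((0.5 * 8.5) / (5.5 * 2.5))

    def test_bonferroni_adjustment(self):
        res = association_from_counts(30, 10, 10, 30, m=6)
        assert res.p_adj == pytest.approx(min(1.0, 6 * res.p))

    def test_empty_margin_untestable(self):
        res = association_from_counts(0, 0, 5, 5)
        assert not res.testable
        assert math.isnan(res.p)

    def test_strata_by_type_and_direction(self):
        df = pd.DataFrame({
            "node": [f"n{i}" for i in range(8)],
            "chrom": "c", "start": 0, "end": 10,
            "type": ["CE"] * 6 + ["RI"] * 2,
            "delta_psi": [0.3, -0.3, 0.0, 0.0, 0.3, -0.4, 0.0, 0.5],
            "probability": [0.95] * 8,
        })
        nodes = classify_nodes(df)
        results = association_test(nodes)
        assert set(results) == {"CE:included", "CE:excluded", "RI:included"}
        assert all(r.m == 3 for r in results.values())

    def test_planted_or_recovered_in_ci(self):
        cfg = SynthConfig(seed=5, planted_or=3.0, psi_base_rate=0.15)
        rng = np.random.default_rng(5)
        flags = rng.random(4000) < 0.5
        df, truth = generate_psi_table(flags, cfg, rng)
        nodes = classify_nodes(df)
        from dataclasses import replace
        nodes = [replace(n, g4_associated=f) for n, f in zip(nodes, flags)]
        res = association_test(nodes, strata="overall")["overall"]
        lo, hi = res.log_or_ci()
        assert lo < math.log(3.0) < hi


class TestGcMatching:
    def test_identical_gc_lists_match_perfectly(self):
        g = GenomeSequence({"c": "ACGT" * 300})
        shorts = [Interval("c", i * 20, i * 20 + 12) for i in range(20)]
        longs = [Interval("c", 400 + i * 20, 400 + i * 20 + 12)
                 for i in range(20)]
        pairs = gc_matched_controls(shorts, longs, g, seed=0)
        assert len(pairs) == 20
        assert all(d == 0 for _, _, d in pairs)

    def test_disjoint_gc_ranges_fail(self):
        seq = "AT" * 500 + "GC" * 500
        g = GenomeSequence({"c": seq})
        shorts = [Interval("c", i * 10, i * 10 + 10) for i in range(15)]
        longs = [Interval("c", 1000 + i * 10, 1000 + i * 10 + 10)
                 for i in range(15)]
        with pytest.raises(ValueError, match="matched pairs"):
            gc_matched_controls(shorts, longs, g, tol=0.01, seed=0)

    def test_null_calibration_equal_g4_rates(self, rng):
        """With equal planted G4 rates in both matched groups, the
        G4-presence chi-squared is non-significant in >= 95/100 runs."""
        nonsig = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            n = 120
            g4_short = r.random(n) < 0.3
            g4_long = r.random(n) < 0.3
            table = np.array([
                [g4_short.sum(), n - g4_short.sum()],
                [g4_long.sum(), n - g4_long.sum()]])
            if (table.sum(axis=0) == 0).any():
                nonsig += 1
                continue
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
            if p >= 0.05:
                nonsig += 1
        assert nonsig >= 95


class TestLengthComparisons:
    def sites(self, ilens, elens=None, kind=ACCEPTOR):
        elens = elens or [100] * len(ilens)
        return [SpliceSite(f"s{i}", kind, "c", 10_000 + 5000 * i, "+",
                           exon_length=e, intron_length=l)
                for i, (l, e) in enumerate(zip(ilens, elens))]

    def test_known_medians_recovered(self):
        with_g4 = self.sites([500] * 20)
        without = self.sites([1500] * 20)
        for i, s in enumerate(without):
            object.__setattr__(s, "junction", 200_000 + 5000 * i)
        hits = [motif("c", s.junction - 60, s.junction - 40)
                for s in with_g4]  # intronic side of a plus acceptor
        df = length_comparisons(with_g4 + without, hits)
        row = df[(df.group == "g4_any")].iloc[0]
        assert row.median_intron_length == 500
        assert df[(df.group == "no_g4")].iloc[0].median_intron_length == 1500

    def test_identical_groups_mwu_nonsignificant(self, rng):
        ilens = list(rng.integers(100, 2000, size=60))
        a = self.sites(ilens)
        b = self.sites(ilens)
        for i, s in enumerate(b):
            object.__setattr__(s, "junction", 500_000 + 5000 * i)
        hits = [motif("c", s.junction - 60, s.junction - 40) for s in a]
        df = length_comparisons(a + b, hits)
        assert df[df.group == "g4_any"].iloc[0].mwu_p_vs_no_g4 > 0.5


class TestSqtlAdjustedEnrichment:
    def track_setup(self, rng, uplift_bins=False):
        sites = [SpliceSite(f"s{i}", DONOR, "c", 2000 + 2000 * i, "+")
                 for i in range(40)]
        # G4 bp spread over the whole +/-500 window of every site
        hits = []
        for s in sites:
            for off in range(-480, 500, 100):
                hits.append(motif("c", s.junction + off,
                                  s.junction + off + 20))
        return sites, hits

    def variants(self, rng, sites, hits, rate, uplift=1.0, urange=100):
        cov = set()
        for h in hits:
            cov.update(range(h.start, h.end))
        out = []
        for s in sites:
            for p in range(s.junction - 500, s.junction + 500):
                r = rate
                if p in cov and abs(p - s.junction) <= urange:
                    r = rate * uplift
                if rng.random() < r:
                    out.append(Interval("c", p, p + 1))
        return out

    def test_uniform_over_g4_bp_gives_flat_adjusted(self, rng):
        sites, hits = self.track_setup(rng)
        sq = self.variants(rng, sites, hits, 0.02)
        sn = self.variants(rng, sites, hits, 0.02)
        track = sqtl_adjusted_enrichment(hits, sq, sn, sites)
        ok = ~np.isnan(track.adjusted)
        assert np.nanmean(track.adjusted) == pytest.approx(1.0, abs=0.25)

    def test_scale_invariance_under_doubling(self, rng):
        sites, hits = self.track_setup(rng)
        sq = self.variants(rng, sites, hits, 0.02, uplift=2.0)
        sn = self.variants(rng, sites, hits, 0.02)
        t1 = sqtl_adjusted_enrichment(hits, sq, sn, sites)
        t2 = sqtl_adjusted_enrichment(hits, sq + sq, sn + sn, sites)
        np.testing.assert_allclose(t1.adjusted, t2.adjusted, equal_nan=True)

    def test_bin_without_g4_bp_reports_nan(self):
        sites = [SpliceSite("s", DONOR, "c", 2000, "+")]
        hits = [motif("c", 2100, 2120)]  # G4 bp only in one bin region
        sq = [Interval("c", 2110, 2111)]
        sn = [Interval("c", 2110, 2111)]
        track = sqtl_adjusted_enrichment(hits, sq, sn, sites)
        assert np.isnan(track.adjusted).sum() > 0
        assert track.g4_bp.sum() == 20

    def test_uneven_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            sqtl_adjusted_enrichment([], [], [], [], L=500, w=33)
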