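import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polycage.clustering import TagCluster
from polycage.enhancers import (
    EnhancerCall,
    balance_score,
    classify_intergenic_intronic_ernas,
    detect_bidirectional_candidates,
    link_enhancers_to_tss,
)


def divergent_frame(minus_pos, plus_pos, minus_val=100.0, plus_val=100.0):
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [minus_pos, plus_pos],
            "strand": ["-", "+"],
            "value": [minus_val, plus_val],
        }
    )


class TestBalanceScore:
    def test_equal_arms_perfectly_balanced(self):
        assert balance_score(100, 100) == pytest.approx(1.0)

    def test_one_sided_limit(self):
        assert balance_score(1, 0) == pytest.approx(math.sqrt(0.5))

    def test_eighty_twenty_split_below_call_threshold(self):
        score = balance_score(0.8, 0.2)
        assert score == pytest.approx(math.sqrt(0.4) + math.sqrt(0.1))
        assert score < 0.95

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            balance_score(0, 0)

    @given(d=st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_unique_maximum(self, d):
        score = balance_score(d, 1 - d)
        assert math.sqrt(0.5) <= score <= 1.0 + 1e-12
        if abs(d - 0.5) > 1e-3:
            assert score < 1.0


class TestCandidateDetection:
    def test_divergent_pair_gives_one_candidate(self):
        calls = detect_bidirectional_candidates(divergent_frame(1000, 1180))
        assert len(calls) == 1
        assert calls[0].called  # equal arms: balance 1.0

    def test_convergent_pair_rejected(self):
        # plus upstream, minus downstream: transcription points inward
        frame = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [1000, 1180],
                "strand": ["+", "-"],
                "value": [100.0, 100.0],
            }
        )
        assert detect_bidirectional_candidates(frame) == []

    def test_single_strand_signal_rejected(self):
        frame = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1000], "strand": ["+"], "value": [100.0]}
        )
        assert detect_bidirectional_candidates(frame) == []

    def test_unbalanced_candidate_detected_but_not_called(self):
        calls = detect_bidirectional_candidates(
            divergent_frame(1000, 1180, minus_val=80.0, plus_val=20.0)
        )
        assert len(calls) == 1
        assert not calls[0].called


def _make_enhancer(midpoint, tpm):
    e = EnhancerCall("E0", "chr1", midpoint, midpoint - 200, midpoint + 200,
                     50.0, 50.0, 1.0, True)
    e.tpm = tpm
    return e


def _make_cluster(peak, tpm):
    cl = TagCluster("TC0", "chr1", "+", peak, peak + 1, peak, 10.0, peak, peak, 1,
                    "sharp")
    cl.tpm = tpm
    return cl


class TestLinking:
    SAMPLES = [f"s{i}" for i in range(8)]

    def _latent_pair(self, noise=0.05, anti=False):
        rng = np.random.default_rng(3)
        latent = rng.lognormal(0.0, 1.0, size=8)
        e_expr = latent * rng.lognormal(0.0, noise, size=8)
        c_expr = (1.0 / latent if anti else latent) * rng.lognormal(0.0, noise, size=8)
        enh = _make_enhancer(10_000, dict(zip(self.SAMPLES, 100 * e_expr)))
        cl = _make_cluster(15_000, dict(zip(self.SAMPLES, 100 * c_expr)))
        return enh, cl

    def test_shared_latent_activity_is_linked(self):
        enh, cl = self._latent_pair()
        (link,) = link_enhancers_to_tss([enh], [cl], self.SAMPLES)
        assert link.distance == 5000
        # r must match the textbook formula on the transformed values
        x = np.log2(np.array([enh.tpm[s] for s in self.SAMPLES]) + 1)
        y = np.log2(np.array([cl.tpm[s] for s in self.SAMPLES]) + 1)
        r_manual = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert link.pearson_r == pytest.approx(r_manual, abs=1e-12)

    def test_distance_bound_is_strict(self):
        enh, cl = self._latent_pair()
        cl.peak = enh.midpoint + 50_001
        assert link_enhancers_to_tss([enh], [cl], self.SAMPLES) == []

    def test_anticorrelated_pair_not_linked(self):
        enh, cl = self._latent_pair(anti=True)
        assert link_enhancers_to_tss([enh], [cl], self.SAMPLES) == []

    def test_fewer_than_three_samples_errors(self):
        enh, cl = self._latent_pair()
        with pytest.raises(ValueError, match="3 samples"):
            link_enhancers_to_tss([enh], [cl], self.SAMPLES[:2])

    def test_relaxing_alpha_only_adds_links(self):
        rng = np.random.default_rng(11)
        enhancers, clusters = [], []
        for i in range(6):
            latent = rng.lognormal(0.0, 0.5, size=8) * rng.lognormal(0, 0.4, size=8)
            e = _make_enhancer(1000 + 500 * i, dict(zip(self.SAMPLES, 50 * latent)))
            e.enhancer_id = f"E{i}"
            c = _make_cluster(
                2000 + 500 * i,
                dict(zip(self.SAMPLES, 50 * latent * rng.lognormal(0, 0.6, size=8))),
            )
            c.cluster_id = f"TC{i}"
            enhancers.append(e)
            clusters.append(c)
        strict = link_enhancers_to_tss(enhancers, clusters, self.SAMPLES, alpha=0.05)
        loose = link_enhancers_to_tss(enhancers, clusters, self.SAMPLES, alpha=1.0)
        strict_keys = {(l.enhancer_id, l.cluster_id) for l in strict}
        loose_keys = {(l.enhancer_id, l.cluster_id) for l in loose}
        assert strict_keys <= loose_keys


class TestErnaFractions:
    def test_no_enhancers_gives_zero(self):
        cl = _make_cluster(100, {})
        calls = pd.DataFrame({"cluster_id": ["TC0"], "category": ["intron"]})
        out = classify_intergenic_intronic_ernas(calls, [], [cl])
        assert out == {"intron": 0.0, "intergenic": 0.0}

    def test_all_intronic_clusters_inside_windows(self):
        clusters = [_make_cluster(100, {}), _make_cluster(150, {})]
        clusters[1].cluster_id = "TC1"
        enh = _make_enhancer(120, {})
        calls = pd.DataFrame(
            {"cluster_id": ["TC0", "TC1"], "category": ["intron", "intron"]}
        )
        out = classify_intergenic_intronic_ernas(calls, [enh], clusters)
        assert out["intron"] == pytest.approx(1.0)

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(5)
        clusters, rows, enhancers = [], [], []
        for i in range(100):
            peak = 1000 * i + 500
            cl = _make_cluster(peak, {})
            cl.cluster_id = f"TC{i}"
            clusters.append(cl)
            rows.append({"cluster_id": f"TC{i}", "category": "intron"})
            if i < 70:  # planted eRNA fraction 0.70
                e = _make_enhancer(peak, {})
                e.enhancer_id = f"E{i}"
                enhancers.append(e)
        out = classify_intergenic_intronic_ernas(
            pd.DataFrame(rows), enhancers, clusters
        )
        assert out["intron"] == pytest.approx(0.70)
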