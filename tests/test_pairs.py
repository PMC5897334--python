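"""Pair-level combined statistic: transforms, Spearman tail, scan, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexpair import (
    P_FLOOR,
    StoufferWeights,
    load_reference_pairs,
    p_from_z,
    pair_scan,
    pair_scan_from_stats,
    pairs_to_frame,
    select_pairs,
    spearman_cc,
    spearman_p,
    stouffer_pair_z,
    z_from_p,
)
from coexpair.synthetic import SyntheticConfig, generate_paired
from coexpair.matrix import filter_missing, impute_feature_mean
from conftest import inv_norm_upper, make_matrix, paired_metadata, spearman_oracle


class TestZTransforms:
    def test_median_maps_to_zero(self):
        assert z_from_p(0.5) == pytest.approx(0.0, abs=1e-12)
        assert p_from_z(0.0) == pytest.approx(0.5)

    def test_extreme_p_matches_bisection_oracle(self):
        # 1.18e-5 is the smallest tail probability on the reference panel's
        # most-correlated pair; the oracle inverts erfc by bisection
        assert z_from_p(1.18e-5) == pytest.approx(inv_norm_upper(1.18e-5), abs=1e-9)
        assert z_from_p(1.18e-5) == pytest.approx(4.2278, abs=5e-4)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(p=st.floats(1e-12, 0.999))
    def test_round_trip_identity(self, p):
        assert p_from_z(z_from_p(p)) == pytest.approx(p, rel=1e-10)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(p=st.floats(1e-6, 1 - 1e-6))
    def test_antisymmetry(self, p):
        assert z_from_p(p) == pytest.approx(-z_from_p(1 - p), abs=1e-7)

    def test_far_tail_is_finite_and_accurate(self):
        z = z_from_p(1e-300)
        assert np.isfinite(z)
        assert p_from_z(z) == pytest.approx(1e-300, rel=1e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3, float("nan")])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            z_from_p(bad)


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert spearman_cc(x, x) == pytest.approx(1.0)
        assert spearman_cc(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # exercise tie handling
                x = np.round(x, 1)
            assert spearman_cc(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_cc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_null_correlation_gives_half(self):
        assert spearman_p(0.0, 22) == pytest.approx(0.5)
        assert spearman_p(0.0, 8) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "cc,printed",
        [(0.774, 1.18e-5), (-0.812, 2.27e-6)],
        ids=["positive-pair", "negative-pair"],
    )
    def test_reference_panel_tail_probabilities(self, cc, printed):
        """One-sided-on-|cc| t-approximation reproduces the published tail
        probabilities (the published cc is itself rounded to 3 digits, so the
        published p must lie inside the p-interval of the rounding band)."""
        p = spearman_p(cc, 22)
        assert p == pytest.approx(printed, rel=0.025)
        band = [spearman_p(abs(cc) + d, 22) for d in (-5e-4, 5e-4)]
        assert min(band) <= printed <= max(band)

    def test_one_sided_is_half_two_sided(self):
        cc, n = 0.6, 15
        t = abs(cc) * np.sqrt((n - 2) / (1 - cc**2))
        assert spearman_p(cc, n) == pytest.approx(stats.t.sf(t, n - 2))
        assert spearman_p(-cc, n) == pytest.approx(spearman_p(cc, n))

    def test_perfect_correlation_floors(self):
        assert spearman_p(1.0, 22) == P_FLOOR
        assert spearman_p(-1.0, 22) == P_FLOOR

    def test_exact_permutation_tail_small_n(self):
        # n = 4: 24 permutations; rho >= 1 only for the identity -> 1/24
        assert spearman_p(1.0, 4, method="exact") == pytest.approx(1 / 24)
        # rho >= 0.8: identity (rho=1) plus 3 single-swap arrangements (rho=0.8)
        assert spearman_p(0.8, 4, method="exact") == pytest.approx(4 / 24)

    def test_exact_agrees_with_t_roughly_at_n8(self):
        p_exact = spearman_p(0.7, 8, method="exact")
        p_t = spearman_p(0.7, 8)
        assert p_exact == pytest.approx(p_t, rel=0.5)


class TestStoufferPairZ:
    def test_all_median_components_give_zero(self):
        assert stouffer_pair_z(0.5, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert stouffer_pair_z(0.5, 0.5, 0.5, StoufferWeights(2.0, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_de_components(self, rng):
        for _ in range(10):
            p1, p2, pc = rng.uniform(1e-6, 1 - 1e-6, size=3)
            assert stouffer_pair_z(p1, p2, pc) == pytest.approx(stouffer_pair_z(p2, p1, pc), abs=1e-13)

    def test_denominator_contract(self):
        w = StoufferWeights()
        assert w.denominator == pytest.approx(np.sqrt(1.5))
        assert StoufferWeights(0.3, 0.7).denominator == pytest.approx(np.sqrt(2 * 0.09 + 0.49))

    def test_reference_panel_first_row(self):
        z = stouffer_pair_z(0.361, 0.0467, 1.18e-5)
        assert z == pytest.approx(4.28, abs=0.005)
        assert p_from_z(4.284) == pytest.approx(9.2e-6, rel=0.01)

    def test_error_names_offending_component(self):
        with pytest.raises(ValueError, match="p_cc"):
            stouffer_pair_z(0.5, 0.5, 1.0)
        with pytest.raises(ValueError, match="p_de2"):
            stouffer_pair_z(0.5, 0.0, 0.5)

    def test_p_z_strictly_decreasing_in_z(self):
        zs = np.linspace(-3, 6, 50)
        ps = [p_from_z(z) for z in zs]
        assert np.all(np.diff(ps) < 0)


class TestPairScan:
    def _complete(self, seed=0, n_features=10):
        cfg = SyntheticConfig(seed=seed, n_features=n_features, missing_rate=0.0,
                              modules=())
        m, meta, _ = generate_paired(cfg)
        return m, meta

    def test_pair_count_is_choose_two(self):
        m, meta = self._complete(n_features=5)
        scan = pair_scan(m, meta)
        assert len(scan) == 10

    def test_min_p_de_and_symmetry_and_order(self):
        m, meta = self._complete(n_features=6)
        scan = pair_scan(m, meta)
        for s in scan:
            assert s.min_p_de == min(s.p_de1, s.p_de2)
            assert s.mirna1 < s.mirna2
        ids = [(s.mirna1, s.mirna2) for s in scan]
        assert ids == sorted(ids)

    def test_duplicate_feature_probe_flags_perfect_correlation(self):
        m, meta = self._complete(n_features=4)
        values = np.vstack([m.values, m.values[0]])
        dup = make_matrix(values, features=list(m.features) + ["zz-dup"],
                          samples=list(m.samples))
        scan = pair_scan(dup, meta)
        probe = [s for s in scan if {s.mirna1, s.mirna2} == {m.features[0], "zz-dup"}][0]
        assert probe.cc == pytest.approx(1.0)
        assert "perfect_correlation" in probe.flags

    def test_de_p_computed_once_per_feature(self):
        m, meta = self._complete(n_features=6)
        scan = pair_scan(m, meta)
        by_feature = {}
        for s in scan:
            for f, p in ((s.mirna1, s.p_de1), (s.mirna2, s.p_de2)):
                by_feature.setdefault(f, set()).add(p)
        assert all(len(v) == 1 for v in by_feature.values())

    def test_fewer_than_two_features_rejected(self):
        m, meta = self._complete(n_features=5)
        single = m.subset_features([True, False, False, False, False])
        with pytest.raises(ValueError, match=">= 2 features"):
            pair_scan(single, meta)

    def test_scan_matches_scalar_path(self):
        """Vectorized scan equals the scalar stouffer_pair_z/spearman route."""
        m, meta = self._complete(n_features=7)
        scan = pair_scan(m, meta)
        idx = {f: i for i, f in enumerate(m.features)}
        for s in scan[:15]:
            cc = spearman_cc(m.values[idx[s.mirna1]], m.values[idx[s.mirna2]])
            assert s.cc == pytest.approx(cc, abs=1e-12)
            assert s.p_cc == pytest.approx(spearman_p(cc, m.n_samples), rel=1e-12)
            assert s.z == pytest.approx(stouffer_pair_z(s.p_de1, s.p_de2, s.p_cc), abs=1e-10)


class TestFromStatsAndSelection:
    def test_reference_panel_z_and_p_reproduced(self):
        ref = load_reference_pairs()
        scored = pair_scan_from_stats(ref)
        for s, (_, row) in zip(scored, ref.iterrows()):
            assert s.z == pytest.approx(row.published_z, abs=0.01)
            assert s.p_z == pytest.approx(row.published_p_z, rel=0.02)

    def test_selection_rule_conjunction(self):
        ref = load_reference_pairs()
        scored = pair_scan_from_stats(ref)
        # all 15 published pairs pass the joint rule within their own universe
        assert len(select_pairs(scored)) == len(scored)
        # strong combined evidence without any DE support is rejected
        weak_de = pair_scan_from_stats(pd.DataFrame(
            {"p_de1": [0.9, 0.02], "p_de2": [0.9, 0.03], "p_cc": [1e-9, 1e-9]}))
        kept = select_pairs(weak_de, fdr_threshold=0.5)
        assert len(kept) == 1 and kept[0].p_de1 == 0.02

    def test_selection_monotone_in_fdr_threshold(self):
        ref = load_reference_pairs()
        scored = pair_scan_from_stats(ref)
        tight = {(s.mirna1, s.mirna2) for s in select_pairs(scored, fdr_threshold=1e-3)}
        loose = {(s.mirna1, s.mirna2) for s in select_pairs(scored, fdr_threshold=1e-2)}
        assert tight <= loose

    def test_selection_sorted_by_combined_p(self):
        scored = pair_scan_from_stats(load_reference_pairs())
        sel = select_pairs(scored)
        ps = [s.p_z for s in sel]
        assert ps == sorted(ps)

    def test_output_frame_column_order(self):
        frame = pairs_to_frame(pair_scan_from_stats(load_reference_pairs()))
        assert list(frame.columns) == [
            "miRNA", "miRNA2", "P_DE(miRNA1)", "P_DE(miRNA2)", "CC", "P_CC",
            "Min_ttest_pval", "Stouffer_Zscore", "pval_Zscore", "FDR_Zscore",
        ]

    def test_fdr_ordering_consistent_with_p(self):
        scored = pair_scan_from_stats(load_reference_pairs())
        by_p = sorted(scored, key=lambda s: s.p_z)
        fdrs = [s.fdr_z for s in by_p]
        assert all(a <= b + 1e-15 for a, b in zip(fdrs, fdrs[1:]))
        assert all(s.fdr_z >= s.p_z for s in scored)
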