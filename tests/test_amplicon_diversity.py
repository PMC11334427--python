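import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from markerlens import amplicon_diversity as div
from markerlens import synthetic_data as sd
from markerlens.core_io import CountMatrix, parse_taxonomy


class TestFilterMinCounts:
    def test_sample_boundary_exclusive(self):
        counts = np.array([[99, 0], [100, 0], [150, 110]])
        m = CountMatrix(["s1", "s2", "s3"], ["a1", "a2"], counts)
        res = div.filter_min_counts(m, 100)
        assert res.dropped_samples == ["s1"]
        assert res.table.sample_ids == ["s2", "s3"]

    def test_low_count_asv_dropped_after_samples(self):
        counts = np.array([[120, 1], [130, 2]])
        m = CountMatrix(["s1", "s2"], ["a1", "a2"], counts)
        res = div.filter_min_counts(m, 100)
        assert res.dropped_asvs == ["a2"]
        assert res.table.asv_ids == ["a1"]

    def test_all_zero_asv_dropped(self, small_table):
        res = div.filter_min_counts(small_table, 100)
        assert "a3" in res.dropped_asvs

    def test_all_samples_dropped_errors(self):
        m = CountMatrix(["s1"], ["a1"], np.array([[5]]))
        with pytest.raises(ValueError, match="below the count threshold"):
            div.filter_min_counts(m, 100)

    def test_idempotent(self, rng):
        counts = rng.integers(0, 80, size=(12, 15))
        m = CountMatrix(
            [f"s{i}" for i in range(12)], [f"a{j}" for j in range(15)], counts
        )
        try:
            once = div.filter_min_counts(m, 100).table
        except ValueError:
            return
        twice = div.filter_min_counts(once, 100).table
        assert once == twice


class TestRarefy:
    def test_rows_sum_to_depth(self, rng):
        counts = rng.integers(0, 200, size=(6, 10)) + 1
        m = CountMatrix([f"s{i}" for i in range(6)], [f"a{j}" for j in range(10)], counts)
        r = div.rarefy(m, seed=5)
        assert (r.sample_sums() == m.sample_sums().min()).all()

    def test_depth_equal_to_sum_is_identity(self):
        m = CountMatrix(["s1"], ["a1", "a2"], np.array([[7, 3]]))
        r = div.rarefy(m, depth=10, seed=0)
        assert np.array_equal(r.counts, m.counts)

    def test_depth_above_sum_rejected(self):
        m = CountMatrix(["s1"], ["a1"], np.array([[5]]))
        with pytest.raises(ValueError, match="exceeds"):
            div.rarefy(m, depth=6)

    def test_deterministic_given_seed(self, rng):
        counts = rng.integers(0, 100, size=(4, 8)) + 1
        m = CountMatrix([f"s{i}" for i in range(4)], [f"a{j}" for j in range(8)], counts)
        a = div.rarefy(m, depth=50, seed=11)
        b = div.rarefy(m, depth=50, seed=11)
        assert a == b

    def test_hypergeometric_mean(self):
        # expected rarefied count of ASV j is depth * c_j / total
        row = np.array([[40, 30, 20, 10]])
        m = CountMatrix(["s1"], ["a", "b", "c", "d"], row)
        depth = 50
        draws = np.array(
            [div.rarefy(m, depth=depth, seed=s).counts[0] for s in range(500)],
            dtype=float,
        )
        expected = depth * row[0] / row.sum()
        # hypergeometric variance, 3 SE over 500 draws
        total = row.sum()
        var = (
            depth
            * (row[0] / total)
            * (1 - row[0] / total)
            * (total - depth)
            / (total - 1)
        )
        se = np.sqrt(var / 500)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se).all()


class TestShannon:
    def test_uniform_four(self):
        assert div.shannon([10, 10, 10, 10]) == pytest.approx(np.log(4), abs=1e-10)

    def test_single_taxon_zero(self):
        assert div.shannon([5, 0, 0]) == 0.0

    def test_hand_computed(self):
        assert div.shannon([1, 1, 2]) == pytest.approx(1.03972, abs=1e-5)

    def test_all_zero_is_zero(self):
        assert div.shannon([0, 0, 0]) == 0.0

    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=30)
    )
    def test_bounded_by_log_richness(self, counts):
        h = div.shannon(counts)
        richness = sum(1 for c in counts if c > 0)
        assert 0.0 <= h <= np.log(max(richness, 1)) + 1e-12


class TestSubsetShannon:
    def test_whole_table_subset_equals_full(self, small_table):
        h_family = div.subset_shannon(small_table, "class", "Clostridia")
        full = div.shannon_per_sample(small_table.matrix)
        pd.testing.assert_series_equal(h_family, full, check_names=False)

    def test_zero_subset_sample_gets_zero(self):
        counts = np.array([[10, 0], [5, 8]])
        tax = {
            "a1": parse_taxonomy("d__B;p__P;c__C;o__O;f__F1;g__G1;s__"),
            "a2": parse_taxonomy("d__B;p__P;c__C;o__O;f__F2;g__G2;s__"),
        }
        table = div.ASVTable(CountMatrix(["s1", "s2"], ["a1", "a2"], counts), tax)
        h = div.subset_shannon(table, "family", "F2")
        assert h["s1"] == 0.0

    def test_absent_name_errors(self, small_table):
        with pytest.raises(ValueError, match="Nope"):
            div.subset_shannon(small_table, "genus", "Nope")


class TestGreedyCluster:
    def test_distinct_sequences_identity_partition_at_1(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTAG", "c": "TTTTACGTAC"}
        ab = {"a": 10, "b": 5, "c": 1}
        clusters = div.greedy_cluster(seqs, ab, 1.0)
        assert len(clusters.centroids) == 3

    def test_one_mismatch_in_100mers_merges_at_097(self):
        a = "ACGT" * 25
        b = a[:-1] + "A"
        clusters = div.greedy_cluster({"a": a, "b": b}, {"a": 2, "b": 1}, 0.97)
        assert clusters.assignment == {"a": "a", "b": "a"}

    def test_same_pair_separate_at_1(self):
        a = "ACGT" * 25
        b = a[:-1] + "A"
        clusters = div.greedy_cluster({"a": a, "b": b}, {"a": 2, "b": 1}, 1.0)
        assert len(clusters.centroids) == 2

    def test_abundance_order_defines_centroids(self):
        a = "ACGT" * 25
        b = a[:-1] + "A"
        clusters = div.greedy_cluster({"a": a, "b": b}, {"a": 1, "b": 2}, 0.97)
        assert clusters.centroids == ["b"]

    def test_cluster_count_monotone_in_threshold(self, rng):
        base = sd.random_sequence(120, rng)
        seqs = {
            f"v{i}": sd.evolve_k80(base, rng.uniform(0, 0.2), 2.0, rng)
            for i in range(12)
        }
        ab = {k: 1 for k in seqs}
        n_clusters = [
            len(div.greedy_cluster(seqs, ab, t).centroids)
            for t in (1.0, 0.97, 0.90, 0.85)
        ]
        assert all(b <= a for a, b in zip(n_clusters, n_clusters[1:]))

    def test_empty_input(self):
        clusters = div.greedy_cluster({}, {}, 0.97)
        assert clusters.assignment == {} and clusters.centroids == []


class TestFitHurdle:
    def _cohort(self, a1, b1, n=2000, seed=0, a0=None, b0=None, **kw):
        spec = sd.CohortSpec(
            n_samples=n,
            a0=(-a1 * 29.0 if a0 is None else a0),
            a1=a1,
            b0=(0.5 - b1 * 29.0 if b0 is None else b0),
            b1=b1,
            city_effects={"CityB": (0.3, 0.1)},
            seed=seed,
            **kw,
        )
        return sd.simulate_diversity_cohort(spec)

    def test_bin_recovery_single_cohort(self):
        meta, h = self._cohort(a1=-0.165, b1=0.0, seed=42)
        fit_bin, _ = div.fit_hurdle(h, meta)
        assert fit_bin.converged
        assert abs(fit_bin.beta_bmi - (-0.165)) < 3 * fit_bin.se

    def test_cont_recovery_single_cohort(self):
        meta, h = self._cohort(a1=0.0, b1=-0.017, a0=10.0, seed=43)
        _, fit_cont = div.fit_hurdle(h, meta)
        assert fit_cont.converged
        assert fit_cont.n_obs == len(meta)  # a0=+10: no zeros
        assert abs(fit_cont.beta_bmi - (-0.017)) < 3 * fit_cont.se

    def test_all_positive_flags_bin(self):
        meta, h = self._cohort(a1=0.0, b1=0.0, a0=15.0, n=200, seed=44)
        fit_bin, fit_cont = div.fit_hurdle(h, meta)
        assert not fit_bin.converged and fit_bin.p is None
        assert fit_cont.converged

    def test_all_zero_flags_both(self):
        meta, h = self._cohort(a1=0.0, b1=0.0, a0=-15.0, n=200, seed=45)
        fit_bin, fit_cont = div.fit_hurdle(h, meta)
        assert fit_bin.p is None and fit_cont.p is None

    def test_too_few_samples_rejected(self):
        meta, h = self._cohort(a1=0.0, b1=0.0, n=5, seed=46)
        with pytest.raises(ValueError, match="at least 10"):
            div.fit_hurdle(h, meta)

    def test_null_bmi_centered_on_zero(self):
        betas = []
        for seed in range(30):
            meta, h = self._cohort(a1=0.0, b1=0.0, a0=0.5, b0=0.5, n=400, seed=seed)
            fit_bin, _ = div.fit_hurdle(h, meta)
            betas.append(fit_bin.beta_bmi)
        betas = np.array(betas)
        assert abs(betas.mean()) < 2 * betas.std(ddof=1) / np.sqrt(len(betas))


class TestAdjustFdr:
    def test_worked_example(self):
        out = div.adjust_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert div.adjust_fdr([0.2]) == pytest.approx([0.2])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        out = div.adjust_fdr(p)
        assert (out >= p - 1e-15).all() and (out <= 1.0).all()

    def test_brute_force_oracle_random_vectors(self, rng):
        def bh_oracle(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = np.inf
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                running = min(running, p[i] * m / rank_from_top)
                adj[i] = min(running, 1.0)
            return adj

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(div.adjust_fdr(p), bh_oracle(p))

    def test_grouped_adjustment_is_within_group(self, rng):
        p = rng.uniform(size=20)
        groups = np.array(["g1"] * 10 + ["g2"] * 10)
        out = div.adjust_fdr(p, groups)
        assert np.allclose(out[:10], div.adjust_fdr(p[:10]))
        assert np.allclose(out[10:], div.adjust_fdr(p[10:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            div.adjust_fdr([0.5, 1.2])


def _cohort_table(seed=7, n_samples=40, n_asvs=24):
    sim = sd.simulate_count_cohort(n_samples, n_asvs, seed=seed)
    table = div.ASVTable(
        sim.table,
        dict(sim.taxonomy),
        {a: sd.random_sequence(120, np.random.default_rng(seed + i))
         for i, a in enumerate(sim.table.asv_ids)},
    )
    return table, sim.metadata


class TestAnalyzeAndSensitivity:
    TAXA = [("family", "Oscillospiraceae"), ("genus", "Genus0")]

    def test_analyze_produces_one_row_per_taxon_and_model(self):
        table, meta = _cohort_table()
        frame = div.analyze_diversity(table, meta, self.TAXA, seed=3)
        assert len(frame) == 4
        assert set(frame["model"]) == {"glm.bin", "glm.cont"}
        testable = frame["p"].notna()
        assert (frame.loc[testable, "fdr"] >= frame.loc[testable, "p"] - 1e-15).all()

    def test_threshold_one_reproduces_unclustered(self):
        table, meta = _cohort_table()
        direct = div.analyze_diversity(table, meta, self.TAXA, seed=3)
        suite = div.sensitivity_suite(
            table, meta, self.TAXA, thresholds=[1.0], seed=3
        )
        pd.testing.assert_frame_equal(direct, suite[1.0])

    def test_full_merge_degenerates_cont_model(self):
        # all ASVs of the genus share one sequence cluster at a loose threshold
        table, meta = _cohort_table()
        base = sd.random_sequence(120, np.random.default_rng(0))
        seqs = {}
        for i, a in enumerate(table.matrix.asv_ids):
            tax = table.taxonomy[a]
            if tax.name_at("genus") == "Genus0":
                seqs[a] = sd.evolve_k80(base, 0.01, 2.0, np.random.default_rng(i))
            else:
                seqs[a] = sd.random_sequence(120, np.random.default_rng(1000 + i))
        table = div.ASVTable(table.matrix, table.taxonomy, seqs)
        suite = div.sensitivity_suite(
            table, meta, [("genus", "Genus0")], thresholds=[0.85], seed=3
        )
        frame = suite[0.85]
        cont = frame[frame["model"] == "glm.cont"].iloc[0]
        assert not cont["converged"]
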