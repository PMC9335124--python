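import numpy as np
import pytest
from scipy import stats

from pepbinder.enrichment import (
    CountMatrix,
    SampleMeta,
    build_count_matrix,
    call_enriched,
    cluster_hits,
    normalize_ppm,
    welch_t_one_tailed,
)


def _meta(spec):
    """spec: list of (condition, n_replicates)."""
    out = []
    for cond, n in spec:
        for r in range(1, n + 1):
            out.append(SampleMeta(f"{cond}_{r}", cond, r))
    return out


def _cm(peptide_rows: dict, meta):
    peps = list(peptide_rows)
    counts = np.array([peptide_rows[p] for p in peps])
    return CountMatrix(peptides=peps, samples=meta, counts=counts)


class TestBuildCountMatrix:
    def test_multiplicity_counting(self):
        meta = [SampleMeta("s1", "R0", 1), SampleMeta("s2", "R0", 2)]
        cm = build_count_matrix({"s1": ["PEPTIDEA", "PEPTIDEA", "PEPTIDEQ"], "s2": ["PEPTIDEQ"]}, meta)
        assert cm.peptides == ["PEPTIDEA", "PEPTIDEQ"]
        assert cm.counts.tolist() == [[2, 0], [1, 1]]

    def test_empty_sample_zero_column(self):
        meta = [SampleMeta("s1", "R0", 1), SampleMeta("s2", "R0", 2)]
        cm = build_count_matrix({"s1": ["PEPTIDEA"]}, meta)
        assert cm.counts[:, 1].sum() == 0

    def test_duplicate_sample_id_error(self):
        meta = [SampleMeta("s1", "R0", 1), SampleMeta("s1", "R1", 1)]
        with pytest.raises(ValueError):
            build_count_matrix({"s1": ["PEPTIDEA"]}, meta)

    def test_unknown_sample_id_error(self):
        with pytest.raises(ValueError):
            build_count_matrix({"sX": ["PEPTIDEA"]}, [SampleMeta("s1", "R0", 1)])


class TestNormalizePPM:
    def test_simple_column(self):
        cm = _cm({"A": [2], "B": [1], "C": [1]}, _meta([("R0", 1)]))
        assert normalize_ppm(cm)[:, 0].tolist() == [500000.0, 250000.0, 250000.0]

    def test_all_equal_column(self):
        cm = _cm({p: [5] for p in "ABCD"}, _meta([("R0", 1)]))
        assert np.allclose(normalize_ppm(cm), 250000.0)

    def test_zero_column_error(self):
        cm = _cm({"A": [1, 0], "B": [1, 0]}, _meta([("R0", 2)]))
        with pytest.raises(ValueError, match="R0_2"):
            normalize_ppm(cm)

    def test_columns_sum_to_1e6(self, rng):
        counts = rng.integers(0, 100, size=(50, 4)) + 1
        cm = CountMatrix([f"P{i}" for i in range(50)], _meta([("R0", 2), ("R1", 2)]), counts)
        assert np.allclose(normalize_ppm(cm).sum(axis=0), 1e6, rtol=1e-9)


class TestWelch:
    def test_identical_groups_symmetric(self):
        t, p = welch_t_one_tailed([5, 5, 5], [5, 5, 5])
        assert t == 0.0 and p == 0.5

    def test_matches_scipy_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(1, 1, size=rng.integers(2, 8))
            b = rng.normal(0, 2, size=rng.integers(2, 8))
            t, p = welch_t_one_tailed(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert np.isclose(t, ref.statistic) and np.isclose(p, ref.pvalue)

    def test_one_tailed_swap_symmetry(self):
        a, b = [10.0, 11, 12], [1.0, 2, 3]
        t1, p1 = welch_t_one_tailed(a, b)
        t2, p2 = welch_t_one_tailed(b, a)
        assert np.isclose(t2, -t1) and np.isclose(p2, 1 - p1)

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError):
            welch_t_one_tailed([1], [1, 2])

    def test_degenerate_unequal_means(self):
        t, p = welch_t_one_tailed([5, 5], [1, 1])
        assert t == np.inf and p == 0.0


LAYOUT = [("R0", 3), ("R1", 3), ("R2_target", 6), ("R2_beads", 3), ("R2_unrelated", 3)]


def _layout_cm(target_counts, control_counts, background=1000):
    """2-peptide matrix: a candidate row plus a large background row so
    column totals are stable."""
    row = list(control_counts[:3]) + list(control_counts[3:6]) + list(target_counts)
    row += list(control_counts[6:9]) + list(control_counts[9:12])
    meta = _meta(LAYOUT)
    # reorder: meta order is R0, R1, R2_target, R2_beads, R2_unrelated
    cand = np.array(row)
    bg = np.full(len(meta), background)
    return CountMatrix(["CANDIDATE", "BACKGROUND"], meta, np.vstack([cand, bg]))


class TestCallEnriched:
    def test_strong_enrichment_is_hit(self):
        cm = _layout_cm([100] * 6, [1] * 12)
        res = {r.peptide: r for r in call_enriched(cm)}
        assert res["CANDIDATE"].is_hit
        assert all(v >= 2 for v in res["CANDIDATE"].ratio_per_control.values())
        assert all(v <= 0.05 for v in res["CANDIDATE"].p_per_control.values())

    def test_flat_abundance_not_hit(self):
        cm = _layout_cm([5] * 6, [5] * 12)
        res = {r.peptide: r for r in call_enriched(cm)}
        assert not res["CANDIDATE"].is_hit
        assert np.allclose(list(res["CANDIDATE"].ratio_per_control.values()), 1.0)

    def test_high_variance_blocks_hit(self):
        # one dominant target replicate: ratio > 2 but Welch p large
        cm = _layout_cm([600, 0, 0, 0, 0, 0], [10] * 12)
        res = {r.peptide: r for r in call_enriched(cm)}
        cand = res["CANDIDATE"]
        assert min(cand.ratio_per_control.values()) >= 2
        assert max(cand.p_per_control.values()) > 0.05
        assert not cand.is_hit

    def test_scaling_invariance(self, rng):
        counts = rng.integers(1, 50, size=(30, 18))
        meta = _meta(LAYOUT)
        cm1 = CountMatrix([f"P{i}" for i in range(30)], meta, counts)
        scaled = counts.copy()
        scaled[:, 0] *= 7  # uniform scaling of one sample
        cm2 = CountMatrix([f"P{i}" for i in range(30)], meta, scaled)
        r1 = call_enriched(cm1)
        r2 = call_enriched(cm2)
        assert [r.is_hit for r in r1] == [r.is_hit for r in r2]
        for a, b in zip(r1, r2):
            assert np.allclose(list(a.ratio_per_control.values()),
                               list(b.ratio_per_control.values()))

    def test_missing_condition_error(self):
        cm = _cm({"PEPTIDEA": [1, 1]}, _meta([("R0", 2)]))
        with pytest.raises(ValueError):
            call_enriched(cm, target="R2_target", controls=("R0",))

    def test_pooled_mode_runs(self):
        cm = _layout_cm([100] * 6, [1] * 12)
        res = {r.peptide: r for r in call_enriched(cm, control_mode="pooled")}
        assert res["CANDIDATE"].is_hit


class TestClusterHits:
    def test_identical_peptides_share_cluster(self):
        hits = ["WWWWYYYY", "WWWWYYYY", "DDDDEEEE", "KKKKRRRR"]
        labels = cluster_hits(hits, n_clusters=2)
        assert labels["WWWWYYYY"] == labels["WWWWYYYY"]

    def test_n_clusters_equals_n(self):
        hits = ["WWWWYYYY", "DDDDEEEE", "KKKKRRRR"]
        labels = cluster_hits(hits, n_clusters=3)
        assert len(set(labels.values())) == 3

    def test_two_motifs_split_perfectly(self):
        a = ["WWWWYYYYFFFF", "WWWWYYYYFFFW", "WWWWYYYWFFFF"]
        b = ["DDDDEEEEKKKK", "DDDDEEEEKKKR", "DDDDEEEDKKKK"]
        labels = cluster_hits(a + b, n_clusters=2)
        assert len({labels[p] for p in a}) == 1
        assert len({labels[p] for p in b}) == 1
        assert labels[a[0]] != labels[b[0]]

    def test_mixed_lengths_error(self):
        with pytest.raises(ValueError):
            cluster_hits(["WWWW", "WWWWW"], n_clusters=1)
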