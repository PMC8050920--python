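import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chromsig import differential as diff
from chromsig import synthetic_data as sd
from chromsig.io_formats import LOG2_INTENSITY, SampleRecord
from chromsig.normalization import normalize_pipeline

from conftest import make_matrix


def bh_bruteforce(pvalues):
    """Step-up definition: q_i = min over p_j >= p_i of m * p_j / rank_j."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


class TestTTest:
    def test_unpaired_equal_variance_closed_form(self):
        t, p = diff.t_test_two_sample([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.021, abs=1e-3)

    def test_paired_all_identical_gives_p_one(self):
        t, p = diff.t_test_two_sample([1, 2, 3], [1, 2, 3], paired=True)
        assert (t, p) == (0.0, 1.0)

    def test_paired_closed_form(self):
        # diffs (1,2,3): mean 2, sd 1, t = 2*sqrt(3), df 2
        t, p = diff.t_test_two_sample([2, 4, 6], [1, 2, 3], paired=True)
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert p == pytest.approx(0.074, abs=1e-3)

    def test_zero_variance_nonzero_difference_gives_p_zero(self):
        t, p = diff.t_test_two_sample([1, 1, 1], [2, 2, 2])
        assert p == 0.0 and t == -np.inf

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            t, p = diff.t_test_two_sample(a, b)
            ts, ps = sps.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ts, rel=1e-10)
            assert p == pytest.approx(ps, rel=1e-10)
            tw, pw = diff.t_test_two_sample(a, b, equal_variance=False)
            ts, ps = sps.ttest_ind(a, b, equal_var=False)
            assert pw == pytest.approx(ps, rel=1e-10)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=8), rng.normal(size=8)
        t, p = diff.t_test_two_sample(a, b, paired=True)
        ts, ps = sps.ttest_rel(a, b)
        assert p == pytest.approx(ps, rel=1e-10)

    def test_size_violations(self):
        with pytest.raises(ValueError):
            diff.t_test_two_sample([1], [2, 3])
        with pytest.raises(ValueError):
            diff.t_test_two_sample([1, 2], [1, 2, 3], paired=True)


class TestBhFdr:
    def test_equal_spacing_example(self):
        q = diff.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert diff.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_two_values(self):
        assert np.allclose(diff.bh_fdr([0.005, 0.5]), [0.01, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10),)
    def test_matches_bruteforce_definition(self, pvals):
        assert np.allclose(diff.bh_fdr(pvals), bh_bruteforce(pvals), atol=1e-12)


def two_group_metadata(n_a, n_b, cell_type="monocyte"):
    meta = [SampleRecord(f"a{i}", cell_type, "RA") for i in range(n_a)]
    meta += [SampleRecord(f"b{i}", cell_type, "OA") for i in range(n_b)]
    return meta


class TestDifferentialTable:
    def make(self, rng, n_regions=50, n_a=4, n_b=4):
        m = make_matrix(rng.normal(5, 1, size=(n_regions, n_a + n_b)),
                        scale=LOG2_INTENSITY)
        m.samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        return m, two_group_metadata(n_a, n_b)

    def test_threshold_family_semantics(self):
        fam = diff.DISEASE_FAMILY
        assert fam.survives(1.5, 1e-4, 0.05, 10)
        assert not fam.survives(0.9, 1e-6, 0.01, 10)   # |log2fc| boundary
        assert not fam.survives(1.0, 1e-6, 0.01, 10)   # strict >
        assert not fam.survives(1.5, 0.001, 0.05, 10)  # strict <

    def test_identical_groups_yield_no_survivors(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5, 1, size=(30, 4))
        m = make_matrix(np.hstack([base, base]), scale=LOG2_INTENSITY)
        m.samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        records, surv = diff.differential_table(m, two_group_metadata(4, 4), "RA", "OA")
        assert surv == set()
        assert all(r.log2fc == 0 for r in records)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        m, meta = self.make(rng)
        fwd, _ = diff.differential_table(m, meta, "RA", "OA")
        rev, _ = diff.differential_table(m, meta, "OA", "RA")
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc)
            assert f.p == pytest.approx(r.p)

    def test_survivors_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        m, meta = self.make(rng)
        tight = diff.ThresholdFamily(min_abs_log2fc=1.0, max_p=0.01, max_fdr=0.1)
        loose = diff.ThresholdFamily(min_abs_log2fc=0.5, max_p=0.05, max_fdr=0.5)
        _, s_tight = diff.differential_table(m, meta, "RA", "OA", tight)
        _, s_loose = diff.differential_table(m, meta, "RA", "OA", loose)
        assert s_tight <= s_loose

    def test_absent_group_rejected(self):
        rng = np.random.default_rng(4)
        m, meta = self.make(rng)
        with pytest.raises(ValueError, match="HD"):
            diff.differential_table(m, meta, "HD", "OA")

    def test_raw_count_matrix_rejected(self):
        rng = np.random.default_rng(5)
        m, meta = self.make(rng)
        m.scale = "raw_counts"
        with pytest.raises(ValueError, match="log2"):
            diff.differential_table(m, meta, "RA", "OA")


class TestCelltypeSpecific:
    def test_planted_block_recovered(self):
        rng = np.random.default_rng(6)
        n = 60
        meta = [SampleRecord(f"m{i}", "monocyte", "RA") for i in range(4)]
        meta += [SampleRecord(f"t{i}", "CD4T", "RA") for i in range(4)]
        values = rng.normal(5, 0.3, size=(n, 8))
        values[:10, :4] += 5.0  # monocyte-high block
        m = make_matrix(values, scale=LOG2_INTENSITY)
        m.samples = [s.sample_id for s in meta]
        out = diff.celltype_specific_peaks(m, meta)
        expected = set(m.region_ids[:10])
        assert out["monocyte"] == expected
        assert out["CD4T"] == set()

    def test_no_structure_gives_empty_sets(self):
        rng = np.random.default_rng(7)
        meta = [SampleRecord(f"m{i}", "monocyte", "RA") for i in range(3)]
        meta += [SampleRecord(f"t{i}", "B", "RA") for i in range(3)]
        m = make_matrix(rng.normal(5, 0.3, size=(40, 6)), scale=LOG2_INTENSITY)
        m.samples = [s.sample_id for s in meta]
        out = diff.celltype_specific_peaks(m, meta)
        assert all(v == set() for v in out.values())

    def test_undersized_cell_type_named(self):
        meta = [SampleRecord("m1", "monocyte", "RA"),
                SampleRecord("t1", "B", "RA"), SampleRecord("t2", "B", "RA")]
        m = make_matrix(np.ones((5, 3)), scale=LOG2_INTENSITY)
        m.samples = ["m1", "t1", "t2"]
        with pytest.raises(ValueError, match="monocyte"):
            diff.celltype_specific_peaks(m, meta)


class TestStimContrast:
    def test_planted_shift_recovered(self):
        config = sd.StimConfig(n_peaks=800, cluster_sizes=(50, 50, 50),
                               stim_effect=1.0, noise_sd=0.2, seed=3)
        matrix, meta, regions, truth = sd.generate_stim_pairs(config)
        norm = normalize_pipeline(matrix)
        records, up, down = diff.stim_contrast(norm, meta)
        c3 = truth.cluster_regions("C3") & set(norm.region_ids)
        assert len(up & c3) / len(c3) > 0.8
        assert len(up - c3) / (len(norm.region_ids) - len(c3)) < 0.02

    @pytest.mark.parametrize("eps,expect_up", [(-1e-9, False), (1e-9, True)])
    def test_fold_change_boundary_is_strict(self, eps, expect_up):
        # a uniform shift a hair below log2(1.5) must fail the strict >
        # filter even though the paired p is 0; a hair above must pass
        n_pairs = 6
        shift = np.log2(1.5) + eps
        rng = np.random.default_rng(8)
        ctrl = rng.normal(5, 0.4, size=(20, n_pairs))
        stim = ctrl + shift
        m = make_matrix(np.hstack([stim, ctrl]), scale=LOG2_INTENSITY)
        meta = []
        samples = []
        for i in range(n_pairs):
            meta.append(SampleRecord(f"s{i}", "monocyte", "CRPstim", pair_id=f"P{i}"))
            samples.append(f"s{i}")
        for i in range(n_pairs):
            meta.append(SampleRecord(f"c{i}", "monocyte", "control", pair_id=f"P{i}"))
            samples.append(f"c{i}")
        m.samples = samples
        records, up, down = diff.stim_contrast(m, meta)
        if expect_up:
            assert len(up) == 20
        else:
            assert up == set()

    def test_unpaired_sample_rejected(self):
        m = make_matrix(np.ones((3, 3)), scale=LOG2_INTENSITY)
        m.samples = ["s1", "s2", "c1"]
        meta = [SampleRecord("s1", "monocyte", "CRPstim", pair_id="P1"),
                SampleRecord("s2", "monocyte", "CRPstim", pair_id="P2"),
                SampleRecord("c1", "monocyte", "control", pair_id="P1")]
        with pytest.raises(ValueError, match="unpaired|P2"):
            diff.stim_contrast(m, meta)


class TestRnaDeFilter:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "p", "total_counts"])

    def test_rule_application(self):
        t = self.table([("g1", 1.0, 0.01, 10),   # fc 2.0 -> kept
                        ("g2", 1.0, 0.01, 5),    # sum == 5 -> dropped (strict)
                        ("g3", 0.5, 0.01, 10),   # fc 1.41 -> dropped
                        ("g4", 1.0, 0.05, 10)])  # p == 0.05 -> dropped (strict)
        assert diff.rna_de_filter(t) == {"g1"}

    def test_empty_table(self):
        assert diff.rna_de_filter(self.table([])) == set()


def test_type_one_error_under_global_null():
    """With zero planted effects the p < alpha fraction matches alpha."""
    config = sd.CohortConfig(n_peaks=5000, cluster_sizes=(100, 100, 100),
                             effect_size=0.0, n_chry_peaks=0, seed=9)
    matrix, meta, regions, truth = sd.generate_cohort(config)
    norm = normalize_pipeline(matrix, min_mean=None)
    records, _ = diff.differential_table(norm, meta, "RA", "OA")
    p = np.array([r.p for r in records])
    for alpha in (0.01, 0.05):
        frac = (p < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / len(p))
        assert abs(frac - alpha) < 3 * se
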