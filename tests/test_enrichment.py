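import math

import numpy as np
import pandas as pd
import pytest

from chromsig import enrichment as en
from chromsig import synthetic_data as sd
from chromsig.io_formats import GeneSet, MotifModel


def gsea_es_bruteforce(ranked: pd.Series, genes, weight=1.0):
    """Direct-formula ES: P_hit(i) - P_miss(i) evaluated at every prefix,
    no incremental update."""
    s = ranked.copy()
    s.index = s.index.str.upper()
    s = s.sort_values(ascending=False)
    genes = {g.upper() for g in genes}
    stats = s.to_numpy()
    in_set = np.array([g in genes for g in s.index])
    n = len(s)
    nh = in_set.sum()
    nr = np.sum(np.abs(stats[in_set]) ** weight)
    devs = []
    for i in range(1, n + 1):
        p_hit = np.sum(np.abs(stats[:i][in_set[:i]]) ** weight) / nr
        p_miss = np.sum(~in_set[:i]) / (n - nh)
        devs.append(p_hit - p_miss)
    # same stated convention as the implementation: earliest extreme of
    # maximal |deviation|, judged with a small tolerance
    best_abs = max(abs(d) for d in devs)
    return next(d for d in devs if abs(d) >= best_abs - 1e-9)


def uniform_motif(width=2):
    return MotifModel("U", np.ones((4, width)))


class TestPwm:
    def test_uniform_counts_give_zero_matrix(self):
        pwm = en.pwm_from_counts(uniform_motif(3))
        assert np.allclose(pwm, 0.0)

    def test_dominant_base_log_odds(self):
        m = MotifModel("M", np.array([[10], [0], [0], [0]], float))
        pwm = en.pwm_from_counts(m, pseudocount=0.25)
        assert pwm[0, 0] == pytest.approx(math.log2((10.25 / 11) / 0.25), abs=1e-9)

    def test_width_preserved(self):
        assert en.pwm_from_counts(uniform_motif(7)).shape == (4, 7)


class TestScan:
    def exact_motif(self, consensus):
        counts = np.full((4, len(consensus)), 0.0)
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 100.0
        return MotifModel("EX", counts + 1e-9)

    def test_single_forward_hit(self):
        motif = self.exact_motif("ACGG")
        hits = en.scan_sequences({"r1": "TTTACGGTTT"}, motif, score_fraction=1.0)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (3, "+")

    def test_reverse_complement_hit(self):
        motif = self.exact_motif("ACGG")
        # reverse complement of ACGG is CCGT
        hits = en.scan_sequences({"r1": "TTCCGTTTTT"}, motif, score_fraction=1.0)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (2, "-")

    def test_all_offsets_match_hand_enumeration(self):
        motif = MotifModel("M2", np.array([[3, 1], [1, 1], [1, 5], [1, 1]], float))
        pwm = en.pwm_from_counts(motif)
        seq = "ACGT"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = {}
        for off in range(3):
            expected[(off, "+")] = pwm[idx[seq[off]], 0] + pwm[idx[seq[off + 1]], 1]
            rc = comp[seq[off + 1]] + comp[seq[off]]
            expected[(off, "-")] = pwm[idx[rc[0]], 0] + pwm[idx[rc[1]], 1]
        threshold_fraction = 0.5
        threshold = threshold_fraction * pwm.max(axis=0).sum()
        hits = en.scan_sequences({"r": seq}, motif, score_fraction=threshold_fraction)
        got = {(h.offset, h.strand): h.score for h in hits}
        # exactly the offsets clearing the threshold are reported, with the
        # hand-enumerated scores
        assert set(got) == {k for k, v in expected.items() if v >= threshold}
        for key, score in got.items():
            assert score == pytest.approx(expected[key], abs=1e-12)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        motif = MotifModel("M", rng.uniform(0.5, 10, size=(4, 5)))
        seq = "".join(rng.choice(list("ACGT"), size=40))
        rc = en.reverse_complement(seq)
        hits_fwd = en.scan_sequences({"r": seq}, motif, 0.5)
        hits_rc = en.scan_sequences({"r": rc}, motif, 0.5)
        mapped = {(len(seq) - h.offset - 5, {"+": "-", "-": "+"}[h.strand])
                  for h in hits_rc}
        assert {(h.offset, h.strand) for h in hits_fwd} == mapped

    def test_short_sequence_yields_no_hits(self):
        hits = en.scan_sequences({"r": "AC"}, self.exact_motif("ACGG"))
        assert hits == []


class TestMotifEnrichment:
    def hit(self, motif_id, region_id):
        return en.MotifHit(motif_id, region_id, 0, "+", 1.0)

    def test_extreme_enrichment_closed_form(self):
        target = {f"t{i}" for i in range(10)}
        background = {f"b{i}" for i in range(10)}
        hits = [self.hit("M", r) for r in target]
        df = en.motif_enrichment(target, background, hits)
        assert df.loc[0, "p"] == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_motif_absent_everywhere_p_one(self):
        target, background = {"t1", "t2"}, {"b1", "b2"}
        hits = [self.hit("M", "elsewhere")]
        df = en.motif_enrichment(target, background, hits)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_planted_motif_ranks_first(self):
        config = sd.MotifConfig(seed=11)
        sequences, motifs, target_ids, background_ids, truth = (
            sd.generate_motif_data(config))
        hits = []
        for m in motifs:
            hits.extend(en.scan_sequences(sequences, m))
        df = en.motif_enrichment(set(target_ids), set(background_ids), hits)
        assert df.loc[0, "motif_id"] == "PLANTED"
        assert df.loc[0, "p"] < 1e-10

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            en.motif_enrichment(set(), {"b"}, [])

    def test_significance_matrix_consistent(self):
        target = {f"t{i}" for i in range(5)}
        background = {f"b{i}" for i in range(15)}
        hits = [self.hit("M", r) for r in target]
        df = en.motif_enrichment(target, background, hits)
        mat = en.motif_significance_matrix(
            {"setA": target}, target | background, hits)
        assert mat.loc["M", "setA"] == pytest.approx(-np.log10(df.loc[0, "p"]))

    def test_neglog10_entries(self):
        target, background = {"t1", "t2"}, {"b1", "b2"}
        mat = en.motif_significance_matrix(
            {"s": target}, target | background,
            [self.hit("M", "nowhere")])
        assert mat.loc["M", "s"] == 0.0  # p = 1 -> entry 0


class TestGseaEs:
    def ranked(self):
        return pd.Series([4.0, 3.0, 2.0, 1.0], index=["A", "B", "C", "D"])

    def test_top_gene_scores_one(self):
        assert en.gsea_es(self.ranked(), {"A"}) == pytest.approx(1.0)

    def test_bottom_gene_scores_minus_one(self):
        assert en.gsea_es(self.ranked(), {"D"}) == pytest.approx(-1.0)

    def test_interleaved_set_scores_small(self):
        # every other gene of a ranking symmetric around zero: the running
        # sum oscillates near zero and never builds a large deviation
        stats = [5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0]
        genes = [f"g{i}" for i in range(10)]
        ranked = pd.Series(stats, index=genes)
        every_other = {genes[i] for i in range(0, 10, 2)}
        es = en.gsea_es(ranked, every_other)
        assert abs(es) < 0.5
        assert es == pytest.approx(gsea_es_bruteforce(ranked, every_other), abs=1e-12)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            en.gsea_es(self.ranked(), {"Z"})
        with pytest.raises(ValueError, match="entire"):
            en.gsea_es(self.ranked(), {"A", "B", "C", "D"})

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(5, 40))
            stats = rng.normal(size=n)
            genes = [f"g{i}" for i in range(n)]
            ranked = pd.Series(stats, index=genes)
            size = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=size, replace=False))
            w = float(rng.choice([0.5, 1.0, 2.0]))
            assert en.gsea_es(ranked, gene_set, w) == pytest.approx(
                gsea_es_bruteforce(ranked, gene_set, w), abs=1e-12)


class TestGseaPvalue:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        ranked = pd.Series(rng.normal(size=50),
                           index=[f"g{i}" for i in range(50)])
        gs = GeneSet("S", frozenset({"g1", "g5", "g30"}))
        a = en.gsea_pvalue(ranked, gs, n_perm=200, seed=3)
        b = en.gsea_pvalue(ranked, gs, n_perm=200, seed=3)
        assert a.p == b.p and a.es == b.es

    def test_planted_top_loaded_set_significant(self):
        rng = np.random.default_rng(7)
        n = 120
        stats = rng.normal(size=n)
        stats[:15] += 2.5
        ranked = pd.Series(stats, index=[f"g{i}" for i in range(n)])
        gs = GeneSet("TOP", frozenset(f"g{i}" for i in range(15)))
        out = en.gsea_pvalue(ranked, gs, n_perm=500, seed=1)
        assert out.p < 0.05 and out.es > 0

    def test_null_p_roughly_uniform(self):
        """Over many seeded null draws the 10th percentile of p sits near
        0.1 (permutation p is discrete and conservative)."""
        rng = np.random.default_rng(8)
        n = 60
        ranked = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        genes = np.asarray(ranked.index)
        ps = []
        for i in range(200):
            gene_set = set(rng.choice(genes, size=8, replace=False))
            ps.append(en.gsea_pvalue(ranked, gene_set, n_perm=100, seed=i).p)
        q10 = float(np.percentile(ps, 10))
        assert 0.05 <= q10 <= 0.2

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            en.gsea_pvalue(pd.Series([1.0, 0.5], index=["a", "b"]), {"a"},
                           n_perm=10)
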