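import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fcgsig import (RankedList, discordant_pathways, enrichment_score,
                    gsea_preranked, nes_matrix, pathway_overlap,
                    rank_from_contrast)
from fcgsig.enrichment import _es_from_positions
from fcgsig.simulate import GeneSetCollection


def ranked_from(metrics, genes=None):
    genes = genes or [f"g{i}" for i in range(len(metrics))]
    return RankedList(genes=tuple(genes),
                      metric=np.asarray(metrics, dtype=float))


def loop_es(ranked, gene_set, weight=1.0):
    """Per-position loop oracle for the weighted-KS enrichment score."""
    gene_set = set(gene_set)
    n = len(ranked)
    n_hits = sum(1 for g in ranked.genes if g in gene_set)
    n_r = sum(abs(ranked.metric[i]) ** weight
              for i, g in enumerate(ranked.genes) if g in gene_set)
    running = []
    value = 0.0
    for i, g in enumerate(ranked.genes):
        if g in gene_set:
            if n_r > 0:
                value += abs(ranked.metric[i]) ** weight / n_r
            else:
                value += 1.0 / n_hits
        else:
            value -= 1.0 / (n - n_hits)
        running.append(value)
    # argmax-first tie handling, matching the implementation
    idx = int(np.argmax(np.abs(np.array(running))))
    return running[idx], running


class TestRankFromContrast:
    def make_table(self, t_values, genes=None):
        genes = genes or [f"g{i}" for i in range(len(t_values))]
        return pd.DataFrame({"t": t_values}, index=genes)

    def test_sorted_descending(self):
        ranked = rank_from_contrast(self.make_table([1.0, 3.0, -2.0]))
        assert list(ranked.metric) == [3.0, 1.0, -2.0]

    def test_sign_reversal_reverses_order(self):
        table = self.make_table([1.0, 3.0, -2.0])
        fwd = rank_from_contrast(table)
        rev = rank_from_contrast(-table)
        assert list(rev.genes) == list(reversed(fwd.genes))

    def test_stable_under_permutation(self, rng):
        table = self.make_table(list(rng.normal(size=20)))
        shuffled = table.sample(frac=1, random_state=0)
        assert rank_from_contrast(table).genes == \
            rank_from_contrast(shuffled).genes

    def test_tie_broken_by_gene_id(self):
        table = self.make_table([1.0, 1.0], genes=["b", "a"])
        assert rank_from_contrast(table).genes == ("a", "b")

    def test_duplicate_gene_error(self):
        table = self.make_table([1.0, 2.0], genes=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            rank_from_contrast(table)


class TestEnrichmentScore:
    def test_top_gene_hits_one(self):
        ranked = ranked_from([4, 3, 2, 1])
        es, _ = enrichment_score(ranked, {"g0"})
        assert es == pytest.approx(1.0)

    def test_bottom_gene_hits_minus_one(self):
        ranked = ranked_from([4, 3, 2, 1])
        es, _ = enrichment_score(ranked, {"g3"})
        assert es == pytest.approx(-1.0)

    def test_weight_zero_equals_classical_ks(self):
        ranked = ranked_from([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        top_half = {f"g{i}" for i in range(5)}
        es, _ = enrichment_score(ranked, top_half, weight=0)
        # brute-force classical KS on hit/miss indicator
        hits = np.array([1] * 5 + [0] * 5)
        cdf_hits = np.cumsum(hits) / 5
        cdf_miss = np.cumsum(1 - hits) / 5
        dev = cdf_hits - cdf_miss
        expected = dev[np.argmax(np.abs(dev))]
        assert es == pytest.approx(expected)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            metric = np.sort(rng.normal(size=n))[::-1]
            ranked = ranked_from(metric)
            k = int(rng.integers(1, n - 1))
            gene_set = set(rng.choice(ranked.genes, size=k, replace=False))
            es, running = enrichment_score(ranked, gene_set)
            es_ref, running_ref = loop_es(ranked, gene_set)
            assert es == pytest.approx(es_ref, abs=1e-12)
            np.testing.assert_allclose(running, running_ref, atol=1e-12)

    def test_vectorized_null_matches_single(self, rng):
        n = 40
        metric = np.sort(rng.normal(size=n))[::-1]
        ranked = ranked_from(metric)
        absw = np.abs(metric)
        for _ in range(20):
            k = int(rng.integers(2, 15))
            pos = np.sort(rng.choice(n, size=k, replace=False))
            es_vec = _es_from_positions(pos[None, :], absw, n)[0]
            gene_set = {ranked.genes[i] for i in pos}
            es, running = enrichment_score(ranked, gene_set)
            assert abs(es_vec) == pytest.approx(abs(es), abs=1e-12)
            # signs must agree unless +|ES| and -|ES| are both attained
            tied = (np.abs(running.max() - np.abs(running).max()) < 1e-12
                    and np.abs(-running.min() - np.abs(running).max())
                    < 1e-12)
            if not tied:
                assert es_vec == pytest.approx(es, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_es_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        metric = np.sort(rng.normal(size=n))[::-1]
        ranked = ranked_from(metric)
        k = int(rng.integers(1, n))
        gene_set = set(rng.choice(ranked.genes, size=k, replace=False))
        es, running = enrichment_score(ranked, gene_set)
        assert abs(es) <= 1 + 1e-12
        assert np.abs(running).max() <= 1 + 1e-12

    def test_antisymmetry(self, rng):
        n = 30
        metric = np.sort(rng.normal(size=n))[::-1]
        ranked = ranked_from(metric)
        flipped = RankedList(genes=tuple(reversed(ranked.genes)),
                             metric=-metric[::-1])
        for _ in range(20):
            k = int(rng.integers(1, n - 1))
            gene_set = set(rng.choice(ranked.genes, size=k, replace=False))
            es_fwd, _ = enrichment_score(ranked, gene_set)
            es_rev, _ = enrichment_score(flipped, gene_set)
            assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_empty_and_full_set_errors(self):
        ranked = ranked_from([3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"absent"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1", "g2"})


class TestGseaPreranked:
    def planted_inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 500
        metric = np.sort(rng.normal(size=n))[::-1] + \
            np.linspace(3, -3, n) * 0
        ranked = ranked_from(np.sort(rng.normal(size=n))[::-1])
        top = set(ranked.genes[:30])
        sets = {"planted": tuple(sorted(top))}
        for i in range(10):
            sets[f"rand{i}"] = tuple(rng.choice(ranked.genes, 30,
                                                replace=False))
        return ranked, GeneSetCollection(sets=sets)

    def test_planted_top_set_significant(self):
        ranked, coll = self.planted_inputs()
        result = gsea_preranked(ranked, coll, n_perm=500, seed=1)
        row = result.loc["planted"]
        assert row["nes"] > 0
        assert row["q"] < 0.25
        assert row["p"] <= 0.01

    def test_seed_determinism(self):
        ranked, coll = self.planted_inputs()
        a = gsea_preranked(ranked, coll, n_perm=200, seed=5)
        b = gsea_preranked(ranked, coll, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_sign_consistency_and_bounds(self):
        ranked, coll = self.planted_inputs()
        result = gsea_preranked(ranked, coll, n_perm=200, seed=2)
        assert (np.sign(result["nes"]) == np.sign(result["es"])).all()
        assert (result["p"] >= 1 / 201).all()
        assert result["q"].between(0, 1).all()

    def test_size_filter_and_error(self):
        ranked, coll = self.planted_inputs()
        with pytest.raises(ValueError, match="size filter"):
            gsea_preranked(ranked, coll, min_size=100, max_size=200)

    def test_leading_edge_subset_of_set(self):
        ranked, coll = self.planted_inputs()
        result = gsea_preranked(ranked, coll, n_perm=100, seed=3)
        leading = set(result.loc["planted", "leading_edge"].split(","))
        assert leading <= set(coll.sets["planted"])
        assert leading

    def test_null_nes_centred_near_one(self, rng):
        metric = np.sort(rng.normal(size=400))[::-1]
        ranked = ranked_from(metric)
        sets = {f"r{i}": tuple(rng.choice(ranked.genes, 25, replace=False))
                for i in range(40)}
        result = gsea_preranked(ranked, sets, n_perm=300, seed=4)
        pos = result.loc[result["nes"] > 0, "nes"]
        neg = result.loc[result["nes"] < 0, "nes"]
        assert abs(pos.mean() - 1.0) < 0.25
        assert abs(neg.mean() + 1.0) < 0.25


class TestNesMatrix:
    def make_result(self, nes, q, sets=None):
        sets = sets or [f"p{i}" for i in range(len(nes))]
        return pd.DataFrame({"nes": nes, "q": q},
                            index=pd.Index(sets, name="set"))

    def test_masking_rule(self):
        res = {"r1": self.make_result([2.0, 1.5], [0.1, 0.5])}
        mat = nes_matrix(res)
        assert mat.loc["r1", "p0"] == 2.0
        assert mat.loc["r1", "p1"] == 0.0

    def test_all_nonsignificant_zero(self):
        res = {"r1": self.make_result([2.0], [0.3])}
        assert (nes_matrix(res).to_numpy() == 0).all()

    def test_masking_idempotent(self):
        res = {"r1": self.make_result([2.0, -1.8], [0.01, 0.6])}
        m1 = nes_matrix(res)
        res2 = {"r1": pd.DataFrame({"nes": m1.loc["r1"],
                                    "q": [0.01, 0.6]})}
        m2 = nes_matrix(res2)
        pd.testing.assert_frame_equal(m1, m2, check_names=False)


class TestPathwayOverlap:
    def test_identical(self):
        df = pathway_overlap({"a": {"p1", "p2"}, "b": {"p1", "p2"}})
        assert df["percent"].iloc[0] == 100.0

    def test_disjoint(self):
        df = pathway_overlap({"a": {"p1"}, "b": {"p2"}})
        assert df["percent"].iloc[0] == 0.0

    def test_toy_jaccard(self):
        a = {f"p{i}" for i in range(14)}          # 5 shared + 9
        b = {f"p{i}" for i in range(9, 18)}       # |a&b|=5, |a|b|=18
        df = pathway_overlap({"a": a, "b": b})
        assert df["intersection"].iloc[0] == 5
        assert df["denominator"].iloc[0] == 18
        assert df["percent"].iloc[0] == pytest.approx(27.8, abs=0.05)


class TestDiscordantPathways:
    STATES = ("sig_up", "sig_down", "ns_up", "ns_down")

    def state_row(self, state):
        nes = 1.5 if state.endswith("up") else -1.5
        q = 0.05 if state.startswith("sig") else 0.6
        return nes, q

    def brute_force(self, states):
        """Independent truth evaluator over one pathway's five states."""
        human, xxf, xxm, xyf, xym = states
        if human != "sig_up":
            return False
        if not all(s == "sig_down" for s in (xxf, xxm, xyf)):
            return False
        return xym == "sig_up" or xym.startswith("ns")

    def test_example_selected(self):
        tables = {}
        for name, state in zip(("human", "xxf", "xxm", "xyf", "xym"),
                               ("sig_up", "sig_down", "sig_down",
                                "sig_down", "ns_up")):
            nes, q = self.state_row(state)
            tables[name] = pd.DataFrame({"nes": [nes], "q": [q]},
                                        index=["pathway"])
        assert discordant_pathways(**tables) == ["pathway"]

    def test_xym_sig_down_excluded(self):
        tables = {}
        for name, state in zip(("human", "xxf", "xxm", "xyf", "xym"),
                               ("sig_up", "sig_down", "sig_down",
                                "sig_down", "sig_down")):
            nes, q = self.state_row(state)
            tables[name] = pd.DataFrame({"nes": [nes], "q": [q]},
                                        index=["pathway"])
        assert discordant_pathways(**tables) == []

    def test_exhaustive_truth_table(self):
        import itertools

        combos = list(itertools.product(self.STATES, repeat=5))
        names = [f"c{i}" for i in range(len(combos))]
        frames = {}
        for pos, response in enumerate(("human", "xxf", "xxm", "xyf",
                                        "xym")):
            rows = [self.state_row(combo[pos]) for combo in combos]
            frames[response] = pd.DataFrame(rows, columns=["nes", "q"],
                                            index=names)
        selected = set(discordant_pathways(**frames))
        expected = {name for name, combo in zip(names, combos)
                    if self.brute_force(combo)}
        assert selected == expected
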