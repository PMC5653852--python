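"""Running-sum enrichment, permutation NES/FDR and hypergeometric ORA,
each checked against an independent brute-force oracle."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from reciprome.enrichment import (
    GeneSetCollection,
    RankedList,
    enrichment_score,
    normalize_and_fdr,
    overrepresentation,
)
from reciprome.errors import ConfigurationError, EnrichmentError


def oracle_running_sum(genes, scores, gene_set, weight):
    """Independent O(N) walk: the textbook weighted KS running sum."""
    hits = [g in gene_set for g in genes]
    n, nh = len(genes), sum(hits)
    wsum = sum(abs(s) ** weight for g, s, h in zip(genes, scores, hits) if h)
    walk, cum = [], 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            cum += (abs(s) ** weight / wsum) if wsum > 0 else 1.0 / nh
        else:
            cum -= 1.0 / (n - nh)
        walk.append(cum)
    # prefer positive on |tie|; round so exact mathematical ties are not
    # broken by float summation order
    es = max(walk, key=lambda v: (round(abs(v), 9), v))
    return es, walk


def ranked(genes, scores, weight=1.0):
    return RankedList(np.array(genes, object), np.array(scores, float), weight)


class TestEnrichmentScore:
    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    def test_matches_brute_force_on_random_toys(self, rng, weight):
        for _ in range(20):
            n = int(rng.integers(10, 51))
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            r = ranked(genes, scores, weight)
            res = enrichment_score(r, gene_set)
            es_oracle, walk = oracle_running_sum(r.genes, r.scores, gene_set, weight)
            assert res.es == pytest.approx(es_oracle)
            assert np.allclose(res.running_sum, walk)

    def test_top_k_concentration_positive_peak_at_k(self):
        genes = [f"g{i}" for i in range(10)]
        scores = list(range(10, 0, -1))
        res = enrichment_score(ranked(genes, scores), set(genes[:3]))
        assert res.es > 0
        assert res.peak_position == 2  # 0-based position of the k-th gene

    def test_weight_zero_reduces_to_classic_ks(self):
        genes = [f"g{i}" for i in range(10)]
        scores = [9.0, 5.0, 4.0, 3.0, 2.5, 2.0, 1.0, 0.5, 0.2, 0.1]
        gene_set = {"g1", "g4", "g7"}
        res = enrichment_score(ranked(genes, scores, weight=0.0), gene_set)
        # classic KS: hits step 1/3, misses step -1/7
        es, _ = oracle_running_sum(genes, scores, gene_set, 0.0)
        assert res.es == pytest.approx(es)

    def test_monotone_score_transform_invariant_at_weight_zero(self, rng):
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        gene_set = set(rng.choice(genes, 8, replace=False))
        es1 = enrichment_score(ranked(genes, scores, 0.0), gene_set).es
        es2 = enrichment_score(ranked(genes, 3 * scores + 7, 0.0), gene_set).es
        assert es1 == pytest.approx(es2)

    def test_disjoint_set_raises(self):
        r = ranked(["a", "b"], [2.0, 1.0])
        with pytest.raises(EnrichmentError):
            enrichment_score(r, {"zzz"})

    def test_bottom_concentration_negative(self):
        genes = [f"g{i}" for i in range(12)]
        scores = list(range(12, 0, -1))
        assert enrichment_score(ranked(genes, scores), set(genes[-3:])).es < 0


def oracle_exhaustive_nes(genes, scores, sets, weight=1.0):
    """Independent exhaustive-permutation NES / nominal p / FDR q."""
    n = len(genes)
    obs, null = {}, {}
    for name, members in sets.items():
        es, _ = oracle_running_sum(genes, scores, members, weight)
        obs[name] = es
        k = len([g for g in genes if g in members])
        vals = []
        for c in combinations(range(n), k):
            subset = {genes[i] for i in c}
            vals.append(oracle_running_sum(genes, scores, subset, weight)[0])
        null[name] = np.array(vals)
    nes, pvals, null_nes = {}, {}, []
    for name in sets:
        nl, es = null[name], obs[name]
        pos_mean = nl[nl > 0].mean()
        neg_mean = np.abs(nl[nl < 0]).mean()
        denom = pos_mean if es >= 0 else neg_mean
        nes[name] = es / denom
        same = nl[nl >= 0] if es >= 0 else nl[nl < 0]
        pvals[name] = (np.abs(same) >= abs(es) - 1e-12).mean()
        null_nes.append(np.where(nl >= 0, nl / pos_mean, nl / neg_mean))
    pool = np.concatenate(null_nes)
    obs_nes = np.array(list(nes.values()))
    fdr = {}
    for name in sets:
        v = nes[name]
        if v >= 0:
            num = (pool >= v - 1e-12).sum() / (pool >= 0).sum()
            den = (obs_nes >= v - 1e-12).sum() / (obs_nes >= 0).sum()
        else:
            num = (pool <= v + 1e-12).sum() / (pool < 0).sum()
            den = (obs_nes <= v + 1e-12).sum() / (obs_nes < 0).sum()
        fdr[name] = min(1.0, num / den)
    return nes, pvals, fdr


class TestNormalizeAndFdr:
    def test_exhaustive_enumeration_on_twelve_gene_list(self):
        genes = [f"g{i}" for i in range(12)]
        scores = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0, -0.5, -1.0, -2.0, -3.0, -4.0, -5.0]
        sets = {"top": {"g0", "g1", "g3"}, "bottom": {"g8", "g10", "g11", "g9"}}
        out = normalize_and_fdr(
            ranked(genes, scores),
            GeneSetCollection.from_dict(sets),
            n_perm=1000,  # C(12,3)=220 and C(12,4)=495 both enumerable
            seed=0,
        )
        nes, pvals, fdr = oracle_exhaustive_nes(genes, scores, sets)
        for name in sets:
            assert out.loc[name, "nes"] == pytest.approx(nes[name])
            assert out.loc[name, "nominal_p"] == pytest.approx(pvals[name])
            assert out.loc[name, "fdr_q"] == pytest.approx(fdr[name])
        assert out.loc["top", "nes"] > 0 > out.loc["bottom", "nes"]

    def test_bottom_concentrated_set_gets_negative_nes(self, rng):
        genes = [f"g{i}" for i in range(200)]
        scores = np.sort(rng.normal(size=200))[::-1]
        sets = {"down": set(genes[-25:])}
        out = normalize_and_fdr(
            ranked(genes, scores), GeneSetCollection.from_dict(sets), n_perm=200, seed=1
        )
        assert out.loc["down", "nes"] < -1
        assert out.loc["down", "nominal_p"] < 0.05

    def test_sign_of_nes_matches_sign_of_es(self, rng):
        genes = [f"g{i}" for i in range(100)]
        scores = np.sort(rng.normal(size=100))[::-1]
        sets = {f"s{j}": set(rng.choice(genes, 12, replace=False)) for j in range(8)}
        out = normalize_and_fdr(
            ranked(genes, scores), GeneSetCollection.from_dict(sets), n_perm=150, seed=2
        )
        assert (np.sign(out["nes"]) == np.sign(out["es"])).all()
        assert out["fdr_q"].between(0, 1).all()

    def test_null_nominal_p_super_uniform(self, rng):
        genes = [f"g{i}" for i in range(60)]
        scores = np.sort(rng.normal(size=60))[::-1]
        sets = {
            f"s{j}": set(rng.choice(genes, 6, replace=False)) for j in range(500)
        }
        out = normalize_and_fdr(
            ranked(genes, scores), GeneSetCollection.from_dict(sets), n_perm=200, seed=3
        )
        for alpha in (0.05, 0.1):
            se = math.sqrt(alpha * (1 - alpha) / 500)
            assert (out["nominal_p"] < alpha).mean() <= alpha + 3 * se

    def test_planted_set_ranks_first_among_negatives(self, rng):
        # a strongly bottom-concentrated set should out-rank 49 decoys by
        # |NES| in nearly every seed
        genes = [f"g{i}" for i in range(400)]
        scores = np.sort(rng.normal(size=400))[::-1]
        wins = 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            sets = {"planted": set(genes[-40:])}
            for j in range(49):
                sets[f"decoy{j}"] = set(local.choice(genes, 40, replace=False))
            out = normalize_and_fdr(
                ranked(genes, scores),
                GeneSetCollection.from_dict(sets),
                n_perm=150,
                seed=seed,
            )
            wins += int(out.loc["planted", "rank_of_set"] == 1 and out.loc["planted", "nes"] < 0)
        assert wins >= 9

    def test_too_few_permutations_rejected(self):
        r = ranked(["a", "b", "c", "d"], [3.0, 2.0, 1.0, 0.5])
        with pytest.raises(ConfigurationError):
            normalize_and_fdr(r, GeneSetCollection.from_dict({"s": {"a", "b"}}), n_perm=10)


def oracle_hypergeom_tail(k, M, K, n):
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, i) * math.comb(M - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestOverrepresentation:
    def test_urn_toy_matches_direct_summation(self):
        universe = [f"u{i}" for i in range(20)]
        gene_set = set(universe[:5])
        query = universe[1:5] + [universe[10]]  # overlap 4
        out = overrepresentation(query, universe, GeneSetCollection.from_dict({"s": gene_set}))
        assert out.loc["s", "overlap"] == 4
        assert out.loc["s", "p"] == pytest.approx(oracle_hypergeom_tail(4, 20, 5, 5))

    def test_query_equal_universe_all_p_one(self):
        universe = [f"u{i}" for i in range(12)]
        coll = GeneSetCollection.from_dict({"a": set(universe[:4]), "b": set(universe[4:9])})
        out = overrepresentation(universe, universe, coll)
        assert np.allclose(out["p"], 1.0)

    def test_bh_adjustment_monotone(self, rng):
        universe = [f"u{i}" for i in range(200)]
        query = list(rng.choice(universe, 30, replace=False))
        coll = GeneSetCollection.from_dict(
            {f"s{j}": set(rng.choice(universe, 20, replace=False)) for j in range(15)}
        )
        out = overrepresentation(query, universe, coll)
        assert (out.sort_values("p")["p_adj"].diff().dropna() >= -1e-12).all()

    def test_stray_query_genes_listed(self):
        universe = ["a", "b"]
        with pytest.raises(ConfigurationError, match="zzz"):
            overrepresentation(["a", "zzz"], universe, GeneSetCollection.from_dict({"s": {"a"}}))

    def test_decision_rule_at_adjusted_alpha(self):
        # construct one strongly enriched set: adjusted p < 0.05 -> significant
        universe = [f"u{i}" for i in range(100)]
        coll = GeneSetCollection.from_dict({"hit": set(universe[:10]), "miss": set(universe[50:60])})
        out = overrepresentation(universe[:10], universe, coll)
        assert bool(out.loc["hit", "significant"])
        assert not bool(out.loc["miss", "significant"])
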