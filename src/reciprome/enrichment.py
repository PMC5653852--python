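"""Preranked gene-set enrichment and hypergeometric overrepresentation.

Implemented from scratch (no external GSEA engine):

* ``enrichment_score`` — weighted Kolmogorov-Smirnov running sum over a
  ranked gene list.  Walking the list, a gene in the set ("hit")
  increments the sum by ``|score|^p`` normalized by the total hit weight;
  a miss decrements by ``1/(N - n_hits)``.  The enrichment score (ES) is
  the signed maximum deviation from zero.  With ``p = 0`` this reduces to
  the classic unweighted KS statistic.
* ``normalize_and_fdr`` — null ES by gene-label permutation preserving
  set size (exact enumeration of all same-size subsets when feasible,
  Monte Carlo otherwise), NES = ES / mean(|null ES| of the matching
  sign), nominal p from the same-sign null tail, and FDR q by the
  standard positive/negative-tail ratio convention with same-sign null
  pooling across sets.
* ``overrepresentation`` — one-sided hypergeometric tail tests against a
  universe with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, EnrichmentError


@dataclass
class RankedList:
    """Genes ordered by a real-valued ranking score, descending.

    Ties in score break lexicographically by gene id (ascending), so the
    ordering — and everything downstream — is deterministic.
    ``weight_exponent`` is the hit-weight power p (0 = unweighted KS,
    1 = standard GSEA weighting).
    """

    genes: np.ndarray
    scores: np.ndarray
    weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if genes.size != scores.size:
            raise ConfigurationError("genes and scores must have equal length")
        if len(set(genes)) != genes.size:
            raise ConfigurationError("ranked list genes must be unique")
        if self.weight_exponent < 0:
            raise ConfigurationError("weight_exponent must be >= 0")
        order = np.lexsort((genes.astype(str), -scores))
        self.genes = genes[order]
        self.scores = scores[order]
        self._pos = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_scores(
        cls, scores: Mapping[str, float] | pd.Series, weight_exponent: float = 1.0
    ) -> "RankedList":
        s = pd.Series(scores)
        return cls(s.index.to_numpy(object), s.to_numpy(float), weight_exponent)

    def __len__(self) -> int:
        return int(self.genes.size)

    def positions(self, gene_set: Iterable[str]) -> np.ndarray:
        """Sorted rank positions (0-based) of set members present in the list."""
        return np.array(
            sorted(self._pos[g] for g in gene_set if g in self._pos), dtype=int
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-derived); members unique within a set."""

    sets: dict[str, frozenset]
    universe: frozenset | None = None

    @classmethod
    def from_dict(
        cls, d: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        return cls(
            {name: frozenset(members) for name, members in d.items()},
            frozenset(universe) if universe is not None else None,
        )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    peak_position: int  # 0-based index in the ranked list where |sum| peaks


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[float, int]:
    """ES and peak from sorted hit positions and their (raw) hit weights.

    O(k) equivalent of the full running-sum walk: between hits the sum
    decreases linearly, so extremes occur right after a hit (maximum
    candidates) or right before a hit (minimum candidates).
    """
    k = positions.size
    if k == 0 or k == n_total:
        raise EnrichmentError("gene set must hit a strict, non-empty subset of the list")
    wsum = weights.sum()
    if wsum <= 0:
        # all hit scores are exactly zero: fall back to unweighted increments
        weights = np.ones(k)
        wsum = float(k)
    cum_w = np.cumsum(weights) / wsum
    miss = 1.0 / (n_total - k)
    idx = np.arange(1, k + 1)
    # value right after hit i (1-based): sum of hit weights so far minus
    # miss penalty for the (pos_i + 1 - i) misses seen so far
    after = cum_w - (positions + 1 - idx) * miss
    # value right before hit i: previous hit weight minus misses up to pos_i - 1
    before = np.concatenate(([0.0], cum_w[:-1])) - (positions - (idx - 1)) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    hi, lo = float(after[i_max]), float(before[i_min])
    if abs(hi) >= abs(lo) - 1e-12:  # prefer the positive extreme on ties
        return hi, int(positions[i_max])
    # the minimum is attained at the last list position before the next hit;
    # report the position just before that hit (or the end of the list)
    peak = int(positions[i_min]) - 1 if positions[i_min] > 0 else 0
    return lo, peak


def enrichment_score(ranked: RankedList, gene_set: Iterable[str]) -> EnrichmentScore:
    """Weighted KS running-sum enrichment score of ``gene_set`` in ``ranked``.

    Raises :class:`EnrichmentError` when the set is disjoint from the list
    (or swallows it whole, leaving no misses).
    """
    pos = ranked.positions(gene_set)
    if pos.size == 0:
        raise EnrichmentError("gene set is disjoint from the ranked list")
    n = len(ranked)
    weights = np.abs(ranked.scores[pos]) ** ranked.weight_exponent
    es, peak = _es_from_positions(pos, weights, n)

    # full running sum, for inspection/plotting
    hit = np.zeros(n)
    wsum = weights.sum()
    if wsum <= 0:
        hit[pos] = 1.0 / pos.size
    else:
        hit[pos] = weights / wsum
    step = hit.copy()
    step[step == 0] = -1.0 / (n - pos.size)
    running = np.cumsum(step)
    return EnrichmentScore(es=es, running_sum=running, peak_position=peak)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    rank_of_set: int  # 1 = most extreme |NES| among sets of the same sign
    size: int


def _null_es(
    ranked: RankedList,
    set_positions: Mapping[str, np.ndarray],
    n_perm: int,
    seed: int | None,
) -> dict[str, np.ndarray]:
    """Null ES distributions per set under gene-label permutation.

    Sets whose subset count C(N, k) <= n_perm are enumerated exhaustively;
    the rest share n_perm Monte-Carlo label permutations of the list (one
    shuffle per iteration, each set's members mapped through it).
    """
    n = len(ranked)
    absw = np.abs(ranked.scores) ** ranked.weight_exponent
    out: dict[str, np.ndarray] = {}
    mc_sets = []
    for name, pos in set_positions.items():
        k = len(pos)
        if math.comb(n, k) <= n_perm:
            vals = [
                _es_from_positions(np.array(c), absw[list(c)], n)[0]
                for c in combinations(range(n), k)
            ]
            out[name] = np.array(vals)
        else:
            mc_sets.append(name)
    if mc_sets:
        rng = np.random.default_rng(seed)
        acc = {name: np.empty(n_perm) for name in mc_sets}
        for i in range(n_perm):
            perm = rng.permutation(n)
            for name in mc_sets:
                p = np.sort(perm[set_positions[name]])
                acc[name][i] = _es_from_positions(p, absw[p], n)[0]
        out.update(acc)
    return out


def normalize_and_fdr(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = 0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Observed ES, permutation NES, nominal p and FDR q for every set.

    NES = ES / mean(|null ES| of the same sign); nominal p is the
    same-sign null tail fraction; FDR q follows the standard convention:
    for a set with NES* >= 0,

        q = [#(null NES >= NES*) / #(null NES >= 0)]
            / [#(observed NES >= NES*) / #(observed NES >= 0)]

    clipped to [0, 1], and symmetrically for negative NES*, with null NES
    pooled across all sets.  Returns a DataFrame sorted by NES descending
    with columns es, nes, nominal_p, fdr_q, rank_of_set, size
    (rank_of_set = 1 is the most extreme |NES| within its sign).
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    sizes: dict[str, int] = {}
    set_pos: dict[str, np.ndarray] = {}
    observed: dict[str, float] = {}
    for name, members in collection.sets.items():
        pos = ranked.positions(members)
        if pos.size < min_size or pos.size >= len(ranked):
            continue
        sizes[name] = int(pos.size)
        set_pos[name] = pos
        observed[name] = enrichment_score(ranked, members).es
    if not sizes:
        raise EnrichmentError("no gene set overlaps the ranked list")

    null = _null_es(ranked, set_pos, n_perm, seed)

    nes: dict[str, float] = {}
    nominal_p: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for name, es in observed.items():
        nl = null[name]
        pos_mean = nl[nl > 0].mean() if (nl > 0).any() else np.nan
        neg_mean = np.abs(nl[nl < 0]).mean() if (nl < 0).any() else np.nan
        if not (np.isfinite(pos_mean) or np.isfinite(neg_mean)):
            raise EnrichmentError(f"degenerate null distribution for {name!r}")
        same = nl[nl >= 0] if es >= 0 else nl[nl < 0]
        denom = pos_mean if es >= 0 else neg_mean
        if not np.isfinite(denom) or denom == 0:
            raise EnrichmentError(f"no same-sign null ES for {name!r}")
        nes[name] = es / denom
        if same.size:
            exact = math.comb(len(ranked), sizes[name]) <= n_perm
            hits = int((np.abs(same) >= abs(es) - 1e-12).sum())
            nominal_p[name] = (
                hits / same.size if exact else (1 + hits) / (1 + same.size)
            )
        else:
            nominal_p[name] = 1.0
        scaled = np.where(nl >= 0, nl / pos_mean if np.isfinite(pos_mean) else 0.0,
                          nl / neg_mean if np.isfinite(neg_mean) else 0.0)
        null_nes_pool.append(scaled)

    pool = np.concatenate(null_nes_pool)
    obs_nes = np.array([nes[name] for name in observed])
    fdr: dict[str, float] = {}
    for name in observed:
        v = nes[name]
        if v >= 0:
            num_den = (pool >= 0).sum()
            obs_den = (obs_nes >= 0).sum()
            num = (pool >= v - 1e-12).sum() / max(num_den, 1)
            den = (obs_nes >= v - 1e-12).sum() / max(obs_den, 1)
        else:
            num_den = (pool < 0).sum()
            obs_den = (obs_nes < 0).sum()
            num = (pool <= v + 1e-12).sum() / max(num_den, 1)
            den = (obs_nes <= v + 1e-12).sum() / max(obs_den, 1)
        fdr[name] = float(min(1.0, num / den)) if den > 0 else 1.0

    df = pd.DataFrame(
        {
            "es": pd.Series(observed),
            "nes": pd.Series(nes),
            "nominal_p": pd.Series(nominal_p),
            "fdr_q": pd.Series(fdr),
            "size": pd.Series(sizes),
        }
    )
    df.index.name = "set_name"
    # rank within sign: 1 = largest |NES|
    df["rank_of_set"] = 0
    for sign_mask in (df["nes"] >= 0, df["nes"] < 0):
        sub = df.loc[sign_mask, "nes"].abs().sort_values(ascending=False)
        df.loc[sub.index, "rank_of_set"] = np.arange(1, len(sub) + 1)
    return df.sort_values("nes", ascending=False)


def overrepresentation(
    genes: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation with BH adjustment.

    For each set, tests whether the query ``genes`` overlap the set more
    than expected when drawing ``len(genes)`` genes from ``universe``.
    ``significant`` means BH-adjusted p < alpha.  Raises if the query is
    not contained in the universe (lists the offending genes).
    """
    query = set(genes)
    uni = set(universe)
    stray = sorted(query - uni)
    if stray:
        raise ConfigurationError(f"query genes not in universe: {stray}")
    M, n_draw = len(uni), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_uni = members & uni
        k = len(query & in_uni)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_uni), n_draw))
        rows.append({"set_name": name, "overlap": k, "set_size": len(in_uni), "p": p})
    df = pd.DataFrame(rows).set_index("set_name")
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    return df.sort_values("p")
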