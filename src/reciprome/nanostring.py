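"""Control-based normalization and permutation screening of miRNA count data.

Digital hybridization counters (nCounter-style assays) ship each cartridge
with spike-in positive-control probes spanning a concentration ladder and
negative-control probes measuring non-specific background.  This module
implements the standard analysis on such data:

* per-sample scaling by the geometric mean of the positive controls,
  anchored so the scale factors have geometric mean 1;
* per-sample background estimation as ``mean + 2*SD`` of the negative
  controls, with a configurable detection rule;
* pseudocounted group fold changes;
* a two-sided permutation test on the difference of group means of
  log2-transformed values, switching automatically to exact enumeration
  of all label assignments when that is cheaper than Monte Carlo;
* a two-sided fold-change screen (strict ``> cutoff`` / ``< 1/cutoff``)
  sorted by effect magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError

ENDOGENOUS = "endogenous"
POSITIVE_CONTROL = "positive_control"
NEGATIVE_CONTROL = "negative_control"
PROBE_CLASSES = (ENDOGENOUS, POSITIVE_CONTROL, NEGATIVE_CONTROL)


@dataclass
class MirnaCountMatrix:
    """Raw probe x sample count matrix with probe-class annotation.

    Parameters
    ----------
    counts
        Integer counts, probes in rows (index = probe id), samples in columns.
    probe_class
        Per-probe class, one of ``endogenous``, ``positive_control``,
        ``negative_control``; indexed like ``counts``.
    sample_groups
        Group label per sample; indexed like ``counts.columns``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise ConfigurationError("counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ConfigurationError("counts must be integral")
        self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            raise ConfigurationError("every probe needs a probe_class")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ConfigurationError(f"unknown probe classes: {sorted(bad)}")
        self.sample_groups = self.sample_groups.reindex(self.counts.columns)
        if self.sample_groups.isna().any():
            raise ConfigurationError("every sample needs a group label")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of(self, probe_class: str) -> pd.Index:
        return self.counts.index[self.probe_class == probe_class]

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.sample_groups:
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class NormalizedMatrix:
    """Positive-control-scaled endogenous values with detection calls.

    ``scale_factors`` have geometric mean 1 across samples (anchoring
    convention); ``background`` is the per-sample negative-control
    ``mean + 2*SD`` on the normalized scale.
    """

    values: pd.DataFrame
    detected: pd.Series
    scale_factors: pd.Series
    background: pd.Series
    sample_groups: pd.Series

    def detected_values(self) -> pd.DataFrame:
        return self.values.loc[self.detected[self.detected].index]


def _geomean_positive(x: np.ndarray) -> float:
    pos = x[x > 0]
    if pos.size == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(pos))))


def normalize_counts(
    raw: MirnaCountMatrix,
    detection_fraction: float = 1.0,
    per_group: bool = True,
    background_sd_mult: float = 2.0,
) -> NormalizedMatrix:
    """Scale samples by positive-control geometric means and call detection.

    The per-sample scale factor is the geometric mean of that sample's
    positive-control counts divided by the across-sample geometric mean of
    those per-sample geometric means, so factors multiply to 1.  Endogenous
    counts are divided by the factor.  Background is estimated per sample
    from the normalized negative controls as ``mean + background_sd_mult*SD``
    (0 when there are no negative-control probes).  A probe is ``detected``
    when its normalized value exceeds the sample background in at least
    ``detection_fraction`` of the samples of at least one group
    (``per_group=True``) or of all samples (``per_group=False``).

    Raises
    ------
    NormalizationError
        If a sample has no nonzero positive-control count (names the sample).
    ConfigurationError
        If the matrix carries no positive-control probes.
    """
    pos_probes = raw.probes_of(POSITIVE_CONTROL)
    if len(pos_probes) == 0:
        raise ConfigurationError("normalization requires >=1 positive-control probe")
    pos = raw.counts.loc[pos_probes]
    gm = {}
    for s in raw.samples:
        g = _geomean_positive(pos[s].to_numpy())
        if g == 0.0:
            raise NormalizationError(
                f"sample {s!r}: all positive-control counts are zero"
            )
        gm[s] = g
    gm = pd.Series(gm)
    anchor = float(np.exp(np.mean(np.log(gm.to_numpy()))))
    scale = gm / anchor

    endo = raw.counts.loc[raw.probes_of(ENDOGENOUS)]
    values = endo.div(scale, axis=1)

    neg_probes = raw.probes_of(NEGATIVE_CONTROL)
    if len(neg_probes) > 0:
        neg = raw.counts.loc[neg_probes].div(scale, axis=1)
        sd = neg.std(axis=0, ddof=1).fillna(0.0) if len(neg_probes) > 1 else 0.0
        background = neg.mean(axis=0) + background_sd_mult * sd
    else:
        background = pd.Series(0.0, index=raw.samples)

    above = values.gt(background, axis=1)
    if per_group:
        frac = above.T.groupby(raw.sample_groups).mean().T
        detected = (frac >= detection_fraction).any(axis=1)
    else:
        detected = above.mean(axis=1) >= detection_fraction

    return NormalizedMatrix(
        values=values,
        detected=detected,
        scale_factors=scale,
        background=background,
        sample_groups=raw.sample_groups.copy(),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Fold change, permutation p-value and screen flags for one feature."""

    feature_id: str
    fold_change: float
    direction: str  # up / down / unchanged
    p_perm: float
    passes_1_5x: bool
    passes_3x: bool

    @property
    def log2_fold_change(self) -> float:
        return math.log2(self.fold_change)


def _group_columns(norm: NormalizedMatrix, group: str) -> list[str]:
    cols = [s for s, g in norm.sample_groups.items() if g == group]
    if not cols:
        raise ConfigurationError(f"unknown or empty group {group!r}")
    return cols


def fold_change(
    norm: NormalizedMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    detected_only: bool = True,
) -> pd.Series:
    """Per-feature ``(mean_a + pc) / (mean_b + pc)`` on the normalized scale."""
    a = _group_columns(norm, group_a)
    b = _group_columns(norm, group_b)
    vals = norm.detected_values() if detected_only else norm.values
    fc = (vals[a].mean(axis=1) + pseudocount) / (vals[b].mean(axis=1) + pseudocount)
    fc.name = f"{group_a}_vs_{group_b}"
    return fc


def _exact_null_stats(x: np.ndarray, n_a: int) -> np.ndarray:
    """All distinct difference-of-means statistics for labelings of columns.

    ``x`` is features x samples; returns features x C(n, n_a).
    """
    n = x.shape[1]
    n_b = n - n_a
    total = x.sum(axis=1, keepdims=True)
    out = []
    for idx in combinations(range(n), n_a):
        sa = x[:, list(idx)].sum(axis=1, keepdims=True)
        out.append(sa / n_a - (total - sa) / n_b)
    return np.hstack(out)


def permutation_test(
    norm: NormalizedMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 10_000,
    seed: int | None = 0,
    pseudocount: float = 0.5,
    detected_only: bool = True,
) -> pd.Series:
    """Two-sided permutation p-values for the difference of group means.

    The statistic is the difference of group means of
    ``log2(value + pseudocount)``.  When the number of distinct label
    assignments ``C(n_a+n_b, n_a)`` does not exceed ``n_perm`` all
    assignments are enumerated and ``p = #{|null| >= |obs|} / #assignments``
    (the observed labeling is one of them, so p >= 1/#assignments).
    Otherwise ``n_perm`` Monte-Carlo relabelings are drawn and
    ``p = (1 + #{|null| >= |obs|}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    a = _group_columns(norm, group_a)
    b = _group_columns(norm, group_b)
    if len(a) + len(b) < 4:
        raise ConfigurationError("permutation test needs >=4 samples combined")
    vals = norm.detected_values() if detected_only else norm.values
    x = np.log2(vals[a + b].to_numpy() + pseudocount)
    n_a = len(a)
    obs = x[:, :n_a].mean(axis=1) - x[:, n_a:].mean(axis=1)
    # tolerance so that permutations tied with the observed statistic count
    tol = 1e-9 * (1.0 + np.abs(obs))

    n_distinct = math.comb(len(a) + len(b), n_a)
    if n_distinct <= n_perm:
        null = _exact_null_stats(x, n_a)
        hits = (np.abs(null) >= (np.abs(obs) - tol)[:, None]).sum(axis=1)
        p = hits / n_distinct
    else:
        rng = np.random.default_rng(seed)
        hits = np.zeros(x.shape[0], dtype=int)
        for _ in range(n_perm):
            perm = rng.permutation(x.shape[1])
            stat = x[:, perm[:n_a]].mean(axis=1) - x[:, perm[n_a:]].mean(axis=1)
            hits += np.abs(stat) >= (np.abs(obs) - tol)
        p = (1 + hits) / (1 + n_perm)
    return pd.Series(p, index=vals.index, name="p_perm")


def compare_groups(
    norm: NormalizedMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fold change + permutation p + screen flags for one group contrast.

    Returns a DataFrame indexed by feature id with columns ``fold_change``,
    ``log2_fc``, ``direction``, ``p_perm``, ``passes_1_5x``, ``passes_3x``.
    """
    fc = fold_change(norm, group_a, group_b, pseudocount=pseudocount)
    p = permutation_test(
        norm, group_a, group_b, n_perm=n_perm, seed=seed, pseudocount=pseudocount
    )
    df = pd.DataFrame({"fold_change": fc, "p_perm": p})
    df["log2_fc"] = np.log2(df["fold_change"])
    df["direction"] = np.where(
        df["fold_change"] > 1, "up", np.where(df["fold_change"] < 1, "down", "unchanged")
    )
    df["passes_1_5x"] = (df["fold_change"] > 1.5) | (df["fold_change"] < 1 / 1.5)
    df["passes_3x"] = (df["fold_change"] > 3.0) | (df["fold_change"] < 1 / 3.0)
    return df[["fold_change", "log2_fc", "direction", "p_perm", "passes_1_5x", "passes_3x"]]


def screen(
    results: pd.DataFrame,
    fold_cutoff: float,
    p_cutoff: float | None = None,
) -> pd.DataFrame:
    """Two-sided strict fold screen, sorted by |log2 fold change| descending.

    Keeps features with ``fold_change > fold_cutoff`` or
    ``fold_change < 1/fold_cutoff`` (and ``p_perm < p_cutoff`` when given).
    Ties in |log2 fc| break lexicographically by feature id.
    """
    if fold_cutoff <= 0:
        raise ConfigurationError("fold_cutoff must be > 0")
    mask = (results["fold_change"] > fold_cutoff) | (
        results["fold_change"] < 1.0 / fold_cutoff
    )
    if p_cutoff is not None:
        if p_cutoff <= 0:
            raise ConfigurationError("p_cutoff must be > 0")
        mask &= results["p_perm"] < p_cutoff
    out = results[mask].copy()
    out["_abs"] = out["log2_fc"].abs()
    out = (
        out.sort_index()
        .sort_values("_abs", ascending=False, kind="stable")
        .drop(columns="_abs")
    )
    return out
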