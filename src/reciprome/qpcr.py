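"""Relative qPCR quantification (2^-ddCt) and Bonferroni-corrected tests.

The comparative-Ct convention used throughout:

* per-sample dCt = mean replicate Ct(target assay) - mean replicate Ct(reference)
* ddCt = mean dCt(group A) - mean dCt(group B)
* fold = 2^-ddCt

Group tests run on the per-sample dCt values (the conventional scale for
relative qPCR), with pooled-variance Student t by default and Welch as an
option, and family-wise control by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

CT_COLUMNS = ("sample", "group", "assay", "replicate", "ct")


@dataclass
class CtTable:
    """Replicate Ct measurements in long form.

    ``data`` columns: sample, group, assay, replicate, ct.  ``reference_assay``
    names the endogenous control (U6 snRNA for miRNA, GAPDH for mRNA) and must
    be measured for every sample.
    """

    data: pd.DataFrame
    reference_assay: str

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ConfigurationError(f"Ct table missing columns: {sorted(missing)}")
        if not np.isfinite(self.data["ct"].to_numpy(dtype=float)).all():
            raise ConfigurationError("Ct values must be finite")
        dup = self.data.duplicated(subset=["sample", "assay", "replicate"])
        if dup.any():
            raise ConfigurationError("replicate index must be unique per (sample, assay)")
        with_ref = set(self.data.loc[self.data["assay"] == self.reference_assay, "sample"])
        for s in self.data["sample"].unique():
            if s not in with_ref:
                raise ConfigurationError(
                    f"sample {s!r} has no reference assay {self.reference_assay!r}"
                )

    @property
    def assays(self) -> list[str]:
        return sorted(self.data["assay"].unique())

    def sample_groups(self) -> pd.Series:
        return self.data.drop_duplicates("sample").set_index("sample")["group"]


def delta_ct(table: CtTable, assay: str) -> pd.DataFrame:
    """Per-sample dCt for one assay: mean replicate Ct minus reference mean Ct.

    Returns a DataFrame with columns sample, group, delta_ct.
    """
    d = table.data
    tgt = d[d["assay"] == assay].groupby("sample")["ct"].mean()
    if tgt.empty:
        raise ConfigurationError(f"assay {assay!r} not in Ct table")
    ref = d[d["assay"] == table.reference_assay].groupby("sample")["ct"].mean()
    missing = [s for s in tgt.index if s not in ref.index]
    if missing:
        raise ConfigurationError(f"samples missing reference assay: {missing}")
    out = (tgt - ref.reindex(tgt.index)).rename("delta_ct").reset_index()
    groups = table.sample_groups()
    out.insert(1, "group", out["sample"].map(groups))
    return out


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt result for one assay and one group contrast."""

    assay: str
    contrast: tuple[str, str]
    delta_ct_a: pd.Series  # per-sample dCt, numerator group
    delta_ct_b: pd.Series
    delta_delta_ct: float
    fold: float
    p_value: float | None = None
    significant: bool | None = None


def relative_expression(
    table: CtTable, assay: str, group_a: str, group_b: str
) -> RelativeExpression:
    """Compute ddCt = mean dCt(A) - mean dCt(B) and fold = 2^-ddCt."""
    dct = delta_ct(table, assay)
    a = dct.loc[dct["group"] == group_a].set_index("sample")["delta_ct"]
    b = dct.loc[dct["group"] == group_b].set_index("sample")["delta_ct"]
    if a.empty or b.empty:
        raise ConfigurationError(
            f"assay {assay!r}: no samples in one of groups {group_a!r}/{group_b!r}"
        )
    ddct = float(a.mean() - b.mean())
    return RelativeExpression(
        assay=assay,
        contrast=(group_a, group_b),
        delta_ct_a=a,
        delta_ct_b=b,
        delta_delta_ct=ddct,
        fold=float(2.0 ** (-ddct)),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha/m (exact value; round to 4 dp for display)."""
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    if m < 1:
        raise ConfigurationError("family size m must be >= 1")
    return alpha / m


def compare_two_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    family_size: int = 1,
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test with Bonferroni family correction.

    Runs on per-sample dCt values (or any per-sample summaries).  Returns
    ``(t, p, significant)`` with ``significant`` meaning
    ``p <= alpha / family_size``.  Two constant, equal groups give
    ``(0.0, 1.0, False)`` rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs >=2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    thresh = bonferroni_threshold(alpha, family_size)
    return float(t), float(p), bool(p <= thresh)


@dataclass
class MultiGroupResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise t-tests."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_adj, significant


def compare_multi_group(
    groups: Mapping[str, Sequence[float]],
    family: int | None = None,
    alpha: float = 0.05,
) -> MultiGroupResult:
    """One-way ANOVA followed by all pairwise Student t-tests.

    ``family`` overrides the Bonferroni family size; by default it is the
    number of pairwise comparisons actually performed, C(k, 2).
    """
    if len(groups) < 3:
        raise ConfigurationError("compare_multi_group needs >=3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ConfigurationError(f"group {k!r} has <2 values")
    if all(v.std(ddof=1) == 0 for v in arrays.values()) and (
        len({v.mean() for v in arrays.values()}) == 1
    ):
        f, p_anova = 0.0, 1.0
    else:
        f, p_anova = stats.f_oneway(*arrays.values())
    pairs = list(combinations(arrays, 2))
    m = family if family is not None else len(pairs)
    rows = []
    for ga, gb in pairs:
        t, p, _ = compare_two_groups(arrays[ga], arrays[gb])
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "t": t,
                "p_raw": p,
                "p_adj": p_adj,
                "significant": p_adj <= alpha,
            }
        )
    return MultiGroupResult(
        f_statistic=float(f), p_value=float(p_anova), pairwise=pd.DataFrame(rows)
    )


def assess_relative_expression(
    table: CtTable,
    assay: str,
    group_a: str,
    group_b: str,
    family_size: int = 1,
    alpha: float = 0.05,
    welch: bool = False,
) -> RelativeExpression:
    """relative_expression plus the two-group t-test on per-sample dCt."""
    rel = relative_expression(table, assay, group_a, group_b)
    t, p, sig = compare_two_groups(
        rel.delta_ct_a.to_numpy(),
        rel.delta_ct_b.to_numpy(),
        family_size=family_size,
        alpha=alpha,
        welch=welch,
    )
    return RelativeExpression(
        assay=rel.assay,
        contrast=rel.contrast,
        delta_ct_a=rel.delta_ct_a,
        delta_ct_b=rel.delta_ct_b,
        delta_delta_ct=rel.delta_delta_ct,
        fold=rel.fold,
        p_value=p,
        significant=sig,
    )
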