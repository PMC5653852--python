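"""Cross-dataset gene screens and reciprocal miRNA->target integration.

miRNAs are negative regulators, most often acting through target mRNA
degradation.  When a treatment lowers a miRNA, its validated targets
should rise in the same samples.  This module operationalizes that logic
over two independent gene-level fold-change datasets (here: in vivo
post- vs pre-therapy, and ex vivo treated vs control):

* genes down-regulated at least ``fold_cutoff``-fold in BOTH datasets
  (inclusive, any-probe rule at gene level);
* the high-magnitude subset (|fold| strictly greater than a cutoff in both);
* reciprocal targets: genes validated as targets of at least
  ``min_coregulators`` of the treatment-decreased miRNAs AND up-regulated
  in both datasets;
* annotation of a gene set by an external regulator map (e.g. predicted
  NF-kB-regulated yes/no).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

EXPRESSION_COLUMNS = ("gene_id", "fold_change", "direction")


def _ratio_from_dialect(fc: np.ndarray, direction: np.ndarray | None, dialect: str) -> np.ndarray:
    """Normalize fold-change encodings to positive ratio form (down < 1).

    dialects: ``ratio`` (already a ratio), ``signed`` (negative magnitude
    means down, e.g. -2.5 == 2.5-fold down), ``magnitude_direction``
    (positive magnitude + explicit direction column).
    """
    fc = fc.astype(float)
    if dialect == "ratio":
        if (fc <= 0).any():
            raise ConfigurationError("ratio fold changes must be > 0")
        return fc
    if dialect == "signed":
        out = np.where(fc < 0, -1.0 / fc, fc)
        if (np.abs(fc) < 1).any():
            raise ConfigurationError("signed fold changes must have magnitude >= 1")
        return out
    if dialect == "magnitude_direction":
        if direction is None:
            raise ConfigurationError("magnitude_direction dialect needs a direction column")
        if (fc <= 0).any():
            raise ConfigurationError("fold magnitudes must be > 0")
        return np.where(direction == "down", 1.0 / fc, fc)
    raise ConfigurationError(f"unknown fold-change dialect {dialect!r}")


@dataclass
class ExpressionDataset:
    """Gene-level fold changes for one contrast, in ratio form internally.

    ``records`` columns: gene_id, fold_change (positive ratio; <1 means
    down), direction (up/down), optional probe_id.  Identical duplicate
    rows are collapsed; distinct probes of the same gene are kept.
    """

    name: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = {"gene_id", "fold_change"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"{self.name}: missing columns {sorted(missing)}")
        if (df["gene_id"].astype(str).str.len() == 0).any():
            raise ConfigurationError(f"{self.name}: empty gene_id")
        if (df["fold_change"] <= 0).any():
            raise ConfigurationError(f"{self.name}: ratios must be > 0")
        if "direction" not in df.columns:
            df["direction"] = np.where(df["fold_change"] >= 1, "up", "down")
        else:
            up = df["direction"] == "up"
            bad = (up & (df["fold_change"] < 1)) | (~up & (df["fold_change"] > 1))
            if bad.any():
                raise ConfigurationError(
                    f"{self.name}: direction inconsistent with fold_change for "
                    f"{sorted(df.loc[bad, 'gene_id'].unique()[:5])}"
                )
        if "probe_id" not in df.columns:
            df["probe_id"] = df["gene_id"]
        self.records = df.drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_fold_table(
        cls, name: str, table: pd.DataFrame, dialect: str = "ratio"
    ) -> "ExpressionDataset":
        """Build from an export whose fold-change encoding is ``dialect``."""
        df = table.copy()
        direction = df["direction"].to_numpy() if "direction" in df.columns else None
        df["fold_change"] = _ratio_from_dialect(
            df["fold_change"].to_numpy(), direction, dialect
        )
        df["direction"] = np.where(df["fold_change"] >= 1, "up", "down")
        return cls(name=name, records=df)

    def genes(self) -> set[str]:
        return set(self.records["gene_id"])

    def down_magnitude(self) -> pd.Series:
        """Per-gene best down-fold magnitude (any-probe rule); >=1, NaN-free."""
        down = self.records[self.records["fold_change"] < 1]
        return (1.0 / down.groupby("gene_id")["fold_change"].min()).rename(self.name)

    def up_magnitude(self) -> pd.Series:
        up = self.records[self.records["fold_change"] > 1]
        return up.groupby("gene_id")["fold_change"].max().rename(self.name)


@dataclass
class InteractionTable:
    """Validated miRNA -> target-gene pairs (TarBase-style), deduplicated."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"mirna", "target_gene"} - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"interaction table missing columns {sorted(missing)}")
        if "evidence" not in self.records.columns:
            self.records = self.records.assign(evidence="")
        self.records = (
            self.records.drop_duplicates(subset=["mirna", "target_gene"])
            .sort_values(["mirna", "target_gene"])
            .reset_index(drop=True)
        )

    @classmethod
    def from_target_map(
        cls, mirna_targets: Mapping[str, Iterable[str]]
    ) -> "InteractionTable":
        rows = [
            {"mirna": m, "target_gene": g}
            for m, genes in mirna_targets.items()
            for g in genes
        ]
        return cls(pd.DataFrame(rows, columns=["mirna", "target_gene"]))

    def targets_of(self, mirna: str) -> set[str]:
        return set(self.records.loc[self.records["mirna"] == mirna, "target_gene"])


def common_downregulated(
    ds1: ExpressionDataset, ds2: ExpressionDataset, fold_cutoff: float = 2.0
) -> pd.DataFrame:
    """Genes down >= fold_cutoff (inclusive) in BOTH datasets.

    Gene-level any-probe rule: a gene qualifies in a dataset if any of its
    probes does.  Returns a DataFrame indexed by gene_id with one
    down-magnitude column per dataset (e.g. 12.3 means 12.3-fold down),
    sorted by gene id.  Symmetric in the two datasets.
    """
    if fold_cutoff < 1:
        raise ConfigurationError("fold_cutoff must be >= 1")
    m1, m2 = ds1.down_magnitude(), ds2.down_magnitude()
    common = sorted(
        set(m1.index[m1 >= fold_cutoff]) & set(m2.index[m2 >= fold_cutoff])
    )
    return pd.DataFrame({m1.name: m1.reindex(common), m2.name: m2.reindex(common)})


def high_magnitude_subset(
    common: pd.DataFrame, magnitude_cutoff: float = 10.0
) -> pd.DataFrame:
    """Rows of ``common`` with |fold| strictly > cutoff in both datasets."""
    if magnitude_cutoff <= 1:
        raise ConfigurationError("magnitude_cutoff must be > 1")
    mask = (common > magnitude_cutoff).all(axis=1)
    return common[mask]


def reciprocal_targets(
    down_mirnas: Sequence[str],
    interactions: InteractionTable,
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    min_coregulators: int = 2,
) -> pd.DataFrame:
    """Validated targets of >= ``min_coregulators`` decreased miRNAs that
    are up-regulated in BOTH datasets.

    Returns a DataFrame indexed by gene_id with columns ``mirnas`` (sorted
    tuple of regulating lead miRNAs) and one up-fold column per dataset.
    Row order of the interaction table does not matter.
    """
    if min_coregulators < 1:
        raise ConfigurationError("min_coregulators must be >= 1")
    regulators: dict[str, set[str]] = {}
    for m in down_mirnas:
        for g in interactions.targets_of(m):
            regulators.setdefault(g, set()).add(m)
    u1, u2 = ds1.up_magnitude(), ds2.up_magnitude()
    rows = []
    for g in sorted(regulators):
        if len(regulators[g]) < min_coregulators:
            continue
        if g in u1.index and g in u2.index:
            rows.append(
                {
                    "gene_id": g,
                    "mirnas": tuple(sorted(regulators[g])),
                    u1.name: u1[g],
                    u2.name: u2[g],
                }
            )
    cols = ["gene_id", "mirnas", u1.name, u2.name]
    return pd.DataFrame(rows, columns=cols).set_index("gene_id")


def annotate_regulator(
    genes: Iterable[str], regulator_annotation: Mapping[str, bool]
) -> tuple[list[str], int, list[str]]:
    """Subset of ``genes`` flagged True in the annotation map, plus count.

    Genes missing from the map count as not annotated and are returned in
    the warning list.
    """
    genes = list(genes)
    annotated = sorted(g for g in genes if regulator_annotation.get(g, False))
    missing = sorted(g for g in genes if g not in regulator_annotation)
    return annotated, len(annotated), missing


@dataclass
class IntegrationResult:
    """Bundle of the cross-dataset screens for reporting."""

    common_down: pd.DataFrame
    high_magnitude: pd.DataFrame
    reciprocal: pd.DataFrame
    regulator_annotated: list[str]
    regulator_annotated_count: int
    annotation_warnings: list[str] = field(default_factory=list)


def integrate(
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    interactions: InteractionTable,
    down_mirnas: Sequence[str],
    regulator_annotation: Mapping[str, bool] | None = None,
    fold_cutoff: float = 2.0,
    magnitude_cutoff: float = 10.0,
    min_coregulators: int = 2,
) -> IntegrationResult:
    """Run the full reciprocal-regulation integration in one call."""
    common = common_downregulated(ds1, ds2, fold_cutoff)
    high = high_magnitude_subset(common, magnitude_cutoff)
    recip = reciprocal_targets(down_mirnas, interactions, ds1, ds2, min_coregulators)
    if regulator_annotation is not None:
        annotated, count, warn = annotate_regulator(common.index, regulator_annotation)
    else:
        annotated, count, warn = [], 0, []
    return IntegrationResult(
        common_down=common,
        high_magnitude=high,
        reciprocal=recip,
        regulator_annotated=annotated,
        regulator_annotated_count=count,
        annotation_warnings=warn,
    )
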