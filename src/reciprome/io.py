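"""Plain-text readers and writers for every pipeline input/output.

Formats (all uncompressed text):

* count matrix CSV — columns ``probe_id, probe_class, <sample>...`` plus a
  companion samples TSV ``sample<TAB>group``;
* RCC-dialect per-sample CSV — ``CodeClass,Name,Count`` rows as exported
  by digital-counter instruments;
* expression TSV — ``gene_id, fold_change, direction`` (optional probe_id);
* interaction TSV — ``mirna, target_gene`` (optional evidence);
* promoter TSV — ``mirna, tf, distance_bp`` (signed, upstream negative);
* Ct TSV — ``sample, group, assay, replicate, ct``;
* GMT — ``name<TAB>description<TAB>member...``;
* ranked-list TSV — ``gene<TAB>score``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError
from .integration import ExpressionDataset, InteractionTable
from .nanostring import MirnaCountMatrix
from .promoter import PromoterAnnotation
from .qpcr import CtTable

_RCC_CLASS = {
    "Endogenous": "endogenous",
    "Positive": "positive_control",
    "Negative": "negative_control",
}


def write_counts(matrix: MirnaCountMatrix, counts_csv: str | Path, samples_tsv: str | Path) -> None:
    out = matrix.counts.astype(int).copy()
    out.insert(0, "probe_class", matrix.probe_class)
    out.index.name = "probe_id"
    out.to_csv(counts_csv)
    matrix.sample_groups.rename("group").rename_axis("sample").to_csv(
        samples_tsv, sep="\t"
    )


def read_counts(counts_csv: str | Path, samples_tsv: str | Path) -> MirnaCountMatrix:
    df = pd.read_csv(counts_csv, index_col="probe_id")
    if "probe_class" not in df.columns:
        raise ConfigurationError("count CSV needs a probe_class column")
    probe_class = df.pop("probe_class")
    groups = pd.read_csv(samples_tsv, sep="\t", index_col="sample")["group"]
    return MirnaCountMatrix(counts=df, probe_class=probe_class, sample_groups=groups)


def read_rcc_csv(path: str | Path) -> pd.DataFrame:
    """One RCC-dialect sample file -> DataFrame(probe_id, probe_class, count)."""
    df = pd.read_csv(path)
    need = {"CodeClass", "Name", "Count"}
    if not need.issubset(df.columns):
        raise ConfigurationError(f"{path}: RCC CSV needs columns {sorted(need)}")
    cls = df["CodeClass"].map(_RCC_CLASS)
    keep = cls.notna()
    return pd.DataFrame(
        {
            "probe_id": df.loc[keep, "Name"].to_numpy(),
            "probe_class": cls[keep].to_numpy(),
            "count": df.loc[keep, "Count"].astype(int).to_numpy(),
        }
    )


def read_rcc_samples(
    files: Mapping[str, str | Path], groups: Mapping[str, str]
) -> MirnaCountMatrix:
    """Merge per-sample RCC-dialect CSVs into one count matrix.

    ``files`` maps sample id -> path; ``groups`` maps sample id -> group.
    """
    cols = {}
    probe_class = None
    for sample, path in files.items():
        tab = read_rcc_csv(path).set_index("probe_id")
        cols[sample] = tab["count"]
        pc = tab["probe_class"]
        if probe_class is None:
            probe_class = pc
        elif not probe_class.equals(pc.reindex(probe_class.index)):
            raise ConfigurationError(f"{path}: probe annotation differs between files")
    counts = pd.DataFrame(cols)
    missing = [s for s in files if s not in groups]
    if missing:
        raise ConfigurationError(f"no group for samples: {missing}")
    return MirnaCountMatrix(
        counts=counts,
        probe_class=probe_class,
        sample_groups=pd.Series({s: groups[s] for s in files}),
    )


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    ds.records.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, name: str | None = None, dialect: str = "ratio") -> ExpressionDataset:
    df = pd.read_csv(path, sep="\t")
    return ExpressionDataset.from_fold_table(name or Path(path).stem, df, dialect=dialect)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> InteractionTable:
    return InteractionTable(pd.read_csv(path, sep="\t"))


def write_promoter_sites(ann: PromoterAnnotation, path: str | Path) -> None:
    ann.sites.to_csv(path, sep="\t", index=False)


def read_promoter_sites(path: str | Path, source: str = "") -> PromoterAnnotation:
    return PromoterAnnotation(pd.read_csv(path, sep="\t"), source=source or str(path))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path, reference_assay: str) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"), reference_assay=reference_assay)


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, members)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    scores.rename("score").rename_axis("gene").to_csv(path, sep="\t")


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]
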