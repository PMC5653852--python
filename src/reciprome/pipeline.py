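"""End-to-end orchestration: simulate or ingest -> screen -> promoter filter
-> ddCt validation -> reciprocal integration -> enrichment.

The pipeline is a plain function over a serializable config.  Every stage
writes its table under the output directory, the report echoes the config
(with a content hash) for provenance, and a rerun with the same config and
seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, nanostring, promoter, qpcr, synthetic
from .enrichment import GeneSetCollection, RankedList, normalize_and_fdr, overrepresentation
from .errors import ConfigurationError, ReciromeError
from .integration import integrate
from .synthetic import (
    INTEGRATION_LEADS,
    LEAD_MIRNAS,
    NEGATIVE_CONTROL_MIRNA,
    NoiseModel,
    StudyDesign,
)

log = logging.getLogger("reciprome")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds, seed and (optionally) input paths for one pipeline run.

    With ``simulate=True`` (default) all inputs are generated from the
    frozen AAT-study conditions in :mod:`reciprome.synthetic`; otherwise
    the ``*_path`` fields must point at the corresponding text files.
    """

    outdir: str = "reciprome_out"
    seed: int = 0
    simulate: bool = True
    plant_effects: bool = True  # False = null simulation (no true signals)
    # input paths (used when simulate=False)
    counts_path: str | None = None
    samples_path: str | None = None
    ds1_path: str | None = None
    ds2_path: str | None = None
    interactions_path: str | None = None
    promoter_path: str | None = None
    ct_path: str | None = None
    gmt_path: str | None = None
    # thresholds
    detect_fold: float = 1.5
    screen_fold: float = 3.0
    n_perm: int = 10_000
    alpha: float = 0.05
    qpcr_family: int = 3
    tfbs_min_dist: int = 100
    tfbs_max_dist: int = 10_000
    down_fold_cutoff: float = 2.0
    high_magnitude_cutoff: float = 10.0
    min_coregulators: int = 2
    gsea_perms: int = 500
    reference_assay: str = "U6"
    lead_mirnas: tuple[str, ...] = LEAD_MIRNAS
    integration_leads: tuple[str, ...] = INTEGRATION_LEADS

    def __post_init__(self) -> None:
        for name in (
            "detect_fold",
            "screen_fold",
            "alpha",
            "down_fold_cutoff",
            "high_magnitude_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_perm < 1 or self.gsea_perms < 100:
            raise ConfigurationError("permutation counts out of range")
        if not (0 <= self.tfbs_min_dist < self.tfbs_max_dist):
            raise ConfigurationError("TFBS window must satisfy 0 <= min < max")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["lead_mirnas"] = list(self.lead_mirnas)
        d["integration_leads"] = list(self.integration_leads)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key in ("lead_mirnas", "integration_leads"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(d) - known
        if stray:
            raise ConfigurationError(f"unknown config keys: {sorted(stray)}")
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Per-stage summaries plus provenance; serializes to report.json."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "provenance": self.provenance,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> dict:
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    design = synthetic.aat_study_design(seed=int(seeds[0]))
    effects = synthetic.aat_mirna_effects() if config.plant_effects else []
    counts = synthetic.generate_mirna_counts(design, effects)
    if config.plant_effects:
        truth = synthetic.aat_gene_truth(seed=int(seeds[1]))
    else:
        truth = {"down_genes": {}, "up_genes": {}, "nfkb_annotation": {}}
    ds1, ds2 = synthetic.generate_expression_datasets(
        truth["up_genes"], truth["down_genes"], seed=int(seeds[2])
    )
    interactions = synthetic.generate_interaction_table(synthetic.aat_interaction_map())
    sites = synthetic.generate_promoter_annotations(synthetic.aat_promoter_sites())
    qpcr_design = synthetic.aat_study_design(seed=int(seeds[3]), n_per_group=4)
    ct = synthetic.generate_ct_table(
        qpcr_design,
        targets=[*LEAD_MIRNAS, NEGATIVE_CONTROL_MIRNA],
        reference=config.reference_assay,
        planted_fold=synthetic.aat_qpcr_folds() if config.plant_effects else {},
    )
    if config.plant_effects:
        gene_sets = synthetic.aat_gene_sets(truth, seed=int(seeds[1]))
    else:
        rng = np.random.default_rng(int(seeds[1]))
        bg = [f"BG{i + 1:05d}" for i in range(2000)]
        gene_sets = {
            f"DECOY_SET_{i + 1:02d}": sorted(rng.choice(bg, size=80, replace=False))
            for i in range(50)
        }

    io.write_counts(counts, outdir / "counts.csv", outdir / "samples.tsv")
    io.write_expression(ds1, outdir / "expression_day2_vs_day0.tsv")
    io.write_expression(ds2, outdir / "expression_exvivo_aat_vs_ctrl.tsv")
    io.write_interactions(interactions, outdir / "interactions.tsv")
    io.write_promoter_sites(sites, outdir / "promoter_sites.tsv")
    io.write_ct_table(ct, outdir / "ct_table.tsv")
    io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    return {
        "counts": counts,
        "ds1": ds1,
        "ds2": ds2,
        "interactions": interactions,
        "sites": sites,
        "ct": ct,
        "gene_sets": gene_sets,
        "nfkb_annotation": truth["nfkb_annotation"],
    }


def _load_inputs(config: PipelineConfig) -> dict:
    required = {
        "counts_path": config.counts_path,
        "samples_path": config.samples_path,
        "ds1_path": config.ds1_path,
        "ds2_path": config.ds2_path,
        "interactions_path": config.interactions_path,
        "promoter_path": config.promoter_path,
        "ct_path": config.ct_path,
        "gmt_path": config.gmt_path,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ConfigurationError(f"simulate=False but inputs missing: {missing}")
    return {
        "counts": io.read_counts(config.counts_path, config.samples_path),
        "ds1": io.read_expression(config.ds1_path, "DAY2_VS_DAY0"),
        "ds2": io.read_expression(config.ds2_path, "EXVIVO_AAT_VS_CTRL"),
        "interactions": io.read_interactions(config.interactions_path),
        "sites": io.read_promoter_sites(config.promoter_path),
        "ct": io.read_ct_table(config.ct_path, config.reference_assay),
        "gene_sets": io.read_gmt(config.gmt_path),
        "nfkb_annotation": None,
    }


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in dependency order; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(
        provenance={
            "config": json.loads(config.to_json()),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        }
    )

    stage = "inputs"
    try:
        inputs = _simulate_inputs(config, outdir) if config.simulate else _load_inputs(config)
        log.info("stage=%s simulate=%s seed=%d", stage, config.simulate, config.seed)

        stage = "normalize"
        norm = nanostring.normalize_counts(inputs["counts"])
        report.stages["normalize"] = {
            "n_probes": int(inputs["counts"].counts.shape[0]),
            "n_detected": int(norm.detected.sum()),
        }

        stage = "screen"
        screens = {}
        for contrast in (("ZZ_ASYMP", "MM"), ("ZZ_DAY2", "ZZ_DAY0")):
            key = f"{contrast[0]}_vs_{contrast[1]}"
            results = nanostring.compare_groups(
                norm, *contrast, n_perm=config.n_perm, seed=config.seed
            )
            hits = nanostring.screen(results, config.screen_fold)
            hits.rename_axis("feature").to_csv(outdir / f"screen_{key}.tsv", sep="\t")
            screens[key] = hits
            report.stages[f"screen_{key}"] = {
                "fold_cutoff": config.screen_fold,
                "n_screened": int(len(hits)),
                "n_up": int((hits["direction"] == "up").sum()),
                "n_down": int((hits["direction"] == "down").sum()),
                "n_detect_1_5x": int(nanostring.screen(results, config.detect_fold).shape[0]),
            }
            log.info("stage=screen contrast=%s hits=%d", key, len(hits))

        stage = "promoter"
        calls = promoter.classify_regulated(
            inputs["sites"],
            tf="NFKB",
            window=(config.tfbs_min_dist, config.tfbs_max_dist),
        )
        zz_screen = list(screens["ZZ_ASYMP_vs_MM"].index)
        candidates = promoter.intersect_with_screen(calls, zz_screen)
        pd.DataFrame(
            [dataclasses.asdict(c) for c in calls]
        ).to_csv(outdir / "regulation_calls.tsv", sep="\t", index=False)
        report.stages["promoter"] = {
            "tf": "NFKB",
            "window_bp": [config.tfbs_min_dist, config.tfbs_max_dist],
            "n_calls": len(calls),
            "candidates": candidates,
            "n_candidates": len(candidates),
        }

        stage = "qpcr"
        ct = inputs["ct"]
        assays = [a for a in ct.assays if a != ct.reference_assay]
        qrows = []
        for assay in assays:
            rel = qpcr.assess_relative_expression(
                ct, assay, "ZZ_ASYMP", "MM",
                family_size=config.qpcr_family, alpha=config.alpha,
            )
            qrows.append(
                {
                    "assay": assay,
                    "contrast": "ZZ_ASYMP_vs_MM",
                    "ddct": rel.delta_delta_ct,
                    "fold": rel.fold,
                    "p": rel.p_value,
                    "significant": rel.significant,
                }
            )
        qdf = pd.DataFrame(qrows)
        qdf.to_csv(outdir / "qpcr_results.tsv", sep="\t", index=False)
        report.stages["qpcr"] = {
            "reference": ct.reference_assay,
            "family_size": config.qpcr_family,
            "threshold": round(qpcr.bonferroni_threshold(config.alpha, config.qpcr_family), 4),
            "folds": {r["assay"]: r["fold"] for r in qrows},
            "n_assays": len(qrows),
        }

        stage = "integration"
        res = integrate(
            inputs["ds1"],
            inputs["ds2"],
            inputs["interactions"],
            down_mirnas=list(config.integration_leads),
            regulator_annotation=inputs["nfkb_annotation"],
            fold_cutoff=config.down_fold_cutoff,
            magnitude_cutoff=config.high_magnitude_cutoff,
            min_coregulators=config.min_coregulators,
        )
        res.common_down.rename_axis("gene_id").to_csv(outdir / "common_down.tsv", sep="\t")
        res.high_magnitude.rename_axis("gene_id").to_csv(outdir / "high_magnitude.tsv", sep="\t")
        recip_out = res.reciprocal.copy()
        if len(recip_out):
            recip_out["mirnas"] = recip_out["mirnas"].map(lambda t: ",".join(t))
        recip_out.to_csv(outdir / "reciprocal_targets.tsv", sep="\t")
        report.stages["integration"] = {
            "n_common_down": int(len(res.common_down)),
            "n_high_magnitude": int(len(res.high_magnitude)),
            "high_magnitude_genes": sorted(res.high_magnitude.index),
            "reciprocal_targets": sorted(res.reciprocal.index),
            "n_reciprocal": int(len(res.reciprocal)),
            "n_regulator_annotated": int(res.regulator_annotated_count)
            if inputs["nfkb_annotation"] is not None
            else None,
        }

        stage = "enrichment"
        # rank dataset-1 genes by signed log2 fold change, descending:
        # genes decreased by therapy concentrate at the bottom
        scores = np.log2(
            inputs["ds1"].records.groupby("gene_id")["fold_change"].min()
        )
        ranked = RankedList.from_scores(scores, weight_exponent=1.0)
        collection = GeneSetCollection.from_dict(inputs["gene_sets"])
        gsea = normalize_and_fdr(
            ranked, collection, n_perm=config.gsea_perms, seed=config.seed
        )
        gsea.to_csv(outdir / "enrichment_gsea.tsv", sep="\t")
        ora = overrepresentation(
            res.high_magnitude.index,
            sorted(inputs["ds1"].genes() | inputs["ds2"].genes()),
            collection,
            alpha=config.alpha,
        ) if len(res.high_magnitude) else pd.DataFrame()
        if len(ora):
            ora.to_csv(outdir / "enrichment_ora.tsv", sep="\t")
        top_neg = gsea[gsea["nes"] < 0].sort_values("nes")
        report.stages["enrichment"] = {
            "n_sets": int(len(gsea)),
            "n_perm": config.gsea_perms,
            "top_negative_set": top_neg.index[0] if len(top_neg) else None,
            "top_negative_nes": float(top_neg["nes"].iloc[0]) if len(top_neg) else None,
            "top_negative_fdr_q": float(top_neg["fdr_q"].iloc[0]) if len(top_neg) else None,
            "n_ora_significant": int(ora["significant"].sum()) if len(ora) else 0,
        }
    except ReciromeError as err:
        raise type(err)(f"stage {stage!r} failed: {err}") from err

    (outdir / "report.json").write_text(report.to_json())
    return report
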