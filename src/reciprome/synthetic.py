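"""Synthetic inputs with the statistical structure of an AAT augmentation
monocyte study.

Generates every input the pipeline consumes — probe-level miRNA count
matrices with positive/negative control probes, gene-level fold-change
tables for two treatment contrasts, a validated miRNA->target interaction
table, promoter TFBS annotations, replicate Ct tables and a hallmark-style
gene-set collection — with planted ground truth, so every downstream stage
can be tested end to end without any external download.

Modelling choices (minimal standard forms; see docs/methods.md):

* counts: negative binomial with mean ``m`` and variance ``m + d*m**2``
  (``d`` = dispersion); ``d = 0`` gives the deterministic limit
  ``count = round(m)`` used by exact-recovery properties;
* per-sample technical scale factors: log-normal around 1, recovered by
  positive-control normalization;
* Ct noise: additive Gaussian per replicate on the Ct scale, plus a
  per-sample RNA-input offset common to all assays (cancels in dCt);
* planted fold changes multiply the numerator group's mean before noise.

The ``aat_*`` factory functions freeze the study conditions emulated here:
five monocyte groups (MM, asymptomatic ZZ, symptomatic ZZ at Day 0 and
Day 2 of weekly augmentation therapy, and ex vivo AAT vs control), n = 3
per group for profiling and n = 4 for qPCR, 731 probes of which roughly
400 are detectable, lead miRNAs planted at 40x/17x/12x (profiling) and
22x/28x/16x (qPCR), 334 commonly down-regulated genes of which 294 are
NF-kB-annotated and 8 exceed 10-fold in both datasets, and reciprocally
up-regulated targets EIF4H and HNRNPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .integration import ExpressionDataset, InteractionTable
from .nanostring import (
    ENDOGENOUS,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    MirnaCountMatrix,
)
from .promoter import PromoterAnnotation
from .qpcr import CtTable

DEFAULT_GROUPS = (
    "MM",
    "ZZ_ASYMP",
    "ZZ_DAY0",
    "ZZ_DAY2",
    "ZZ_EXVIVO_AAT",
    "ZZ_EXVIVO_CTRL",
)

# nominal positive-control ladder (counts at scale factor 1)
_POS_LADDER = (32.0, 128.0, 512.0, 2048.0, 8192.0, 32768.0)


@dataclass(frozen=True)
class StudyDesign:
    """Group structure and probe-universe size of a simulated study."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 3
    n_features: int = 731
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("group labels must be unique")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_pos_controls < 0 or self.n_neg_controls < 0:
            raise ConfigurationError("control probe counts must be >= 0")

    def samples(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs, deterministic order."""
        return [
            (f"{g}_{i + 1}", g) for g in self.groups for i in range(self.n_per_group)
        ]


@dataclass(frozen=True)
class PlantedEffect:
    """A true fold change for one feature in one ordered group contrast.

    ``true_fold_change`` multiplies the numerator group's mean relative to
    the feature baseline carried by every other group (values < 1 plant a
    decrease).  Effects on different groups compose independently.
    """

    feature_id: str
    contrast: tuple[str, str]
    true_fold_change: float

    def __post_init__(self) -> None:
        if self.true_fold_change <= 0:
            raise ConfigurationError("true_fold_change must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the generators.

    baseline_mean: floor for planted features' baseline counts (and the
    location of the detectable-feature abundance distribution).
    dispersion: NB overdispersion d with var = m + d*m^2; 0 = deterministic.
    ct_sd: per-replicate Gaussian SD on the Ct scale; 0 = noiseless.
    scale_sigma: log-SD of per-sample technical scale factors.
    background_mean: negative-control (non-specific binding) mean count.
    """

    baseline_mean: float = 300.0
    dispersion: float = 0.005
    ct_sd: float = 0.25
    scale_sigma: float = 0.15
    background_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")
        if self.dispersion < 0 or self.ct_sd < 0 or self.scale_sigma < 0:
            raise ConfigurationError("noise magnitudes must be >= 0")
        if self.background_mean < 0:
            raise ConfigurationError("background_mean must be >= 0")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) counts; Poisson at d=0 was rejected in favour of
    the deterministic limit so that planted truths are exactly recoverable."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.round(mean).astype(int)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=int)
    nz = mean > 0
    out[nz] = rng.negative_binomial(size, p[nz])
    return out


def generate_mirna_counts(
    design: StudyDesign,
    effects: Sequence[PlantedEffect] = (),
    noise: NoiseModel = NoiseModel(),
    detectable_fraction: float = 398 / 731,
) -> MirnaCountMatrix:
    """Simulate a raw probe x sample count matrix with control probes.

    Endogenous probe ids are the planted features (in input order) followed
    by filler ``miR-sim-####`` probes up to ``design.n_features``.  A
    ``detectable_fraction`` of the features (always including planted ones)
    receive log-normal baseline means around ``noise.baseline_mean``
    (planted features are floored at ``baseline_mean`` so effect recovery
    is not Poisson-limited); the remainder sit below background.
    """
    rng = np.random.default_rng(design.seed)
    planted_ids = list(dict.fromkeys(e.feature_id for e in effects))
    if len(planted_ids) > design.n_features:
        raise ConfigurationError("more planted features than n_features")
    for e in effects:
        for g in e.contrast:
            if g not in design.groups:
                raise ConfigurationError(
                    f"effect on {e.feature_id!r}: unknown group {g!r}"
                )
    n_filler = design.n_features - len(planted_ids)
    features = planted_ids + [f"miR-sim-{i:04d}" for i in range(1, n_filler + 1)]

    n_detect = max(len(planted_ids), int(round(detectable_fraction * design.n_features)))
    detectable = np.zeros(design.n_features, dtype=bool)
    detectable[: len(planted_ids)] = True
    extra = rng.choice(
        np.arange(len(planted_ids), design.n_features),
        size=n_detect - len(planted_ids),
        replace=False,
    )
    detectable[extra] = True

    baseline = np.where(
        detectable,
        noise.baseline_mean * rng.lognormal(0.0, 1.0, design.n_features),
        0.2,
    )
    baseline[: len(planted_ids)] = np.maximum(
        baseline[: len(planted_ids)], noise.baseline_mean
    )

    samples = design.samples()
    group_of = {s: g for s, g in samples}
    # per-feature per-group multiplicative effect
    fold = {g: np.ones(design.n_features) for g in design.groups}
    index_of = {f: i for i, f in enumerate(features)}
    for e in effects:
        fold[e.contrast[0]][index_of[e.feature_id]] *= e.true_fold_change

    scale = (
        rng.lognormal(0.0, noise.scale_sigma, len(samples))
        if noise.scale_sigma > 0
        else np.ones(len(samples))
    )

    cols = {}
    for j, (s, g) in enumerate(samples):
        mean = baseline * fold[g] * scale[j]
        cols[s] = _nb_counts(rng, mean, noise.dispersion)
    endo = pd.DataFrame(cols, index=features)

    pos_ids = [f"POS_{chr(65 + i)}" for i in range(design.n_pos_controls)]
    ladder = np.array(
        [_POS_LADDER[i % len(_POS_LADDER)] for i in range(design.n_pos_controls)]
    )
    pos = pd.DataFrame(
        {
            s: _nb_counts(rng, ladder * scale[j], noise.dispersion)
            for j, (s, _) in enumerate(samples)
        },
        index=pos_ids,
    )
    neg_ids = [f"NEG_{chr(65 + i)}" for i in range(design.n_neg_controls)]
    neg = pd.DataFrame(
        {
            s: _nb_counts(
                rng, np.full(design.n_neg_controls, noise.background_mean), noise.dispersion
            )
            for s, _ in samples
        },
        index=neg_ids,
    )

    counts = pd.concat([endo, pos, neg])
    probe_class = pd.Series(
        [ENDOGENOUS] * len(features)
        + [POSITIVE_CONTROL] * len(pos_ids)
        + [NEGATIVE_CONTROL] * len(neg_ids),
        index=counts.index,
    )
    sample_groups = pd.Series({s: g for s, g in samples})
    return MirnaCountMatrix(counts=counts, probe_class=probe_class, sample_groups=sample_groups)


def generate_expression_datasets(
    up_genes: Mapping[str, tuple[float, float]],
    down_genes: Mapping[str, tuple[float, float]],
    n_background: int = 2000,
    seed: int = 0,
    names: tuple[str, str] = ("DAY2_VS_DAY0", "EXVIVO_AAT_VS_CTRL"),
    planted_sd_log2: float = 0.05,
    background_sd_log2: float = 0.3,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Two gene-level fold-change tables with planted up/down genes.

    ``up_genes``/``down_genes`` map gene -> (fold in dataset 1, fold in
    dataset 2) as magnitudes >= or close to 1 (a magnitude of 1 leaves the
    gene at background in that dataset).  Down folds are stored as ratios
    1/fold.  Planted folds are jittered by ``planted_sd_log2`` and
    background genes are centred on a ratio of 1.
    """
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise ConfigurationError(f"genes in both up and down maps: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    tables: list[pd.DataFrame] = []
    for k, name in enumerate(names):
        rows = []
        for g, folds in up_genes.items():
            ratio = folds[k] * 2.0 ** rng.normal(0.0, planted_sd_log2)
            rows.append({"gene_id": g, "fold_change": ratio})
        for g, folds in down_genes.items():
            ratio = (1.0 / folds[k]) * 2.0 ** rng.normal(0.0, planted_sd_log2)
            rows.append({"gene_id": g, "fold_change": ratio})
        for i in range(n_background):
            rows.append(
                {
                    "gene_id": f"BG{i + 1:05d}",
                    "fold_change": 2.0 ** rng.normal(0.0, background_sd_log2),
                }
            )
        tables.append(pd.DataFrame(rows))
    return (
        ExpressionDataset(name=names[0], records=tables[0]),
        ExpressionDataset(name=names[1], records=tables[1]),
    )


def generate_interaction_table(
    mirna_targets: Mapping[str, Iterable[str]],
) -> InteractionTable:
    """Validated-interaction stand-in: one deduplicated row per pair."""
    return InteractionTable.from_target_map(mirna_targets)


def generate_promoter_annotations(
    site_map: Mapping[str, Sequence[tuple[str, int]]],
) -> PromoterAnnotation:
    """TFBS annotation preserving all (TF, signed distance) sites."""
    return PromoterAnnotation.from_site_map(site_map, source="synthetic")


def generate_ct_table(
    design: StudyDesign,
    targets: Sequence[str],
    reference: str,
    planted_fold: Mapping[tuple[str, tuple[str, str]], float],
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    seed: int | None = None,
) -> CtTable:
    """Replicate Ct table where a planted fold f for (assay, (A, B)) shifts
    the target's Ct by -log2(f) in group A (dCt moves by -log2(f), so
    2^-ddCt recovers f).

    Each sample carries a common RNA-input offset on all assays (cancels in
    dCt) and each replicate independent N(0, ct_sd) noise.
    """
    if reference in targets:
        raise ConfigurationError("reference assay must not be a target assay")
    for (assay, (ga, gb)), f in planted_fold.items():
        if assay not in targets:
            raise ConfigurationError(f"planted fold for unknown assay {assay!r}")
        if ga not in design.groups or gb not in design.groups:
            raise ConfigurationError(f"planted fold references unknown group {ga!r}/{gb!r}")
        if f <= 0:
            raise ConfigurationError("planted folds must be > 0")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    base_ct = {reference: 20.0}
    for i, assay in enumerate(targets):
        base_ct[assay] = 25.0 + 0.5 * i
    shift = {(a, g): 0.0 for a in targets for g in design.groups}
    for (assay, (ga, _gb)), f in planted_fold.items():
        shift[(assay, ga)] -= np.log2(f)

    rows = []
    for s, g in design.samples():
        offset = rng.normal(0.0, 0.5)
        for assay in [reference, *targets]:
            mu = base_ct[assay] + offset + (shift.get((assay, g), 0.0))
            for r in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0.0, noise.ct_sd) if noise.ct_sd > 0 else 0.0)
                rows.append(
                    {"sample": s, "group": g, "assay": assay, "replicate": r, "ct": ct}
                )
    return CtTable(data=pd.DataFrame(rows), reference_assay=reference)


# ---------------------------------------------------------------------------
# Frozen study conditions: the AAT augmentation-therapy monocyte design
# ---------------------------------------------------------------------------

LEAD_MIRNAS = ("hsa-miR-199a-5p", "hsa-miR-598", "hsa-miR-320a")
NEGATIVE_CONTROL_MIRNA = "hsa-miR-30a-5p"
# Fig-3-style lead list for target integration: the -3p arm of the miR-199a
# hairpin carries the validated co-regulated targets
INTEGRATION_LEADS = ("hsa-miR-199a-3p", "hsa-miR-320a", "hsa-miR-598")

HIGH_MAGNITUDE_GENES = (
    "ABLIM3",
    "CCL11",
    "DNAJC14",
    "FAHD1",
    "IL17RC",
    "LOC100287482",
    "RHD",
    "TPD52L2",
)
RECIPROCAL_GENES = ("EIF4H", "HNRNPU")

N_COMMON_DOWN = 334
N_NFKB_ANNOTATED = 294
N_SCREEN_3X_ZZ_VS_MM = 21
N_SCREEN_3X_DAY2_VS_DAY0 = 11
N_DECREASED_DAY2_VS_DAY0 = 7


def aat_study_design(seed: int = 0, n_per_group: int = 3) -> StudyDesign:
    """Default five-arm profiling design: 731 probes, n = 3 per group."""
    return StudyDesign(seed=seed, n_per_group=n_per_group)


def aat_mirna_effects() -> list[PlantedEffect]:
    """Planted profiling truth.

    ZZ_ASYMP vs MM: the three lead miRNAs at 40x/17x/12x plus 18 filler
    features beyond 3-fold (14 up at 4.5-9x, 4 down) — 21 in total.
    ZZ_DAY2 vs ZZ_DAY0: 11 features altered >3-fold, 7 of them decreased
    (including miR-199a-5p, restored to below the MM baseline after
    infusion, and miR-598), with miR-30a-5p among the 4 increased.
    """
    eff: list[PlantedEffect] = [
        PlantedEffect("hsa-miR-199a-5p", ("ZZ_ASYMP", "MM"), 40.0),
        PlantedEffect("hsa-miR-598", ("ZZ_ASYMP", "MM"), 17.0),
        PlantedEffect("hsa-miR-320a", ("ZZ_ASYMP", "MM"), 12.0),
        # therapy arms, relative to the MM-level baseline:
        # miR-199a-5p: 8x below asymptomatic ZZ at Day 0, 50x below at Day 2
        PlantedEffect("hsa-miR-199a-5p", ("ZZ_DAY0", "MM"), 40.0 / 8.0),
        PlantedEffect("hsa-miR-199a-5p", ("ZZ_DAY2", "MM"), 40.0 / 50.0),
        # miR-598: unchanged at Day 0, 4x decrease at Day 2
        PlantedEffect("hsa-miR-598", ("ZZ_DAY0", "MM"), 17.0),
        PlantedEffect("hsa-miR-598", ("ZZ_DAY2", "MM"), 17.0 / 4.0),
        # miR-320a: elevated in all ZZ arms, not changed by therapy
        PlantedEffect("hsa-miR-320a", ("ZZ_DAY0", "MM"), 12.0),
        PlantedEffect("hsa-miR-320a", ("ZZ_DAY2", "MM"), 12.0),
        # miR-30a-5p: flat in ZZ vs MM, 4x increased at Day 2
        PlantedEffect("hsa-miR-30a-5p", ("ZZ_DAY2", "ZZ_DAY0"), 4.0),
    ]
    # 18 fillers >3-fold in ZZ_ASYMP vs MM (14 up, 4 down)
    for i in range(14):
        eff.append(
            PlantedEffect(f"miR-zz-up-{i + 1:02d}", ("ZZ_ASYMP", "MM"), 4.5 + 0.3 * i)
        )
    for i in range(4):
        eff.append(
            PlantedEffect(f"miR-zz-dn-{i + 1:02d}", ("ZZ_ASYMP", "MM"), 1.0 / (4.5 + i))
        )
    # Day 2 vs Day 0 fillers: 5 more decreased, 3 more increased
    for i in range(5):
        eff.append(
            PlantedEffect(f"miR-d2-dn-{i + 1:02d}", ("ZZ_DAY0", "MM"), 4.5 + 0.5 * i)
        )
    for i in range(3):
        eff.append(
            PlantedEffect(f"miR-d2-up-{i + 1:02d}", ("ZZ_DAY2", "MM"), 5.0 + 0.5 * i)
        )
    return eff


def aat_gene_truth(seed: int = 0) -> dict:
    """Planted gene-level truth for the two expression contrasts.

    334 genes down >= 2-fold in both datasets, of which exactly the 8
    named high-magnitude genes exceed 10-fold in both and 294 (the 8
    included) carry an NF-kB-regulated annotation; EIF4H and HNRNPU up in
    both datasets; decoy targets up in only one dataset.
    """
    rng = np.random.default_rng(seed)
    down: dict[str, tuple[float, float]] = {}
    for g in HIGH_MAGNITUDE_GENES:
        down[g] = (float(rng.uniform(12.0, 40.0)), float(rng.uniform(12.0, 40.0)))
    for i in range(N_COMMON_DOWN - len(HIGH_MAGNITUDE_GENES)):
        down[f"DN{i + 1:04d}"] = (
            float(rng.uniform(2.5, 9.0)),
            float(rng.uniform(2.5, 9.0)),
        )
    up: dict[str, tuple[float, float]] = {
        "EIF4H": (8.0, 4.0),
        "HNRNPU": (5.0, 3.0),
        # decoy targets: up in one dataset only, or up in both but with a
        # single lead regulator
        "MAN1A2": (3.0, 1.0),
        "HSP90AA1": (1.0, 3.5),
        "EDEM1": (4.0, 1.0),
        # NFKB1 is targeted by two leads, so it must be unambiguously
        # non-increased in dataset 1 (0.45 = 2.2-fold down) to stay out of
        # the reciprocal set
        "NFKB1": (0.45, 2.5),
        "RELA": (2.5, 1.0),
        "SINGLE1": (3.0, 3.0),
        "SINGLE2": (2.8, 2.2),
    }
    genes = list(down)
    nfkb_true = set(HIGH_MAGNITUDE_GENES) | set(
        rng.choice(
            [g for g in genes if g not in HIGH_MAGNITUDE_GENES],
            size=N_NFKB_ANNOTATED - len(HIGH_MAGNITUDE_GENES),
            replace=False,
        )
    )
    nfkb_annotation = {g: (g in nfkb_true) for g in genes}
    return {"down_genes": down, "up_genes": up, "nfkb_annotation": nfkb_annotation}


def aat_interaction_map() -> dict[str, set[str]]:
    """Validated-target stand-in keyed by mature miRNA arm.

    EIF4H and HNRNPU are co-regulated by miR-199a-3p and miR-320a (and by
    no third lead); the remaining targets either sit on a single lead or
    fail the both-datasets-up requirement.
    """
    return {
        "hsa-miR-199a-3p": {"EIF4H", "HNRNPU", "NFKB1", "RELA", "SINGLE1"},
        "hsa-miR-320a": {"EIF4H", "HNRNPU", "EDEM1", "SINGLE2"},
        "hsa-miR-598": {"MAN1A2", "NFKB1"},
        "hsa-miR-199a-5p": {"NFKB1", "RELA", "HSP90AA1"},
    }


def aat_promoter_sites() -> dict[str, list[tuple[str, int]]]:
    """NF-kB site annotation: three leads in the functional window, the
    miR-30a site inside the too-close exclusion zone."""
    return {
        "hsa-miR-199a-5p": [("NFKB", -1800)],
        "hsa-miR-598": [("NFKB", -520), ("SP1", -60)],
        "hsa-miR-320a": [("NFKB", -3200)],
        "hsa-miR-30a-5p": [("NFKB", -45)],
        "miR-zz-up-01": [("SP1", -900)],
    }


def aat_qpcr_folds() -> dict[tuple[str, tuple[str, str]], float]:
    """Planted qPCR truth, ZZ_ASYMP vs MM: 22x/28x/16x for the leads and
    5x for the miR-30a negative control."""
    return {
        ("hsa-miR-199a-5p", ("ZZ_ASYMP", "MM")): 22.0,
        ("hsa-miR-598", ("ZZ_ASYMP", "MM")): 28.0,
        ("hsa-miR-320a", ("ZZ_ASYMP", "MM")): 16.0,
        ("hsa-miR-30a-5p", ("ZZ_ASYMP", "MM")): 5.0,
    }


def aat_gene_sets(
    gene_truth: dict, n_sets: int = 50, seed: int = 0
) -> dict[str, list[str]]:
    """Hallmark-style collection: one set concentrated in NF-kB-annotated
    down-regulated genes plus ``n_sets - 1`` random decoys."""
    rng = np.random.default_rng(seed)
    nfkb_down = sorted(g for g, v in gene_truth["nfkb_annotation"].items() if v)
    universe = (
        sorted(gene_truth["down_genes"])
        + sorted(gene_truth["up_genes"])
        + [f"BG{i + 1:05d}" for i in range(2000)]
    )
    sets: dict[str, list[str]] = {
        "TNFA_SIGNALING_VIA_NFKB_SYNTH": sorted(
            rng.choice(nfkb_down, size=80, replace=False)
        )
    }
    for i in range(n_sets - 1):
        size = int(rng.integers(50, 150))
        sets[f"DECOY_SET_{i + 1:02d}"] = sorted(
            rng.choice(universe, size=size, replace=False)
        )
    return sets
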