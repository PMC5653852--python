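"""Promoter TFBS distance filtering: who is plausibly NF-kB-regulated?

Upstream predictors report transcription-factor binding sites in miRNA
regulatory regions as distances from the annotated transcription start
site (TSS).  A site sitting essentially on top of the TSS is unlikely to
be a functional enhancer element, so classification uses a distance
window: a miRNA counts as regulated by a TF only if at least one site
falls at ``min_distance <= |distance| <= max_distance`` on the upstream
side.  The minimum distance implements the "too close to the TSS to be
functional" exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError

SITE_COLUMNS = ("mirna", "tf", "distance_bp")


@dataclass
class PromoterAnnotation:
    """Per-miRNA TF binding sites with signed distance from the TSS.

    Distances are signed base pairs, upstream negative.  Records are
    deduplicated on (mirna, tf, distance_bp).
    """

    sites: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(SITE_COLUMNS) - set(self.sites.columns)
        if missing:
            raise ConfigurationError(f"promoter table missing columns: {sorted(missing)}")
        self.sites = (
            self.sites.drop_duplicates(subset=list(SITE_COLUMNS))
            .reset_index(drop=True)
            .astype({"distance_bp": int})
        )

    @classmethod
    def from_site_map(
        cls,
        site_map: Mapping[str, Sequence[tuple[str, int]]],
        source: str = "",
    ) -> "PromoterAnnotation":
        """Build from {mirna: [(tf, signed distance), ...]}; empty lists allowed.

        miRNAs with no sites are retained (they classify as ``no_site``).
        """
        rows = [
            {"mirna": m, "tf": tf, "distance_bp": int(d)}
            for m, sites in site_map.items()
            for tf, d in sites
        ]
        ann = cls(pd.DataFrame(rows, columns=list(SITE_COLUMNS)), source=source)
        ann._known = list(site_map)
        return ann

    _known: list[str] = field(default_factory=list, repr=False)

    def mirnas(self) -> list[str]:
        known = list(dict.fromkeys([*self._known, *self.sites["mirna"]]))
        return known


@dataclass(frozen=True)
class RegulationCall:
    """Classification of one miRNA for one TF."""

    mirna_id: str
    tf_name: str
    regulated: bool
    qualifying_sites: tuple[int, ...]
    reason: str  # no_site | too_close | in_window


def classify_regulated(
    ann: PromoterAnnotation,
    tf: str,
    window: tuple[int, int] = (100, 10_000),
    mirnas: Iterable[str] | None = None,
    require_upstream: bool = True,
    unsigned_upstream: bool = False,
) -> list[RegulationCall]:
    """Call each miRNA regulated/not by ``tf`` under a distance window.

    A site qualifies iff ``min_distance <= |distance_bp| <= max_distance``
    and, when ``require_upstream`` (default), the site lies upstream of the
    TSS (negative signed distance).  ``unsigned_upstream=True`` accepts
    tables whose upstream distances were exported as positive magnitudes.

    Reasons: ``in_window`` when regulated; ``too_close`` when the miRNA has
    at least one site of this TF inside the exclusion zone (|d| < min) and
    none qualifying; ``no_site`` otherwise (no site of this TF, or sites
    only beyond the window / on the wrong side).
    """
    lo, hi = window
    if not (0 <= lo < hi):
        raise ConfigurationError("window must satisfy 0 <= min_distance < max_distance")

    queried = list(mirnas) if mirnas is not None else ann.mirnas()
    tf_sites = ann.sites[ann.sites["tf"] == tf]
    calls: list[RegulationCall] = []
    for m in queried:
        dists = tf_sites.loc[tf_sites["mirna"] == m, "distance_bp"].tolist()
        if unsigned_upstream:
            dists = [-abs(d) for d in dists]
        considered = [d for d in dists if d < 0] if require_upstream else dists
        qualifying = tuple(sorted(d for d in considered if lo <= abs(d) <= hi))
        if qualifying:
            reason = "in_window"
        elif any(abs(d) < lo for d in considered):
            reason = "too_close"
        else:
            reason = "no_site"
        calls.append(
            RegulationCall(
                mirna_id=m,
                tf_name=tf,
                regulated=bool(qualifying),
                qualifying_sites=qualifying,
                reason=reason,
            )
        )
    return calls


def intersect_with_screen(
    calls: Sequence[RegulationCall], screened: Sequence[str]
) -> list[str]:
    """Screened features with a positive regulation call, screen order kept."""
    regulated = {c.mirna_id for c in calls if c.regulated}
    return [f for f in screened if f in regulated]


def distances_from_bed(
    bed: pd.DataFrame, tss: Mapping[str, tuple[str, int, str]]
) -> PromoterAnnotation:
    """Convert BED-like site intervals to signed TSS distances.

    ``bed`` columns: chrom, start, end, mirna, tf (0-based half-open).
    ``tss`` maps mirna -> (chrom, tss_position, strand '+'/'-').  The signed
    distance is measured from the site edge nearest the TSS, negative when
    the site lies upstream of the TSS on the annotated strand; a site
    overlapping the TSS gets distance 0.
    """
    rows = []
    for rec in bed.itertuples(index=False):
        if rec.mirna not in tss:
            raise ConfigurationError(f"no TSS annotation for {rec.mirna!r}")
        chrom, pos, strand = tss[rec.mirna]
        if chrom != rec.chrom:
            raise ConfigurationError(f"{rec.mirna!r}: site on {rec.chrom}, TSS on {chrom}")
        if rec.start <= pos < rec.end:
            d = 0
        elif rec.end <= pos:  # site left of TSS in genome coordinates
            d = rec.end - 1 - pos  # negative
        else:
            d = rec.start - pos  # positive
        if strand == "-":
            d = -d
        rows.append({"mirna": rec.mirna, "tf": rec.tf, "distance_bp": int(d)})
    return PromoterAnnotation(pd.DataFrame(rows, columns=list(SITE_COLUMNS)))
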