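"""Fat-source classification from fatty-acid carbon isotopes.

The discriminant is the within-sherd offset Δ13C = δ13C18:0 − δ13C16:0.
Ruminant body fats deplete C18:0 relative to C16:0 and milk fats deplete
it further (mammary-gland biosynthesis draws on different carbon pools),
so increasingly negative Δ13C moves from non-ruminant through ruminant
carcass to dairy fat.  Threshold and ellipse classifications are reported
side by side and never merged: the thresholds act on Δ13C alone, while
ellipse membership uses the joint (δ13C16:0, δ13C18:0) position against
the modern reference groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import AnalysisConfig, SherdSample, Site, SourceClass
from .reference import SourceGroup, in_ellipse

logger = logging.getLogger("potlip")

__all__ = [
    "ThresholdClass",
    "ClassifiedSample",
    "RegionalSummary",
    "delta13c",
    "classify_threshold",
    "classify_ellipses",
    "classify_samples",
    "latitudinal_gradient",
    "summarize_regions",
]


class ThresholdClass:
    DAIRY = "dairy"
    RUMINANT_ADIPOSE = "ruminant_adipose"
    NON_RUMINANT = "non_ruminant"
    ALL = (DAIRY, RUMINANT_ADIPOSE, NON_RUMINANT)


@dataclass
class ClassifiedSample:
    sample_id: str
    site_id: str
    region: str
    d13c_16: float
    d13c_18: float
    delta13c: float
    delta13c_sd: float
    threshold_class: str
    ellipse_classes: set[SourceClass] = field(default_factory=set)
    marine_candidate: bool = False

    @property
    def outside_all_ellipses(self) -> bool:
        """True when no reference ellipse contains the point — a mixture
        of resources is then envisaged."""
        return len(self.ellipse_classes) == 0


def delta13c(sample: SherdSample) -> tuple[float, float]:
    """Δ13C = δ13C18:0 − δ13C16:0 with propagated replicate uncertainty
    sqrt(sd16² + sd18²).  Requires both isotope values."""
    if not sample.isotope_ready:
        raise ValueError(f"sample {sample.sample_id!r} lacks a full d13C pair")
    d = sample.d13c_18 - sample.d13c_16
    sd = math.hypot(sample.d13c_16_sd, sample.d13c_18_sd)
    return d, sd


def classify_threshold(delta: float, cfg: AnalysisConfig = AnalysisConfig()) -> str:
    """Assign a fat class from Δ13C alone.

    dairy iff Δ ≤ −3.3‰; ruminant adipose iff −3.3 < Δ < −1.0; non-ruminant
    iff Δ ≥ −1.0 (defaults; boundaries inclusive on the outer classes).
    Total over finite Δ; NaN is an error.
    """
    if not np.isfinite(delta):
        raise ValueError(f"delta13c must be finite, got {delta}")
    if delta <= cfg.delta_dairy_max:
        return ThresholdClass.DAIRY
    if delta >= cfg.delta_nonruminant_min:
        return ThresholdClass.NON_RUMINANT
    return ThresholdClass.RUMINANT_ADIPOSE


def classify_ellipses(
    sample: SherdSample,
    groups: dict[SourceClass, SourceGroup],
    level: float = 0.68,
) -> tuple[set[SourceClass], bool]:
    """Membership of the sherd's (δ13C16:0, δ13C18:0) point in each source
    group's confidence ellipse.  Returns (classes, marine_candidate); an
    empty set flags a probable mixture of resources."""
    point = (sample.d13c_16, sample.d13c_18)
    members = {cls for cls, g in groups.items() if in_ellipse(point, g, level)}
    marine = SourceClass.MARINE_OIL in members
    return members, marine


def classify_samples(
    samples: Sequence[SherdSample],
    groups: Optional[dict[SourceClass, SourceGroup]] = None,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[ClassifiedSample]:
    """Classify every isotope-ready sherd; sherds lacking a d13C pair are
    skipped with a log entry."""
    out = []
    skipped = 0
    for s in samples:
        if not s.isotope_ready:
            skipped += 1
            continue
        d, sd = delta13c(s)
        ellipse_classes: set[SourceClass] = set()
        marine = False
        if groups:
            ellipse_classes, marine = classify_ellipses(s, groups)
        out.append(
            ClassifiedSample(
                sample_id=s.sample_id,
                site_id=s.site_id,
                region=s.region,
                d13c_16=s.d13c_16,
                d13c_18=s.d13c_18,
                delta13c=d,
                delta13c_sd=sd,
                threshold_class=classify_threshold(d, cfg),
                ellipse_classes=ellipse_classes,
                marine_candidate=marine,
            )
        )
    if skipped:
        logger.info("classification: skipped %d sherds without full d13C pairs", skipped)
    logger.info("classified %d sherds", len(out))
    return out


def latitudinal_gradient(
    classified: Sequence[ClassifiedSample],
    sites: Sequence[Site],
    method: str = "t",
    per_site_mean: bool = False,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Spearman rank correlation between site latitude and Δ13C.

    Default pairs each sherd's Δ13C with its site latitude (``per_site_mean
    = True`` instead correlates site-mean Δ13C with latitude).  Ties get
    average ranks.  ``method="t"`` uses the t-distribution approximation
    for the p-value; ``method="perm"`` uses a seeded permutation test,
    preferable at small n.

    Returns (rho, p, n).  All-identical latitudes are an error (the
    correlation is undefined).
    """
    lat_by_site = {s.site_id: s.latitude for s in sites}
    pairs = [
        (lat_by_site[c.site_id], c.delta13c)
        for c in classified
        if c.site_id in lat_by_site
    ]
    if per_site_mean:
        by_site: dict[float, list[float]] = {}
        for lat, d in pairs:
            by_site.setdefault(lat, []).append(d)
        pairs = [(lat, float(np.mean(ds))) for lat, ds in by_site.items()]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 samples with site latitude, got {len(pairs)}")
    lats = np.array([p[0] for p in pairs])
    deltas = np.array([p[1] for p in pairs])
    if np.ptp(lats) == 0:
        raise ValueError("all latitudes identical; correlation undefined")

    res = stats.spearmanr(lats, deltas)
    rho = float(res.statistic)
    n = len(pairs)
    if method == "t":
        p = float(res.pvalue)
    elif method == "perm":
        rng = np.random.default_rng(seed)
        rank_lat = stats.rankdata(lats)
        rank_d = stats.rankdata(deltas)
        obs = abs(np.corrcoef(rank_lat, rank_d)[0, 1])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(rank_d)
            if abs(np.corrcoef(rank_lat, perm)[0, 1]) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    logger.info("latitudinal gradient: Spearman rho = %.3f, p = %.3g, n = %d", rho, p, n)
    return rho, p, n


@dataclass
class RegionalSummary:
    region: str
    n: int
    delta_mean: float
    delta_sd: float
    class_fractions: dict[str, float]


def summarize_regions(
    classified: Sequence[ClassifiedSample],
) -> list[RegionalSummary]:
    """Per-region n, Δ13C mean and unbiased SD, and the fraction of sherds
    in each threshold class (fractions sum to 1)."""
    regions: dict[str, list[ClassifiedSample]] = {}
    for c in classified:
        regions.setdefault(c.region, []).append(c)
    out = []
    for region, members in regions.items():
        deltas = np.array([m.delta13c for m in members])
        fractions = {
            cls: sum(m.threshold_class == cls for m in members) / len(members)
            for cls in ThresholdClass.ALL
        }
        out.append(
            RegionalSummary(
                region=region,
                n=len(members),
                delta_mean=float(deltas.mean()),
                delta_sd=float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
                class_fractions=fractions,
            )
        )
    return out
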