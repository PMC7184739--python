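"""Lipid-yield interpretability filter and aquatic biomarker screening."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .datatypes import AnalysisConfig, BiomarkerFlags, SherdSample

logger = logging.getLogger("potlip")

__all__ = [
    "AquaticEvidence",
    "AquaticRule",
    "ScreeningResult",
    "filter_interpretable",
    "flag_aquatic",
    "screen_samples",
]


class AquaticEvidence(str, Enum):
    NONE = "none"
    PARTIAL = "partial"
    POSITIVE = "positive"


@dataclass(frozen=True)
class AquaticRule:
    """Decision rule for aquatic-resource evidence.

    Default rule: *positive* requires a long-chain APAA (C20 or C22,
    formed by prolonged heating of aquatic unsaturated fatty acids) AND at
    least one isoprenoid indicator (phytanic, pristanic or TMTD presence,
    or a phytanic SRR diastereomer fraction above ``srr_cutoff``).
    Exactly one of the two conditions gives *partial*.  The C18 APAA alone
    is only weak support (it also forms when terrestrial fats are heated)
    and counts as partial evidence on its own.

    The SRR cutoff default of 0.755 is a literature-derived convention for
    separating aquatic from ruminant phytanic acid; it is not a value
    measured here.
    """

    require_long_apaa: bool = True
    srr_cutoff: float = 0.755
    apaa_c18_partial: bool = True


def flag_aquatic(
    flags: Optional[BiomarkerFlags], rule: AquaticRule = AquaticRule()
) -> AquaticEvidence:
    """Classify a sherd's biomarker flags as none/partial/positive aquatic
    evidence.  Monotone: adding a true flag never demotes the level."""
    if flags is None:
        return AquaticEvidence.NONE
    long_apaa = flags.apaa_c20 or flags.apaa_c22
    srr_aquatic = (
        flags.phytanic_srr_fraction is not None
        and flags.phytanic_srr_fraction > rule.srr_cutoff
    )
    isoprenoid = flags.phytanic or flags.pristanic or flags.tmtd or srr_aquatic
    if long_apaa and isoprenoid:
        return AquaticEvidence.POSITIVE
    if long_apaa or isoprenoid:
        return AquaticEvidence.PARTIAL
    if rule.apaa_c18_partial and flags.apaa_c18:
        return AquaticEvidence.PARTIAL
    return AquaticEvidence.NONE


@dataclass
class ScreeningResult:
    sample_id: str
    interpretable: Optional[bool]      # None when lipid_conc missing
    isotope_ready: bool
    aquatic_evidence: AquaticEvidence


def filter_interpretable(
    samples: Sequence[SherdSample], threshold: float = 5.0
) -> tuple[list[SherdSample], list[SherdSample], list[SherdSample]]:
    """Partition sherds by lipid yield into (kept, rejected, no_conc).

    A sherd is kept iff its lipid concentration strictly exceeds
    ``threshold`` (µg g⁻¹); a yield exactly at the threshold is rejected.
    Sherds without a recorded concentration are returned separately, never
    silently dropped.  Negative concentrations are an error.
    """
    kept, rejected, missing = [], [], []
    for s in samples:
        if s.lipid_conc is None:
            missing.append(s)
        elif s.lipid_conc < 0:
            raise ValueError(
                f"negative lipid concentration {s.lipid_conc} for {s.sample_id!r}"
            )
        elif s.lipid_conc > threshold:
            kept.append(s)
        else:
            rejected.append(s)
    total = len(samples)
    if total:
        logger.info(
            "interpretable lipid yields (>%g ug/g): n = %d of %d (%.0f%% of the total); "
            "%d below threshold, %d without concentration",
            threshold, len(kept), total, 100.0 * len(kept) / total,
            len(rejected), len(missing),
        )
    return kept, rejected, missing


def screen_samples(
    samples: Sequence[SherdSample],
    config: AnalysisConfig = AnalysisConfig(),
    rule: Optional[AquaticRule] = None,
) -> list[ScreeningResult]:
    """Run the full screening stage: interpretability + aquatic flags."""
    rule = rule or AquaticRule(srr_cutoff=config.phytanic_srr_cutoff)
    results = []
    for s in samples:
        if s.lipid_conc is None:
            interpretable = None
        else:
            if s.lipid_conc < 0:
                raise ValueError(
                    f"negative lipid concentration {s.lipid_conc} for {s.sample_id!r}"
                )
            interpretable = s.lipid_conc > config.lipid_threshold
        results.append(
            ScreeningResult(
                sample_id=s.sample_id,
                interpretable=interpretable,
                isotope_ready=s.isotope_ready,
                aquatic_evidence=flag_aquatic(s.biomarkers, rule),
            )
        )
    n_pos = sum(r.aquatic_evidence is AquaticEvidence.POSITIVE for r in results)
    logger.info("aquatic biomarker screening: %d of %d positive", n_pos, len(results))
    return results
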