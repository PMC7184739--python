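"""Domain types for pottery lipid residue analysis.

All carbon isotope ratios are per mill (‰) on the VPDB scale and are stored
as plain floats; no internal rescaling is performed.  Lipid concentrations
are µg lipid per g of sherd powder.  Dates are calendar years cal BC as
positive numbers (larger = older).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "SourceClass",
    "BiomarkerFlags",
    "SherdSample",
    "Site",
    "ReferenceFat",
    "AnalysisConfig",
    "DEFAULT_REGIONS",
    "normalize_region",
]

#: Default regional vocabulary, ordered south to north along the Atlantic
#: transect, plus the Western Baltic.  Region labels are free text matched
#: case-insensitively after trimming; these six ship as the documented
#: default vocabulary.
DEFAULT_REGIONS = (
    "Central-southern Portugal",
    "Northern Spain",
    "France and the Channel Islands",
    "Southern England",
    "Northern England, Ireland and Scotland",
    "Western Baltic",
)


def normalize_region(label: str) -> str:
    """Map a free-text region label onto the default vocabulary if it
    matches case-insensitively after trimming; otherwise return the
    trimmed label unchanged."""
    trimmed = label.strip()
    lowered = trimmed.lower()
    for canonical in DEFAULT_REGIONS:
        if canonical.lower() == lowered:
            return canonical
    return trimmed


class SourceClass(str, Enum):
    """Food-source classes distinguished by fatty-acid carbon isotopes."""

    RUMINANT_ADIPOSE = "ruminant_adipose"
    RUMINANT_DAIRY = "ruminant_dairy"
    NON_RUMINANT = "non_ruminant"
    MARINE_OIL = "marine_oil"


@dataclass(frozen=True)
class BiomarkerFlags:
    """Presence/absence of aquatic-resource molecular biomarkers.

    APAAs (omega-(o-alkylphenyl)alkanoic acids) form when unsaturated fatty
    acids are heated; the long-chain C20/C22 homologues indicate aquatic
    oils while the C18 homologue also forms from terrestrial fats.
    Isoprenoid acids (phytanic, pristanic, TMTD) corroborate an aquatic
    origin, as does a phytanic SRR diastereomer fraction above the
    configured cutoff.
    """

    apaa_c18: bool = False
    apaa_c20: bool = False
    apaa_c22: bool = False
    phytanic: bool = False
    pristanic: bool = False
    tmtd: bool = False
    phytanic_srr_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phytanic_srr_fraction is not None:
            if not self.phytanic:
                raise ValueError(
                    "phytanic_srr_fraction supplied but phytanic is False"
                )
            if not 0.0 <= self.phytanic_srr_fraction <= 1.0:
                raise ValueError(
                    "phytanic_srr_fraction must lie in [0, 1], got "
                    f"{self.phytanic_srr_fraction}"
                )


@dataclass
class SherdSample:
    """One pottery residue measurement.

    ``d13c_16`` / ``d13c_18`` are the compound-specific carbon isotope
    ratios of palmitic (C16:0) and stearic (C18:0) acid.  ``None`` means
    the sherd yielded no isotopic measurement; such rows are retained but
    flagged non-isotopic.
    """

    sample_id: str
    site_id: str
    region: str = ""
    d13c_16: Optional[float] = None
    d13c_18: Optional[float] = None
    d13c_16_sd: float = 0.1
    d13c_18_sd: float = 0.1
    lipid_conc: Optional[float] = None
    biomarkers: Optional[BiomarkerFlags] = None

    def __post_init__(self) -> None:
        for name in ("d13c_16", "d13c_18"):
            v = getattr(self, name)
            if v is not None and not (-45.0 <= v <= 0.0):
                raise ValueError(
                    f"{name}={v} outside plausible d13C range [-45, 0] permil "
                    f"for sample {self.sample_id!r}"
                )
        self.region = normalize_region(self.region) if self.region else ""

    @property
    def isotope_ready(self) -> bool:
        """True when both d13C values are present."""
        return self.d13c_16 is not None and self.d13c_18 is not None


@dataclass
class Site:
    """An archaeological site with coordinates and an (optional) earliest
    Neolithic arrival date in cal BC."""

    site_id: str
    name: str = ""
    longitude: float = 0.0
    latitude: float = 0.0
    region: str = ""
    earliest_date: Optional[float] = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if self.earliest_date is not None and not (
            2000.0 <= self.earliest_date <= 12000.0
        ):
            raise ValueError(
                f"earliest_date {self.earliest_date} cal BC outside [2000, 12000]"
            )
        self.region = normalize_region(self.region) if self.region else ""


@dataclass
class ReferenceFat:
    """A modern authentic reference fat or oil, as measured (i.e. before
    Suess-effect correction)."""

    ref_id: str
    source_class: SourceClass
    d13c_16: float
    d13c_18: float
    collection_year: float

    def __post_init__(self) -> None:
        if isinstance(self.source_class, str):
            try:
                self.source_class = SourceClass(self.source_class)
            except ValueError:
                valid = ", ".join(c.value for c in SourceClass)
                raise ValueError(
                    f"unknown source_class {self.source_class!r} for "
                    f"{self.ref_id!r}; expected one of: {valid}"
                ) from None
        if not 1850 <= self.collection_year <= 2030:
            raise ValueError(
                f"collection_year {self.collection_year} outside [1850, 2030]"
            )


@dataclass
class AnalysisConfig:
    """Pipeline configuration housing the analysis constants.

    Parameters
    ----------
    lipid_threshold : float
        Minimum lipid yield (µg g⁻¹, strict) for a residue to be
        interpretable; default 5.0.
    delta_dairy_max : float
        Δ13C at or below which a residue classifies as dairy (‰);
        default −3.3.
    delta_nonruminant_min : float
        Δ13C at or above which a residue classifies as non-ruminant (‰);
        default −1.0.
    obs_sigma : float
        Observation uncertainty on each isotope proxy entering the mixing
        model (‰); default 0.5.
    mcmc_burnin, mcmc_iters : int
        Discarded and retained iterations per MCMC chain; defaults 5000
        and 10000.
    se_mask : float
        Standard-error threshold above which spatial surface cells are
        suppressed (‰); default 0.30.
    spread_tau : float
        Extreme quantile used for the arrival-date surface; default 0.005.
    excluded_regions : list of str
        Regions excluded from the regional mixing model; default the
        Western Baltic, whose isotope values are bimodal (marine plus
        terrestrial).
    """

    lipid_threshold: float = 5.0
    delta_dairy_max: float = -3.3
    delta_nonruminant_min: float = -1.0
    obs_sigma: float = 0.5
    mcmc_burnin: int = 5000
    mcmc_iters: int = 10000
    se_mask: float = 0.30
    spread_tau: float = 0.005
    rng_seed: int = 0
    excluded_regions: list[str] = field(
        default_factory=lambda: ["Western Baltic"]
    )
    phytanic_srr_cutoff: float = 0.755

    def __post_init__(self) -> None:
        if not self.delta_dairy_max < self.delta_nonruminant_min:
            raise ValueError(
                "delta_dairy_max must be < delta_nonruminant_min "
                f"(got {self.delta_dairy_max} >= {self.delta_nonruminant_min})"
            )
        if not 0.0 < self.spread_tau < 0.5:
            raise ValueError(f"spread_tau must lie in (0, 0.5), got {self.spread_tau}")
        if self.mcmc_iters <= 0:
            raise ValueError("mcmc_iters must be positive")

    @classmethod
    def from_toml(cls, path) -> "AnalysisConfig":
        """Load a configuration from a TOML file; unknown keys error."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
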