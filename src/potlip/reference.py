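"""Statistical source groups from modern reference fats.

Modern fats must be corrected for the Suess effect (the industrial-era
decline in atmospheric CO2 d13C) before comparison with archaeological
residues.  Corrected reference fats are pooled per source class into a
bivariate-normal summary (mean, covariance, SEM) used for 68% confidence
ellipses and as priors in the mixing model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import ReferenceFat, SourceClass

__all__ = [
    "SuessCurve",
    "DEFAULT_SUESS_CURVE",
    "suess_correct",
    "FattyAcidConcentration",
    "DEFAULT_CONCENTRATIONS",
    "SourceGroup",
    "fit_source_group",
    "fit_all_groups",
    "ConfidenceEllipse",
    "ellipse_for",
    "in_ellipse",
    "mahalanobis_sq",
]


@dataclass(frozen=True)
class SuessCurve:
    """Piecewise-linear atmospheric CO2 d13C series (‰ VPDB vs year CE).

    The correction for a fat collected in year y shifts its d13C back to
    the pre-industrial baseline:  corrected = measured + [atm(baseline) -
    atm(y)].  On a monotonically declining curve the correction is >= 0
    for post-baseline years.
    """

    years: tuple[float, ...]
    values: tuple[float, ...]
    baseline_year: float = 1850.0

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values) or len(self.years) < 2:
            raise ValueError("curve needs >= 2 (year, value) pairs")
        if list(self.years) != sorted(self.years):
            raise ValueError("curve years must be increasing")

    @property
    def span(self) -> tuple[float, float]:
        return (self.years[0], self.years[-1])

    def at(self, year: float) -> float:
        lo, hi = self.span
        if not lo <= year <= hi:
            raise ValueError(
                f"collection year {year} outside the atmospheric curve span "
                f"[{lo:g}, {hi:g}]"
            )
        return float(np.interp(year, self.years, self.values))


#: Built-in synthetic atmospheric d13C series: a smooth decline from
#: -6.4‰ at 1850 to -8.4‰ at 2010, steepening after 1960 in the shape of
#: published atmospheric records.  Users may supply their own curve.
DEFAULT_SUESS_CURVE = SuessCurve(
    years=(1850.0, 1900.0, 1950.0, 1960.0, 1980.0, 2000.0, 2010.0, 2025.0),
    values=(-6.4, -6.55, -6.85, -7.0, -7.5, -8.1, -8.4, -8.75),
)


def suess_correct(
    d13c: float, collection_year: float, curve: SuessCurve = DEFAULT_SUESS_CURVE
) -> float:
    """Shift a modern d13C measurement back to the pre-industrial
    atmospheric baseline.

    The correction is additive: ``suess_correct(a + x) ==
    suess_correct(a) + x`` for any offset x, and the baseline year yields
    zero correction.
    """
    shift = curve.at(curve.baseline_year) - curve.at(collection_year)
    return d13c + shift


@dataclass(frozen=True)
class FattyAcidConcentration:
    """Palmitic (C16:0) and stearic (C18:0) acid content of a source fat,
    as % of total lipid by weight, with standard errors of the mean."""

    c16: float
    c18: float
    c16_sem: float = 0.0
    c18_sem: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.c16 <= 100.0 and 0.0 < self.c18 <= 100.0):
            raise ValueError("concentrations must lie in (0, 100] % by weight")


#: Packaged default fatty-acid concentrations (% lipid by weight), in the
#: style of food-composition-database entries for beef tallow, butter fat,
#: lard and fish oil.  These are defaults with provenance notes, not
#: values asserted by any particular study; override freely.
DEFAULT_CONCENTRATIONS: dict[SourceClass, FattyAcidConcentration] = {
    SourceClass.RUMINANT_ADIPOSE: FattyAcidConcentration(26.0, 22.0, 1.5, 1.5),
    SourceClass.RUMINANT_DAIRY: FattyAcidConcentration(30.0, 12.0, 1.5, 1.0),
    SourceClass.NON_RUMINANT: FattyAcidConcentration(24.0, 14.0, 1.5, 1.0),
    SourceClass.MARINE_OIL: FattyAcidConcentration(17.0, 4.0, 1.5, 0.8),
}


@dataclass
class SourceGroup:
    """Bivariate-normal summary of one food-source class in
    (d13C16:0, d13C18:0) space."""

    source_class: SourceClass
    mean: np.ndarray           # shape (2,), ‰
    cov: np.ndarray            # shape (2, 2), ‰²
    n: int
    conc: FattyAcidConcentration

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (2,) or self.cov.shape != (2, 2):
            raise ValueError("mean must be (2,), cov must be (2, 2)")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        eigs = np.linalg.eigvalsh(self.cov)
        if eigs.min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def sem(self) -> np.ndarray:
        """Standard errors of the two means: sqrt(diag(cov) / n)."""
        return np.sqrt(np.diag(self.cov) / self.n)

    @property
    def sem_cov(self) -> np.ndarray:
        """Covariance of the mean estimate: cov / n (the SEM-scaled
        covariance used for signature uncertainty in the mixing model)."""
        return self.cov / self.n

    def to_dict(self) -> dict:
        return {
            "source_class": self.source_class.value,
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "sem": self.sem.tolist(),
            "n": self.n,
            "conc": {
                "c16": self.conc.c16,
                "c18": self.conc.c18,
                "c16_sem": self.conc.c16_sem,
                "c18_sem": self.conc.c18_sem,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceGroup":
        return cls(
            source_class=SourceClass(d["source_class"]),
            mean=np.array(d["mean"]),
            cov=np.array(d["cov"]),
            n=int(d["n"]),
            conc=FattyAcidConcentration(**d["conc"]),
        )


def fit_source_group(
    refs: Sequence[ReferenceFat],
    conc: FattyAcidConcentration,
    curve: SuessCurve = DEFAULT_SUESS_CURVE,
    suess: bool = True,
) -> SourceGroup:
    """Fit a bivariate-normal source group from reference fats of one class.

    Each fat is Suess-corrected using its collection year (unless
    ``suess=False``, for already-corrected inputs), then the arithmetic
    mean and unbiased sample covariance are computed.  Requires >= 2 fats,
    all of the same class.
    """
    if len(refs) < 2:
        raise ValueError(f"need >= 2 reference fats to fit a group, got {len(refs)}")
    classes = {r.source_class for r in refs}
    if len(classes) != 1:
        raise ValueError(f"mixed source classes in one group: {sorted(c.value for c in classes)}")
    pts = np.array(
        [
            (
                suess_correct(r.d13c_16, r.collection_year, curve),
                suess_correct(r.d13c_18, r.collection_year, curve),
            )
            if suess
            else (r.d13c_16, r.d13c_18)
            for r in refs
        ]
    )
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return SourceGroup(
        source_class=refs[0].source_class,
        mean=mean,
        cov=np.atleast_2d(cov),
        n=len(refs),
        conc=conc,
    )


def fit_all_groups(
    refs: Sequence[ReferenceFat],
    concentrations: Optional[dict[SourceClass, FattyAcidConcentration]] = None,
    curve: SuessCurve = DEFAULT_SUESS_CURVE,
) -> dict[SourceClass, SourceGroup]:
    """Partition a reference table by class and fit each group."""
    concentrations = concentrations or DEFAULT_CONCENTRATIONS
    groups = {}
    for cls in SourceClass:
        members = [r for r in refs if r.source_class == cls]
        if len(members) >= 2:
            groups[cls] = fit_source_group(members, concentrations[cls], curve)
    return groups


@dataclass(frozen=True)
class ConfidenceEllipse:
    """A population confidence ellipse of a bivariate normal.

    The ellipse is {x : (x - center)' cov^-1 (x - center) <= q} where q is
    the chi-square(2 df) quantile at ``level`` — i.e. it covers ``level``
    of the population, which differs from the 1-SD convention.
    """

    center: np.ndarray
    axes: tuple[float, float]      # semi-axis lengths, ‰
    angle: float                   # radians, major axis from +x
    level: float
    cov: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if min(self.axes) <= 0:
            raise ValueError("ellipse axes must be positive")


def _chi2_quantile(level: float) -> float:
    return float(stats.chi2.ppf(level, df=2))


def ellipse_for(group: SourceGroup, level: float = 0.68) -> ConfidenceEllipse:
    """Population confidence ellipse of a fitted source group.

    Semi-axes are sqrt(q * eigenvalues of cov) with q the chi-square(2)
    quantile at ``level``.  A singular covariance is an error (jitter the
    references or supply more of them).
    """
    eigvals, eigvecs = np.linalg.eigh(group.cov)
    if eigvals.min() <= 1e-12:
        raise ValueError(
            f"covariance of {group.source_class.value} is singular; add more "
            "reference fats or jitter the measurements"
        )
    q = _chi2_quantile(level)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    major = eigvecs[:, 0]
    return ConfidenceEllipse(
        center=group.mean.copy(),
        axes=(float(np.sqrt(q * eigvals[0])), float(np.sqrt(q * eigvals[1]))),
        angle=float(np.arctan2(major[1], major[0])),
        level=level,
        cov=group.cov.copy(),
    )


def mahalanobis_sq(point, mean, cov) -> float:
    """Squared Mahalanobis distance of a 2-vector from a bivariate normal."""
    d = np.asarray(point, dtype=float) - np.asarray(mean, dtype=float)
    return float(d @ np.linalg.solve(cov, d))


def in_ellipse(point, group_or_ellipse, level: float = 0.68) -> bool:
    """Membership test: is ``point`` inside the ``level`` confidence
    ellipse?  Boundary points count as inside."""
    if isinstance(group_or_ellipse, ConfidenceEllipse):
        mean, cov = group_or_ellipse.center, group_or_ellipse.cov
        level = group_or_ellipse.level
        if cov is None:
            raise ValueError("ellipse carries no covariance; build via ellipse_for")
    else:
        mean, cov = group_or_ellipse.mean, group_or_ellipse.cov
    return mahalanobis_sq(point, mean, cov) <= _chi2_quantile(level)


def save_groups(groups: dict[SourceClass, SourceGroup], path) -> None:
    """Serialise fitted groups (with their 68% ellipses) to JSON."""
    payload = {}
    for cls, g in groups.items():
        d = g.to_dict()
        try:
            e = ellipse_for(g)
            d["ellipse68"] = {
                "center": e.center.tolist(),
                "axes": list(e.axes),
                "angle": e.angle,
                "level": e.level,
            }
        except ValueError:
            d["ellipse68"] = None
        payload[cls.value] = d
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_groups(path) -> dict[SourceClass, SourceGroup]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {SourceClass(k): SourceGroup.from_dict(v) for k, v in payload.items()}
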