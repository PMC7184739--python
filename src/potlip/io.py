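"""Tabular readers/writers and dataset validation.

CSV dialect: UTF-8, comma-separated, ``.`` decimal, header row mandatory.
Missing values are empty cells on write; the sentinels ``NA``, ``n/a``,
``NaN`` and the empty string are accepted on read.  A schema mapping lets
users rename columns rather than edit their files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BiomarkerFlags,
    ReferenceFat,
    SherdSample,
    Site,
    SourceClass,
)

logger = logging.getLogger("potlip")

_NA_STRINGS = {"", "na", "n/a", "nan", "none"}

SHERD_COLUMNS = (
    "sample_id",
    "site_id",
    "region",
    "d13c_16",
    "d13c_18",
    "d13c_16_sd",
    "d13c_18_sd",
    "lipid_conc",
    "apaa_c18",
    "apaa_c20",
    "apaa_c22",
    "phytanic",
    "pristanic",
    "tmtd",
    "phytanic_srr_fraction",
)
SITE_COLUMNS = ("site_id", "name", "longitude", "latitude", "region", "earliest_date")
REFERENCE_COLUMNS = ("ref_id", "source_class", "d13c_16", "d13c_18", "collection_year")


class TableFormatError(ValueError):
    """A CSV table violates the expected schema or content rules."""


def _parse_float(raw, row_num: int, column: str, errors: list[str]) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in _NA_STRINGS:
        return None
    # tolerate the unicode minus sign used in typeset tables
    text = text.replace("−", "-")
    try:
        return float(text)
    except ValueError:
        errors.append(f"row {row_num}: column {column!r} has malformed numeric {raw!r}")
        return None


def _parse_bool(raw) -> bool:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return False
    return str(raw).strip().lower() in {"1", "true", "t", "yes", "y"}


def _load_frame(path, schema: Optional[Mapping[str, str]]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    frame.columns = [c.strip() for c in frame.columns]
    return frame


def read_sherd_table(
    path, schema: Optional[Mapping[str, str]] = None
) -> list[SherdSample]:
    """Read per-sherd residue measurements from CSV.

    Parameters
    ----------
    path : path-like
        CSV file with at least ``sample_id`` and ``site_id`` columns.
    schema : mapping, optional
        Maps canonical column names to the file's actual headers, e.g.
        ``{"d13c_16": "d13C C16:0"}``.

    Rows lacking both d13C values are retained but are non-isotopic
    (``SherdSample.isotope_ready`` is False).  Malformed numerics are
    reported with their row numbers; duplicate sample ids are an error.
    """
    frame = _load_frame(path, schema)
    for required in ("sample_id", "site_id"):
        if required not in frame.columns:
            raise TableFormatError(
                f"mandatory column {required!r} missing from {path} "
                f"(have: {list(frame.columns)})"
            )

    ids = frame["sample_id"].str.strip()
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise TableFormatError(f"duplicate sample_id values: {dupes}")

    errors: list[str] = []
    samples: list[SherdSample] = []
    for idx, row in frame.iterrows():
        row_num = int(idx) + 2  # 1-based plus header line
        get = lambda col: row[col] if col in frame.columns else None
        d16 = _parse_float(get("d13c_16"), row_num, "d13c_16", errors)
        d18 = _parse_float(get("d13c_18"), row_num, "d13c_18", errors)
        sd16 = _parse_float(get("d13c_16_sd"), row_num, "d13c_16_sd", errors)
        sd18 = _parse_float(get("d13c_18_sd"), row_num, "d13c_18_sd", errors)
        conc = _parse_float(get("lipid_conc"), row_num, "lipid_conc", errors)

        flags = None
        if any(col in frame.columns for col in ("apaa_c18", "apaa_c20", "phytanic")):
            srr = _parse_float(
                get("phytanic_srr_fraction"), row_num, "phytanic_srr_fraction", errors
            )
            phytanic = _parse_bool(get("phytanic"))
            flags = BiomarkerFlags(
                apaa_c18=_parse_bool(get("apaa_c18")),
                apaa_c20=_parse_bool(get("apaa_c20")),
                apaa_c22=_parse_bool(get("apaa_c22")),
                phytanic=phytanic,
                pristanic=_parse_bool(get("pristanic")),
                tmtd=_parse_bool(get("tmtd")),
                phytanic_srr_fraction=srr if phytanic else None,
            )

        samples.append(
            SherdSample(
                sample_id=str(row["sample_id"]).strip(),
                site_id=str(row["site_id"]).strip(),
                region=str(get("region") or "").strip(),
                d13c_16=d16,
                d13c_18=d18,
                d13c_16_sd=sd16 if sd16 is not None else 0.1,
                d13c_18_sd=sd18 if sd18 is not None else 0.1,
                lipid_conc=conc,
                biomarkers=flags,
            )
        )

    if errors:
        for msg in errors:
            logger.warning("%s: %s", path, msg)
    n_iso = sum(s.isotope_ready for s in samples)
    logger.info(
        "read %d sherd rows from %s (%d with full isotope pairs)",
        len(samples), path, n_iso,
    )
    return samples


def write_sherd_table(samples: Sequence[SherdSample], path) -> None:
    """Write sherds to CSV with canonical headers (round-trips with
    :func:`read_sherd_table`)."""
    rows = []
    for s in samples:
        b = s.biomarkers or BiomarkerFlags()
        rows.append(
            {
                "sample_id": s.sample_id,
                "site_id": s.site_id,
                "region": s.region,
                "d13c_16": s.d13c_16,
                "d13c_18": s.d13c_18,
                "d13c_16_sd": s.d13c_16_sd,
                "d13c_18_sd": s.d13c_18_sd,
                "lipid_conc": s.lipid_conc,
                "apaa_c18": b.apaa_c18,
                "apaa_c20": b.apaa_c20,
                "apaa_c22": b.apaa_c22,
                "phytanic": b.phytanic,
                "pristanic": b.pristanic,
                "tmtd": b.tmtd,
                "phytanic_srr_fraction": b.phytanic_srr_fraction,
            }
        )
    pd.DataFrame(rows, columns=SHERD_COLUMNS).to_csv(
        path, index=False, encoding="utf-8", float_format="%.12g"
    )


def read_site_table(path, schema: Optional[Mapping[str, str]] = None) -> list[Site]:
    """Read the site table (id, name, coordinates, region, earliest cal BC
    date) from CSV."""
    frame = _load_frame(path, schema)
    for required in ("site_id", "longitude", "latitude"):
        if required not in frame.columns:
            raise TableFormatError(f"mandatory column {required!r} missing from {path}")
    ids = frame["site_id"].str.strip()
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise TableFormatError(f"duplicate site_id values: {dupes}")
    errors: list[str] = []
    sites = []
    for idx, row in frame.iterrows():
        row_num = int(idx) + 2
        get = lambda col: row[col] if col in frame.columns else None
        sites.append(
            Site(
                site_id=str(row["site_id"]).strip(),
                name=str(get("name") or "").strip(),
                longitude=_parse_float(row["longitude"], row_num, "longitude", errors) or 0.0,
                latitude=_parse_float(row["latitude"], row_num, "latitude", errors) or 0.0,
                region=str(get("region") or "").strip(),
                earliest_date=_parse_float(
                    get("earliest_date"), row_num, "earliest_date", errors
                ),
            )
        )
    if errors:
        raise TableFormatError("; ".join(errors))
    logger.info("read %d sites from %s", len(sites), path)
    return sites


def write_site_table(sites: Sequence[Site], path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "name": s.name,
            "longitude": s.longitude,
            "latitude": s.latitude,
            "region": s.region,
            "earliest_date": s.earliest_date,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(
        path, index=False, encoding="utf-8", float_format="%.12g"
    )


def read_reference_table(
    path, schema: Optional[Mapping[str, str]] = None
) -> list[ReferenceFat]:
    """Read modern reference fats/oils from CSV.

    A ``source_class`` outside the closed enum (ruminant_adipose,
    ruminant_dairy, non_ruminant, marine_oil) is an error naming the row.
    An empty file (header only) returns an empty list with a warning.
    """
    frame = _load_frame(path, schema)
    for required in REFERENCE_COLUMNS:
        if required not in frame.columns:
            raise TableFormatError(f"mandatory column {required!r} missing from {path}")
    if len(frame) == 0:
        logger.warning("reference table %s contains no data rows", path)
        return []
    errors: list[str] = []
    refs = []
    for idx, row in frame.iterrows():
        row_num = int(idx) + 2
        try:
            refs.append(
                ReferenceFat(
                    ref_id=str(row["ref_id"]).strip(),
                    source_class=str(row["source_class"]).strip(),
                    d13c_16=_parse_float(row["d13c_16"], row_num, "d13c_16", errors),
                    d13c_18=_parse_float(row["d13c_18"], row_num, "d13c_18", errors),
                    collection_year=_parse_float(
                        row["collection_year"], row_num, "collection_year", errors
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"row {row_num}: {exc}") from exc
    if errors:
        raise TableFormatError("; ".join(errors))
    logger.info("read %d reference fats from %s", len(refs), path)
    return refs


def write_reference_table(refs: Sequence[ReferenceFat], path) -> None:
    rows = [
        {
            "ref_id": r.ref_id,
            "source_class": r.source_class.value,
            "d13c_16": r.d13c_16,
            "d13c_18": r.d13c_18,
            "collection_year": r.collection_year,
        }
        for r in refs
    ]
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(
        path, index=False, encoding="utf-8", float_format="%.12g"
    )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`.

    ``broken_references`` are (sample_id, site_id) pairs pointing at
    unknown sites — the only problem that should stop a pipeline run.
    """

    broken_references: list[tuple[str, str]] = field(default_factory=list)
    empty_sites: list[str] = field(default_factory=list)
    isotope_outliers: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.broken_references

    @property
    def problems(self) -> list[str]:
        out = [f"sample {s!r} references unknown site {site!r}"
               for s, site in self.broken_references]
        out += [f"site {s!r} has no samples" for s in self.empty_sites]
        out += [f"sample {s!r} is a d13C outlier (>3 SD from pooled mean)"
                for s in self.isotope_outliers]
        return out


def validate_dataset(
    samples: Sequence[SherdSample], sites: Sequence[Site]
) -> ValidationReport:
    """Cross-check samples against sites and screen for isotopic outliers.

    Side-effect free and idempotent.  Outliers are samples whose d13C
    values fall more than 3 pooled standard deviations from the pooled
    mean of all isotope-ready samples (computed per proxy).
    """
    site_ids = {s.site_id for s in sites}
    report = ValidationReport()
    for s in samples:
        if s.site_id not in site_ids:
            report.broken_references.append((s.sample_id, s.site_id))
    used = {s.site_id for s in samples}
    report.empty_sites = sorted(site_ids - used)

    iso = [s for s in samples if s.isotope_ready]
    if len(iso) >= 3:
        arr16 = np.array([s.d13c_16 for s in iso])
        arr18 = np.array([s.d13c_18 for s in iso])
        for arr in (arr16, arr18):
            mu, sd = arr.mean(), arr.std(ddof=1)
            if sd > 0:
                flagged = np.abs(arr - mu) > 3 * sd
                for s, bad in zip(iso, flagged):
                    if bad and s.sample_id not in report.isotope_outliers:
                        report.isotope_outliers.append(s.sample_id)
    return report
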