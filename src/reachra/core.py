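"""Reach-equity analysis across the rural-urban continuum.

This module implements a complete pipeline for asking whether a health
intervention's users are geographically representative of an eligible
reference population:

1. **Geographic classification** — free-text postal (ZIP) codes from
   registration records are normalized and resolved through a three-stage
   crosswalk (ZIP -> ZCTA -> county -> Rural-Urban Continuum Code) and
   collapsed to three strata: Large Metro (RUCC 1), Small Metro (RUCC 2-3)
   and Nonmetro (RUCC 4-9).
2. **Reach statistics** — per-year stratum proportions for the cohort and
   for a reference population (e.g. NSDUH estimated smoker counts) are
   combined into reach ratios (ReRa = p1/p2) with log-scale Wald
   (Katz-type) 95% confidence intervals.  A ReRa of 1.0 means a stratum is
   proportionally represented; the default interval treats the reference
   proportion as a known constant (its variance term is dropped), with the
   full two-sample interval available behind a config switch.
3. **Synthetic data** — seeded generators for cohorts, crosswalks and
   reference tables with known ground truth, including a log-linear
   ZIP-missingness mechanism in age and gender, so every pipeline stage is
   testable without any proprietary registration data.
4. **Pipeline & reporting** — orchestration that classifies, tabulates,
   computes reach ratios and renders proportion/ReRa tables as CSV and
   plain text.

The module is laid out in the order the method runs; the command-line
interface in :mod:`reachra.__main__` is a thin wrapper over these
functions.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import contingency as _contingency

__all__ = [
    # configuration
    "AreaCategory",
    "CATEGORY_ORDER",
    "AnalysisConfig",
    "ReachraError",
    "ZipFormatError",
    "CrosswalkLookupError",
    "RuccRangeError",
    "EmptyStratumError",
    "MissingCategoryError",
    "UndefinedRatioError",
    "DegenerateProportionError",
    "YearMismatchError",
    "round_half_even",
    # geographic classification
    "RegistrationRecord",
    "Crosswalk",
    "ClassificationReport",
    "normalize_zip",
    "resolve_zcta_county",
    "collapse_rucc",
    "classify_cohort",
    "missingness_summary",
    "MissingnessSummary",
    "RelativeRisk",
    "relative_risk_2x2",
    # reach statistics
    "StratumTable",
    "ReachRatioResult",
    "cohort_proportions",
    "cohort_stratum_tables",
    "reference_proportions",
    "reference_stratum_tables",
    "stratum_tables_from_percent",
    "reach_ratio",
    "reach_ratio_ci",
    "reach_ratio_ci_two_sample",
    "reach_table",
    "results_frame",
    # synthetic data
    "SimulationScenario",
    "SyntheticFixture",
    "gen_crosswalk",
    "gen_reference",
    "gen_cohort",
    # pipeline & reporting
    "PipelineRun",
    "run_pipeline",
    "render_reports",
    "read_cohort_csv",
    "read_crosswalk_dir",
    "read_reference_csv",
]

logger = logging.getLogger("reachra")


# --------------------------------------------------------------------------
# configuration, constants and errors
# --------------------------------------------------------------------------


class AreaCategory(str, Enum):
    """Collapsed rural-urban stratum.

    Large Metro counties are RUCC 1 (metro areas of 1M+ people), Small
    Metro counties are RUCC 2-3, and Nonmetro counties are RUCC 4-9.
    UNCLASSIFIED marks records whose postal code could not be resolved to
    a RUCC value; such records are excluded from reach-ratio numerators.
    """

    LARGE_METRO = "LARGE_METRO"
    SMALL_METRO = "SMALL_METRO"
    NONMETRO = "NONMETRO"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the three named strata, in reporting order (UNCLASSIFIED excluded)
CATEGORY_ORDER: tuple[AreaCategory, ...] = (
    AreaCategory.LARGE_METRO,
    AreaCategory.SMALL_METRO,
    AreaCategory.NONMETRO,
)

#: default two-sided 95% critical value (scipy.stats.norm.ppf(0.975) to 6 dp)
DEFAULT_Z = 1.959964


class ReachraError(Exception):
    """Base class for all errors raised by this package."""


class ZipFormatError(ReachraError):
    """A raw postal code could not be normalized to 5 digits."""

    def __init__(self, raw: str, reason: str):
        self.raw = raw
        self.reason = reason  # one of: empty, non_numeric, wrong_length
        super().__init__(f"invalid ZIP {raw!r}: {reason}")


class CrosswalkLookupError(ReachraError, KeyError):
    """A ZIP, ZCTA or county is absent from the crosswalk."""


class RuccRangeError(ReachraError, ValueError):
    """A RUCC value outside 1-9."""


class EmptyStratumError(ReachraError):
    """No classified records available where at least one is required."""


class MissingCategoryError(ReachraError):
    """A reference table lacks a required category for a year."""


class UndefinedRatioError(ReachraError):
    """Reach ratio requested with a zero reference proportion."""


class DegenerateProportionError(ReachraError):
    """Interval requested for p in {0, 1}, where the log-scale SE is undefined."""


class YearMismatchError(ReachraError):
    """Cohort and reference tables do not cover the same years."""

    def __init__(self, missing_in_reference: Sequence[int], missing_in_cohort: Sequence[int] = ()):
        self.missing_in_reference = tuple(missing_in_reference)
        self.missing_in_cohort = tuple(missing_in_cohort)
        super().__init__(
            f"year coverage mismatch: missing in reference {list(missing_in_reference)}, "
            f"missing in cohort {list(missing_in_cohort)}"
        )


def round_half_even(x: float, decimals: int = 2) -> float:
    """Round to ``decimals`` places with banker's (half-even) rounding.

    Operates on the shortest decimal representation of the float so that
    values such as 1.005 stored as 1.00499... round the way a human reading
    the printed number expects.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical settings for the reach-ratio analysis.

    Parameters
    ----------
    alpha
        Two-sided significance level for the confidence intervals.
    z
        Critical value.  If None it is derived from ``alpha`` via the
        normal quantile; the default 1.959964 is the 97.5% quantile to six
        decimals (1.96 gives identical results at two-decimal reporting).
    rounding
        Decimal places for reported ReRa and CI endpoints.
    interval_variant
        ``"fixed_reference"`` drops the reference sample's variance term
        (the reference proportion is treated as a known constant);
        ``"two_sample"`` is the full Katz interval for two independent
        binomial proportions.
    """

    alpha: float = 0.05
    z: float | None = DEFAULT_Z
    rounding: int = 2
    interval_variant: str = "fixed_reference"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ReachraError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rounding < 0:
            raise ReachraError("rounding must be >= 0")
        if self.interval_variant not in ("fixed_reference", "two_sample"):
            raise ReachraError(f"unknown interval_variant {self.interval_variant!r}")

    @property
    def critical_value(self) -> float:
        if self.z is not None:
            return self.z
        return float(stats.norm.ppf(1.0 - self.alpha / 2.0))


# --------------------------------------------------------------------------
# geographic classification: ZIP -> ZCTA -> county -> RUCC -> stratum
# --------------------------------------------------------------------------

#: 5 digits, optionally followed by a +4 extension (with or without a dash)
_ZIP_RE = re.compile(r"^(\d{5})(?:-\d{4}|\d{4})?$")


@dataclass(frozen=True)
class RegistrationRecord:
    """One cohort member: registration year, raw postal code, optional demographics.

    ``raw_zip`` is free text as typed at registration ("" = not provided);
    ``age_years`` is None when age was not provided; ``gender`` is one of
    "female", "male" or "" (not provided).
    """

    user_id: str
    year: int
    raw_zip: str = ""
    age_years: float | None = None
    gender: str = ""


#: cohort CSV / DataFrame column order
COHORT_COLUMNS = ("user_id", "year", "zip", "age", "gender")


def records_to_frame(records: Iterable[RegistrationRecord]) -> pd.DataFrame:
    """Convert RegistrationRecord objects to the canonical cohort DataFrame."""
    rows = [
        (r.user_id, r.year, r.raw_zip, np.nan if r.age_years is None else r.age_years, r.gender)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def normalize_zip(raw_zip: str) -> str:
    """Normalize free-text postal input to a 5-digit ZIP string.

    Surrounding whitespace is stripped and a ZIP+4 extension (with or
    without the dash) is truncated to the first five digits.  Leading
    zeros are preserved: ZIPs are strings, never integers.  Four-digit
    input is rejected rather than zero-padded, because a stripped leading
    zero cannot be distinguished from a typo.

    Raises
    ------
    ZipFormatError
        with ``reason`` in {"empty", "non_numeric", "wrong_length"}.
    """
    s = str(raw_zip).strip()
    if not s:
        raise ZipFormatError(raw_zip, "empty")
    m = _ZIP_RE.match(s)
    if m:
        return m.group(1)
    core = s.split("-", 1)[0].strip()
    if not core or not core.isdigit():
        raise ZipFormatError(raw_zip, "non_numeric")
    raise ZipFormatError(raw_zip, "wrong_length")


@dataclass(frozen=True)
class Crosswalk:
    """Three-stage geographic mapping with weights for many-to-many links.

    ``zip_to_zcta`` maps 5-digit ZIP strings to ZCTA identifiers;
    ``zcta_to_county`` maps each ZCTA to one or more (county FIPS,
    population-overlap weight) pairs; ``county_to_rucc`` maps 5-character
    county FIPS strings to RUCC integers 1-9.  ``vintage`` labels the
    code revision the county table carries (RUCC is revised each
    decennial census).
    """

    zip_to_zcta: Mapping[str, str]
    zcta_to_county: Mapping[str, tuple[tuple[str, float], ...]]
    county_to_rucc: Mapping[str, int]
    vintage: str = "RUCC2013"

    def __post_init__(self) -> None:
        for county, rucc in self.county_to_rucc.items():
            if not 1 <= int(rucc) <= 9:
                raise RuccRangeError(f"county {county}: RUCC {rucc} outside 1-9")
        for zcta, pairs in self.zcta_to_county.items():
            if pairs and not any(w > 0 for _, w in pairs):
                raise ReachraError(f"ZCTA {zcta}: all county weights are zero")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        zip_to_zcta: pd.DataFrame,
        zcta_to_county: pd.DataFrame,
        county_to_rucc: pd.DataFrame,
        vintage: str = "RUCC2013",
    ) -> "Crosswalk":
        """Build from the three crosswalk tables.

        Expected columns: ``zip,zcta`` / ``zcta,county_fips,weight`` /
        ``county_fips,rucc``.  FIPS and ZIP columns are read as strings
        and zero-padded to five characters.
        """
        z2z = {
            str(z).zfill(5): str(zc).strip()
            for z, zc in zip(zip_to_zcta["zip"], zip_to_zcta["zcta"])
        }
        z2c: dict[str, list[tuple[str, float]]] = {}
        for zcta, fips, w in zip(
            zcta_to_county["zcta"], zcta_to_county["county_fips"], zcta_to_county["weight"]
        ):
            z2c.setdefault(str(zcta).strip(), []).append((str(fips).zfill(5), float(w)))
        c2r = {
            str(f).zfill(5): int(r)
            for f, r in zip(county_to_rucc["county_fips"], county_to_rucc["rucc"])
        }
        return cls(
            zip_to_zcta=z2z,
            zcta_to_county={k: tuple(v) for k, v in z2c.items()},
            county_to_rucc=c2r,
            vintage=vintage,
        )

    @classmethod
    def from_dir(cls, directory: str | Path, vintage: str = "RUCC2013") -> "Crosswalk":
        """Load ``zip_to_zcta.csv``, ``zcta_to_county.csv`` and
        ``county_to_rucc.csv`` from a directory."""
        d = Path(directory)
        return cls.from_frames(
            pd.read_csv(d / "zip_to_zcta.csv", dtype={"zip": str, "zcta": str}),
            pd.read_csv(d / "zcta_to_county.csv", dtype={"zcta": str, "county_fips": str}),
            pd.read_csv(d / "county_to_rucc.csv", dtype={"county_fips": str}),
            vintage=vintage,
        )

    def write_dir(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(z, zc) for z, zc in sorted(self.zip_to_zcta.items())], columns=["zip", "zcta"]
        ).to_csv(d / "zip_to_zcta.csv", index=False)
        pd.DataFrame(
            [
                (zcta, fips, w)
                for zcta, pairs in sorted(self.zcta_to_county.items())
                for fips, w in pairs
            ],
            columns=["zcta", "county_fips", "weight"],
        ).to_csv(d / "zcta_to_county.csv", index=False)
        pd.DataFrame(
            [(f, r) for f, r in sorted(self.county_to_rucc.items())],
            columns=["county_fips", "rucc"],
        ).to_csv(d / "county_to_rucc.csv", index=False)

    # -- resolution --------------------------------------------------------

    def dominant_county(self) -> dict[str, str]:
        """ZCTA -> county chosen by largest population-overlap weight,
        ties broken by lexicographically smallest FIPS."""
        return {
            zcta: resolve_zcta_county(zcta, self)
            for zcta in self.zcta_to_county
        }

    def rucc_for_zip(self, zip5: str) -> int:
        """Resolve a normalized 5-digit ZIP to its RUCC value."""
        try:
            zcta = self.zip_to_zcta[zip5]
        except KeyError:
            raise CrosswalkLookupError(f"ZIP {zip5} has no ZCTA") from None
        county = resolve_zcta_county(zcta, self)
        try:
            return self.county_to_rucc[county]
        except KeyError:
            raise CrosswalkLookupError(f"county {county} has no RUCC") from None

    def classify_zip(self, zip5: str) -> AreaCategory:
        return collapse_rucc(self.rucc_for_zip(zip5))


def resolve_zcta_county(zcta: str, crosswalk: Crosswalk) -> str:
    """Pick the county for a ZCTA by dominant population-overlap weight.

    Ties are broken deterministically by the lexicographically smallest
    county FIPS, so classification is byte-reproducible.
    """
    try:
        pairs = crosswalk.zcta_to_county[zcta]
    except KeyError:
        raise CrosswalkLookupError(f"ZCTA {zcta} has no county links") from None
    if not pairs:
        raise CrosswalkLookupError(f"ZCTA {zcta} has no county links")
    # max weight first, then smallest FIPS
    return min(pairs, key=lambda fw: (-fw[1], fw[0]))[0]


def collapse_rucc(rucc: int) -> AreaCategory:
    """Collapse a RUCC value 1-9 to the three-stratum scheme."""
    r = int(rucc)
    if r == 1:
        return AreaCategory.LARGE_METRO
    if r in (2, 3):
        return AreaCategory.SMALL_METRO
    if 4 <= r <= 9:
        return AreaCategory.NONMETRO
    raise RuccRangeError(f"RUCC {rucc} outside 1-9")


@dataclass(frozen=True)
class ClassificationReport:
    """Audit of how many records received a RUCC-based stratum.

    ``failure_reasons`` tallies are exhaustive and mutually exclusive:
    empty (no ZIP provided), malformed (not a 5-digit code after cleanup)
    and unmapped (valid format but absent from some crosswalk stage).
    """

    total_records: int
    valid_zip_records: int
    per_year: pd.DataFrame  # columns: year, total, valid, fraction
    failure_reasons: Mapping[str, int]

    @property
    def valid_zip_fraction(self) -> float:
        """Share of records with a valid, RUCC-assigned ZIP (0 for an empty cohort)."""
        if self.total_records == 0:
            return 0.0
        return self.valid_zip_records / self.total_records

    @property
    def valid_zip_percent(self) -> float:
        """valid_zip_fraction as a percentage rounded half-even to 2 dp."""
        return round_half_even(100.0 * self.valid_zip_fraction, 2)

    @classmethod
    def from_counts(
        cls,
        total_records: int,
        valid_zip_records: int,
        per_year: pd.DataFrame | None = None,
        failure_reasons: Mapping[str, int] | None = None,
    ) -> "ClassificationReport":
        """Build a report directly from tallies (e.g. published sample accounting)."""
        if valid_zip_records > total_records:
            raise ReachraError("valid_zip_records exceeds total_records")
        if per_year is None:
            per_year = pd.DataFrame(columns=["year", "total", "valid", "fraction"])
        if failure_reasons is None:
            failure_reasons = {
                "empty": 0,
                "malformed": 0,
                "unmapped": total_records - valid_zip_records,
            }
        return cls(total_records, valid_zip_records, per_year, dict(failure_reasons))

    def to_frame(self) -> pd.DataFrame:
        rows = [("ALL", self.total_records, self.valid_zip_records, self.valid_zip_fraction)]
        rows += [
            (str(int(r.year)), int(r.total), int(r.valid), float(r.fraction))
            for r in self.per_year.itertuples()
        ]
        return pd.DataFrame(rows, columns=["year", "total", "valid", "fraction"])

    def to_text(self) -> str:
        lines = [
            "Classification report",
            f"  records:            {self.total_records}",
            f"  assigned a stratum: {self.valid_zip_records} "
            f"({self.valid_zip_percent:.2f}%)",
            "  failure reasons:    "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.failure_reasons.items())),
        ]
        if len(self.per_year):
            lines.append("  per year:")
            for r in self.per_year.itertuples():
                lines.append(
                    f"    {int(r.year)}: {int(r.valid)}/{int(r.total)} "
                    f"({100 * float(r.fraction):.2f}%)"
                )
        return "\n".join(lines) + "\n"


def _normalize_zip_series(raw: pd.Series) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Vectorized normalize_zip: (zip5 or NaN, empty mask, malformed mask)."""
    s = raw.fillna("").astype(str).str.strip()
    empty = s == ""
    zip5 = s.str.extract(_ZIP_RE, expand=False)
    malformed = ~empty & zip5.isna()
    return zip5, empty, malformed


def classify_cohort(
    records: pd.DataFrame | Iterable[RegistrationRecord],
    crosswalk: Crosswalk,
) -> tuple[pd.DataFrame, ClassificationReport]:
    """Assign every record an AreaCategory and audit the failures.

    Records whose ZIP is empty or malformed, or fails at any crosswalk
    stage, receive UNCLASSIFIED; failures are tallied, never raised.  The
    returned frame adds ``zip5``, ``rucc`` (nullable integer) and
    ``category`` columns; the four category tallies always partition the
    cohort exactly.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    df = records.copy()
    if len(df) == 0:
        df["zip5"] = pd.Series(dtype=object)
        df["rucc"] = pd.Series(dtype="Int64")
        df["category"] = pd.Series(dtype=object)
        report = ClassificationReport(
            0, 0, pd.DataFrame(columns=["year", "total", "valid", "fraction"]),
            {"empty": 0, "malformed": 0, "unmapped": 0},
        )
        return df, report

    zip5, empty, malformed = _normalize_zip_series(df["zip"])
    dominant = crosswalk.dominant_county()
    zcta = zip5.map(crosswalk.zip_to_zcta)
    county = zcta.map(dominant)
    rucc = county.map(crosswalk.county_to_rucc)
    unmapped = zip5.notna() & rucc.isna()

    rucc = rucc.astype("Int64")
    category = pd.Series(AreaCategory.UNCLASSIFIED.value, index=df.index, dtype=object)
    ok = rucc.notna()
    if ok.any():
        category.loc[ok] = [collapse_rucc(r).value for r in rucc[ok]]

    df["zip5"] = zip5
    df["rucc"] = rucc
    df["category"] = category

    valid = ok
    per_year = (
        pd.DataFrame({"year": df["year"].astype(int), "valid": valid.astype(int)})
        .groupby("year", as_index=False)
        .agg(total=("valid", "size"), valid=("valid", "sum"))
    )
    per_year["fraction"] = per_year["valid"] / per_year["total"]
    report = ClassificationReport(
        total_records=int(len(df)),
        valid_zip_records=int(valid.sum()),
        per_year=per_year,
        failure_reasons={
            "empty": int(empty.sum()),
            "malformed": int(malformed.sum()),
            "unmapped": int(unmapped.sum()),
        },
    )
    logger.info(
        "classified %d/%d records (%.2f%%) [vintage %s]",
        report.valid_zip_records, report.total_records,
        100 * report.valid_zip_fraction, crosswalk.vintage,
    )
    return df, report


# -- missingness audit -----------------------------------------------------


@dataclass(frozen=True)
class RelativeRisk:
    """Ratio of two proportions with a two-sample log-scale Wald CI."""

    rr: float | None
    ci_low: float | None
    ci_high: float | None
    defined: bool = True


def relative_risk_2x2(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> RelativeRisk:
    """RR = (k1/n1)/(k2/n2) with a log-scale Wald interval.

    Returns an undefined result (rather than raising) when either group
    is empty or the comparison proportion is zero, so callers tabulating
    many strata can flag and move on.
    """
    if n1 == 0 or n2 == 0 or k2 == 0:
        return RelativeRisk(None, None, None, defined=False)
    res = _contingency.relative_risk(k1, n1, k2, n2)
    if not math.isfinite(res.relative_risk) or res.relative_risk == 0.0:
        return RelativeRisk(float(res.relative_risk), None, None, defined=False)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    return RelativeRisk(float(res.relative_risk), float(ci.low), float(ci.high))


@dataclass(frozen=True)
class MissingnessSummary:
    """Descriptive audit of who provides a postal code at registration.

    ``table`` holds one row per year x age-decade x gender cell with the
    provision proportion; ``rr_female_overall`` and ``rr_female_by_year``
    compare women to men (ratio > 1 means women provide ZIPs more often).
    Cells with an empty comparison stratum carry an undefined RR flag.
    """

    table: pd.DataFrame
    rr_female_overall: RelativeRisk
    rr_female_by_year: Mapping[int, RelativeRisk]


def missingness_summary(records: pd.DataFrame, alpha: float = 0.05) -> MissingnessSummary:
    """Tabulate ZIP-provision proportions by year, age decade and gender.

    A record "provides" a ZIP when its raw postal code normalizes to five
    digits (crosswalk coverage is deliberately not required here: the
    audit concerns registration behaviour, not geography).
    """
    df = records.copy()
    zip5, _, _ = _normalize_zip_series(df["zip"])
    df["provided"] = zip5.notna()
    age = pd.to_numeric(df.get("age"), errors="coerce")
    df["age_decade"] = np.where(age.notna(), np.floor(age / 10.0), np.nan)
    gender = df.get("gender", pd.Series("", index=df.index)).fillna("").astype(str)
    df["gender"] = gender.where(gender.isin(["female", "male"]), "missing")

    table = (
        df.groupby(["year", "age_decade", "gender"], dropna=False, as_index=False)
        .agg(n=("provided", "size"), provided=("provided", "sum"))
    )
    table["proportion"] = table["provided"] / table["n"]

    def _rr(sub: pd.DataFrame) -> RelativeRisk:
        f = sub[sub["gender"] == "female"]
        m = sub[sub["gender"] == "male"]
        return relative_risk_2x2(
            int(f["provided"].sum()), int(len(f)),
            int(m["provided"].sum()), int(len(m)),
            alpha=alpha,
        )

    overall = _rr(df)
    by_year = {int(y): _rr(sub) for y, sub in df.groupby("year")}
    return MissingnessSummary(table=table, rr_female_overall=overall, rr_female_by_year=by_year)


# --------------------------------------------------------------------------
# reach statistics: stratum proportions, ReRa, log-scale Wald intervals
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumTable:
    """Per-year stratum counts and proportions for one population.

    For a cohort, ``counts`` are classified user counts and ``n`` is the
    number of classified users that year.  For a reference population,
    counts are estimated totals (e.g. smokers in thousands) and ``n`` is
    their sum.  Proportions over the three named strata sum to 1 (tables
    built from rounded published percentages may be off by the printed
    rounding, hence the construction-time tolerance).
    """

    year: int
    counts: Mapping[AreaCategory, float] | None
    n: float
    proportions: Mapping[AreaCategory, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions[c] for c in CATEGORY_ORDER)
        if not math.isclose(total, 1.0, abs_tol=1e-3):
            raise ReachraError(
                f"year {self.year}: stratum proportions sum to {total}, expected 1"
            )
        if self.counts is not None and any(v < 0 for v in self.counts.values()):
            raise ReachraError(f"year {self.year}: negative stratum count")

    @classmethod
    def from_counts(cls, year: int, counts: Mapping[AreaCategory, float]) -> "StratumTable":
        missing = [c for c in CATEGORY_ORDER if c not in counts]
        if missing:
            raise MissingCategoryError(f"year {year}: missing categories {missing}")
        n = float(sum(counts[c] for c in CATEGORY_ORDER))
        if n <= 0:
            raise EmptyStratumError(f"year {year}: no counts")
        props = {c: counts[c] / n for c in CATEGORY_ORDER}
        return cls(int(year), {c: float(counts[c]) for c in CATEGORY_ORDER}, n, props)

    @classmethod
    def from_percent(
        cls, year: int, percent: Mapping[AreaCategory, float], n: float
    ) -> "StratumTable":
        """Build from published percentages (e.g. a printed table) plus a total."""
        props = {c: float(percent[c]) / 100.0 for c in CATEGORY_ORDER}
        return cls(int(year), None, float(n), props)

    def proportion(self, category: AreaCategory) -> float:
        return self.proportions[category]


def cohort_proportions(classified: pd.DataFrame, year: int) -> StratumTable:
    """Stratum proportions among classified cohort members for one year.

    UNCLASSIFIED records are excluded from both numerator and denominator;
    a year with no classified records raises EmptyStratumError.
    """
    sub = classified[(classified["year"] == year)]
    sub = sub[sub["category"] != AreaCategory.UNCLASSIFIED.value]
    if len(sub) == 0:
        raise EmptyStratumError(f"year {year}: no classified records")
    vc = sub["category"].value_counts()
    counts = {c: float(vc.get(c.value, 0)) for c in CATEGORY_ORDER}
    return StratumTable.from_counts(year, counts)


def cohort_stratum_tables(classified: pd.DataFrame) -> dict[int, StratumTable]:
    """cohort_proportions for every year present with classified records."""
    years = sorted(
        classified.loc[
            classified["category"] != AreaCategory.UNCLASSIFIED.value, "year"
        ].unique()
    )
    return {int(y): cohort_proportions(classified, int(y)) for y in years}


def reference_proportions(reference: pd.DataFrame, year: int) -> StratumTable:
    """Stratum proportions for the reference population in one year.

    ``reference`` has columns ``year, category, smokers_thousands``; the
    total is the sum over the three categories (published totals may
    differ from this sum by their own rounding).
    """
    sub = reference[reference["year"] == year]
    counts = {}
    for c in CATEGORY_ORDER:
        rows = sub[sub["category"] == c.value]
        if len(rows) == 0:
            raise MissingCategoryError(f"year {year}: reference lacks {c.value}")
        counts[c] = float(rows["smokers_thousands"].sum())
    return StratumTable.from_counts(year, counts)


def reference_stratum_tables(reference: pd.DataFrame) -> dict[int, StratumTable]:
    return {
        int(y): reference_proportions(reference, int(y))
        for y in sorted(reference["year"].unique())
    }


def stratum_tables_from_percent(
    percent: pd.DataFrame, totals: Mapping[int, float]
) -> dict[int, StratumTable]:
    """Build StratumTables from a published percentage table.

    ``percent`` has columns ``year, category, percent``; ``totals`` maps
    year to the population total (classified cohort size, or reference
    total)."""
    out: dict[int, StratumTable] = {}
    for y in sorted(percent["year"].unique()):
        sub = percent[percent["year"] == y]
        pc = {
            c: float(sub.loc[sub["category"] == c.value, "percent"].iloc[0])
            for c in CATEGORY_ORDER
        }
        out[int(y)] = StratumTable.from_percent(int(y), pc, float(totals[int(y)]))
    return out


def reach_ratio(p1: float, p2: float) -> float:
    """ReRa = p1/p2: cohort share over reference share for one stratum."""
    if p2 <= 0:
        raise UndefinedRatioError(f"reference proportion must be positive, got {p2}")
    return p1 / p2


def _check_p1(p1: float, n1: float) -> None:
    if not 0.0 < p1 < 1.0:
        raise DegenerateProportionError(
            f"cohort proportion must be strictly inside (0, 1), got {p1}"
        )
    if n1 < 1:
        raise ReachraError(f"cohort size must be >= 1, got {n1}")


def reach_ratio_ci(
    p1: float, n1: float, p2: float, config: AnalysisConfig | None = None
) -> tuple[float, float]:
    """Fixed-reference log-scale Wald (Katz-type) interval for p1/p2.

    The reference proportion is treated as a known constant: the interval
    is ``exp(ln(p1/p2) +/- z * sqrt((1-p1)/(n1*p1)))``.  Appropriate when
    the reference comes from a population-scale survey whose sampling
    variance is negligible (or deliberately ignored) relative to the
    cohort's.
    """
    config = config or AnalysisConfig()
    _check_p1(p1, n1)
    rr = reach_ratio(p1, p2)
    se = math.sqrt((1.0 - p1) / (n1 * p1))
    z = config.critical_value
    return math.exp(math.log(rr) - z * se), math.exp(math.log(rr) + z * se)


def reach_ratio_ci_two_sample(
    p1: float, n1: float, p2: float, n2: float, config: AnalysisConfig | None = None
) -> tuple[float, float]:
    """Full two-sample Katz interval for a ratio of binomial proportions.

    Adds the reference sample's variance term, so it is always at least
    as wide as the fixed-reference interval and converges to it as
    ``n2 -> inf``.
    """
    config = config or AnalysisConfig()
    _check_p1(p1, n1)
    if not 0.0 < p2 < 1.0:
        raise DegenerateProportionError(
            f"reference proportion must be strictly inside (0, 1), got {p2}"
        )
    if n2 < 1:
        raise ReachraError(f"reference size must be >= 1, got {n2}")
    rr = reach_ratio(p1, p2)
    se = math.sqrt((1.0 - p1) / (n1 * p1) + (1.0 - p2) / (n2 * p2))
    z = config.critical_value
    return math.exp(math.log(rr) - z * se), math.exp(math.log(rr) + z * se)


@dataclass(frozen=True)
class ReachRatioResult:
    """ReRa point estimate, CI and significance flag for one year x stratum.

    ``significant`` is True iff 1.0 lies outside the unrounded interval.
    """

    year: int
    category: AreaCategory
    rera: float
    ci_low: float
    ci_high: float
    significant: bool

    def rounded(self, decimals: int = 2) -> tuple[float, float, float]:
        return (
            round_half_even(self.rera, decimals),
            round_half_even(self.ci_low, decimals),
            round_half_even(self.ci_high, decimals),
        )

    def display(self, decimals: int = 2, marker: str = "*") -> str:
        r, lo, hi = self.rounded(decimals)
        flag = marker if self.significant else ""
        return f"{r:.{decimals}f} ({lo:.{decimals}f}-{hi:.{decimals}f}){flag}"


def reach_table(
    cohort_tables: Mapping[int, StratumTable],
    reference_tables: Mapping[int, StratumTable],
    config: AnalysisConfig | None = None,
) -> list[ReachRatioResult]:
    """Reach ratios with CIs for every year x stratum.

    Years must match between cohort and reference tables; a mismatch is a
    structured error listing the missing years on each side.
    """
    config = config or AnalysisConfig()
    cohort_years = set(cohort_tables)
    reference_years = set(reference_tables)
    if cohort_years != reference_years:
        raise YearMismatchError(
            missing_in_reference=sorted(cohort_years - reference_years),
            missing_in_cohort=sorted(reference_years - cohort_years),
        )
    results: list[ReachRatioResult] = []
    for year in sorted(cohort_years):
        ct, rt = cohort_tables[year], reference_tables[year]
        for cat in CATEGORY_ORDER:
            p1 = ct.proportion(cat)
            p2 = rt.proportion(cat)
            rr = reach_ratio(p1, p2)
            if config.interval_variant == "two_sample":
                lo, hi = reach_ratio_ci_two_sample(p1, ct.n, p2, rt.n, config)
            else:
                lo, hi = reach_ratio_ci(p1, ct.n, p2, config)
            results.append(
                ReachRatioResult(
                    year=year,
                    category=cat,
                    rera=rr,
                    ci_low=lo,
                    ci_high=hi,
                    significant=not (lo <= 1.0 <= hi),
                )
            )
    return results


def results_frame(
    results: Sequence[ReachRatioResult], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Tabulate results with values rounded per the analysis config."""
    config = config or AnalysisConfig()
    d = config.rounding
    rows = []
    for r in results:
        rr, lo, hi = r.rounded(d)
        rows.append((r.year, r.category.value, rr, lo, hi, r.significant))
    return pd.DataFrame(
        rows, columns=["year", "category", "rera", "ci_low", "ci_high", "significant"]
    )


# --------------------------------------------------------------------------
# synthetic data: cohorts, crosswalks and reference tables with ground truth
# --------------------------------------------------------------------------

# Default study conditions: a 2013-2017 US web-based cessation cohort
# compared with NSDUH smoker estimates.  Classified cohort totals per year
# and published stratum percentages; registered sizes are the classified
# totals divided by the overall valid-ZIP share (0.5334), since per-year
# registration totals are not published.

DEFAULT_YEARS: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017)

DEFAULT_CLASSIFIED_TOTALS: dict[int, int] = {
    2013: 33484, 2014: 18255, 2015: 5491, 2016: 1820, 2017: 8832,
}

DEFAULT_PROVISION_BASELINE = 0.5334

DEFAULT_COHORT_SIZES: dict[int, int] = {
    y: int(round(n / DEFAULT_PROVISION_BASELINE))
    for y, n in DEFAULT_CLASSIFIED_TOTALS.items()
}

#: cohort stratum probabilities (Large Metro, Small Metro, Nonmetro) per year
DEFAULT_CATEGORY_PROBS: dict[int, tuple[float, float, float]] = {
    2013: (0.4886, 0.3316, 0.1798),
    2014: (0.5063, 0.3253, 0.1684),  # published panel sums to 99.99; remainder to Nonmetro
    2015: (0.4886, 0.3305, 0.1809),
    2016: (0.4385, 0.3670, 0.1945),
    2017: (0.4265, 0.3624, 0.2111),
}

#: reference smoker counts (thousands) per year, consistent with published
#: totals and 2-dp stratum percentages
DEFAULT_REFERENCE_COUNTS: dict[int, dict[str, int]] = {
    2013: {"LARGE_METRO": 26849, "SMALL_METRO": 17643, "NONMETRO": 11286},
    2014: {"LARGE_METRO": 27656, "SMALL_METRO": 17125, "NONMETRO": 10459},
    2015: {"LARGE_METRO": 26124, "SMALL_METRO": 17108, "NONMETRO": 8719},
    2016: {"LARGE_METRO": 25259, "SMALL_METRO": 16421, "NONMETRO": 9653},
    2017: {"LARGE_METRO": 23458, "SMALL_METRO": 16385, "NONMETRO": 8849},
}

# substream ids so adding a generator never perturbs another's draws
_STREAM_CROSSWALK, _STREAM_COHORT, _STREAM_REFERENCE = 11, 23, 37


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named PCG64 substream: independent generator per (seed, component, ...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth description of a synthetic registration study.

    Defaults emulate the study conditions of a five-year web-based
    cessation cohort: per-year stratum probabilities and cohort sizes,
    NSDUH-style reference counts, and a ZIP-provision mechanism that is
    log-linear in age (RR 1.03 per decade) and gender (RR 1.10 for
    women), with provision probability
    ``clamp(baseline * rr_age^((age-40)/10) * rr_female^is_female)``
    anchored at a 40-year-old man.  ``informative_missingness`` maps a
    category to a provision multiplier, switching on the selection
    mechanism the analysis cannot correct for.
    """

    seed: int = 0
    years: tuple[int, ...] = DEFAULT_YEARS
    cohort_sizes: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    category_probs: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    reference_counts: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {y: dict(v) for y, v in DEFAULT_REFERENCE_COUNTS.items()}
    )
    provision_baseline: float = DEFAULT_PROVISION_BASELINE
    rr_age_per_decade: float = 1.03
    rr_female: float = 1.10
    age_mean: float = 40.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 80.0
    age_missing_rate: float = 0.2278
    gender_missing_rate: float = 0.2339
    p_female: float = 0.5
    informative_missingness: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for y in self.years:
            probs = self.category_probs[y]
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ReachraError(f"year {y}: category probabilities sum to {sum(probs)}")
        if not 0.0 < self.provision_baseline < 1.0:
            raise ReachraError("provision_baseline must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimulationScenario":
        """Load a scenario from a flat TOML file.

        Per-year maps use string year keys, e.g.
        ``cohort_sizes = {"2013" = 62000}``.
        """
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        for key in ("cohort_sizes", "category_probs", "reference_counts"):
            if key in raw:
                raw[key] = {int(y): v for y, v in raw[key].items()}
        if "category_probs" in raw:
            raw["category_probs"] = {
                y: tuple(v) for y, v in raw["category_probs"].items()
            }
        if "years" in raw:
            raw["years"] = tuple(int(y) for y in raw["years"])
        return cls(**raw)


@dataclass(frozen=True)
class SyntheticFixture:
    """A complete synthetic input set plus its ground truth.

    ``cohort`` is a registration table (ZIP withheld per the missingness
    model); ``truth`` carries every record's true category and provision
    propensity, so recovery tests can compare estimates to known values.
    """

    cohort: pd.DataFrame
    crosswalk: Crosswalk
    reference: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(d / "cohort.csv", index=False)
        self.crosswalk.write_dir(d)
        self.reference.to_csv(d / "reference.csv", index=False)
        self.truth.to_csv(d / "truth.csv", index=False)


def gen_crosswalk(
    n_zips_per_category: int = 20,
    seed: int = 0,
    multi_county_fraction: float = 0.0,
    dominant_weight: float = 0.8,
) -> Crosswalk:
    """Synthetic three-stage crosswalk wired so each ZIP has a known stratum.

    ZIPs for category *i* (0 = Large Metro, 1 = Small Metro, 2 = Nonmetro)
    are ``(i+1)0000 .. (i+1)0000+n-1``; each maps to its own ZCTA and a
    home county whose RUCC lies in the category's range (1 / 2-3 / 4-9).
    A ``multi_county_fraction`` of ZCTAs additionally link to a county of
    a *different* category with weight ``1 - dominant_weight``, so the
    dominant-weight resolution rule is actually exercised: resolving the
    minority link would misclassify the record.
    """
    if n_zips_per_category < 1:
        raise ReachraError("n_zips_per_category must be >= 1")
    if not 0.5 < dominant_weight <= 1.0:
        raise ReachraError("dominant_weight must exceed the minority share")
    rng = _rng(seed, _STREAM_CROSSWALK)
    rucc_pools = {0: [1], 1: [2, 3], 2: [4, 5, 6, 7, 8, 9]}
    zip_to_zcta: dict[str, str] = {}
    zcta_to_county: dict[str, tuple[tuple[str, float], ...]] = {}
    county_to_rucc: dict[str, int] = {}
    home_county: dict[tuple[int, int], str] = {}
    for i in range(3):
        for j in range(n_zips_per_category):
            county = f"{i + 1:02d}{j:03d}"
            county_to_rucc[county] = rucc_pools[i][j % len(rucc_pools[i])]
            home_county[(i, j)] = county
    for i in range(3):
        for j in range(n_zips_per_category):
            zip5 = f"{(i + 1) * 10000 + j:05d}"
            zcta = f"Z{zip5}"
            zip_to_zcta[zip5] = zcta
            links = [(home_county[(i, j)], dominant_weight)]
            if rng.random() < multi_county_fraction:
                other_cat = (i + 1) % 3
                other = home_county[(other_cat, int(rng.integers(n_zips_per_category)))]
                links.append((other, 1.0 - dominant_weight))
            else:
                links[0] = (links[0][0], 1.0)
            zcta_to_county[zcta] = tuple(links)
    return Crosswalk(zip_to_zcta, zcta_to_county, county_to_rucc, vintage="SYNTHETIC")


def _zip_pools(crosswalk: Crosswalk) -> dict[str, list[str]]:
    """Group the crosswalk's ZIPs by the category they classify to."""
    pools: dict[str, list[str]] = {c.value: [] for c in CATEGORY_ORDER}
    for zip5 in sorted(crosswalk.zip_to_zcta):
        pools[crosswalk.classify_zip(zip5).value].append(zip5)
    return pools


def gen_reference(
    scenario: SimulationScenario, noise_sd: float = 0.0
) -> pd.DataFrame:
    """Reference counts table (year, category, smokers_thousands).

    Counts come straight from the scenario; with ``noise_sd`` > 0 each
    count is perturbed multiplicatively by exp(N(0, noise_sd)) using the
    scenario seed's reference substream.
    """
    rng = _rng(scenario.seed, _STREAM_REFERENCE)
    rows = []
    for year in scenario.years:
        for cat in CATEGORY_ORDER:
            count = float(scenario.reference_counts[year][cat.value])
            if noise_sd > 0:
                count *= float(np.exp(rng.normal(0.0, noise_sd)))
            rows.append((year, cat.value, count))
    return pd.DataFrame(rows, columns=["year", "category", "smokers_thousands"])


def gen_cohort(scenario: SimulationScenario, crosswalk: Crosswalk) -> SyntheticFixture:
    """Generate a registration cohort with known category ground truth.

    Per year: categories are multinomial with the scenario's true
    probabilities; a ZIP from the record's category pool is drawn, then
    withheld with probability 1 - provision propensity from the
    log-linear missingness model.  Ages are truncated normal; age and
    gender are independently blanked at the scenario's missingness rates
    (a blank covariate contributes a neutral multiplier to provision).
    Deterministic for a fixed scenario: seeded substreams per year.
    """
    pools = _zip_pools(crosswalk)
    for cat in CATEGORY_ORDER:
        if not pools[cat.value]:
            raise ReachraError(f"crosswalk has no ZIPs classifying to {cat.value}")
    frames, truth_frames = [], []
    for year in scenario.years:
        n = int(scenario.cohort_sizes[year])
        rng = _rng(scenario.seed, _STREAM_COHORT, year)
        cat_idx = rng.choice(3, size=n, p=list(scenario.category_probs[year]))
        categories = np.array([c.value for c in CATEGORY_ORDER])[cat_idx]
        zips = np.empty(n, dtype=object)
        for cat in CATEGORY_ORDER:
            mask = categories == cat.value
            if mask.any():
                pool = np.array(pools[cat.value], dtype=object)
                zips[mask] = pool[rng.integers(0, len(pool), size=int(mask.sum()))]
        a, b = (
            (scenario.age_min - scenario.age_mean) / scenario.age_sd,
            (scenario.age_max - scenario.age_mean) / scenario.age_sd,
        )
        ages = stats.truncnorm.rvs(
            a, b, loc=scenario.age_mean, scale=scenario.age_sd, size=n, random_state=rng
        )
        female = rng.random(n) < scenario.p_female
        age_missing = rng.random(n) < scenario.age_missing_rate
        gender_missing = rng.random(n) < scenario.gender_missing_rate

        decades = np.where(age_missing, 0.0, (ages - scenario.age_mean) / 10.0)
        female_eff = np.where(gender_missing, False, female)
        propensity = (
            scenario.provision_baseline
            * scenario.rr_age_per_decade ** decades
            * np.where(female_eff, scenario.rr_female, 1.0)
        )
        if scenario.informative_missingness:
            mult = np.array(
                [scenario.informative_missingness.get(c, 1.0) for c in categories]
            )
            propensity = propensity * mult
        propensity = np.clip(propensity, 1e-9, 1.0 - 1e-9)
        provided = rng.random(n) < propensity

        user_ids = np.array([f"u{year}-{k:06d}" for k in range(n)])
        frames.append(
            pd.DataFrame(
                {
                    "user_id": user_ids,
                    "year": year,
                    "zip": np.where(provided, zips, ""),
                    "age": np.where(age_missing, np.nan, np.round(ages, 1)),
                    "gender": np.where(
                        gender_missing, "", np.where(female, "female", "male")
                    ),
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "user_id": user_ids,
                    "year": year,
                    "true_category": categories,
                    "provision_propensity": propensity,
                    "provided_zip": provided,
                }
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    reference = gen_reference(scenario)
    return SyntheticFixture(cohort=cohort, crosswalk=crosswalk, reference=reference, truth=truth)


# --------------------------------------------------------------------------
# pipeline & reporting
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class PipelineRun:
    """Everything one pipeline execution produced, plus provenance.

    Outputs are pure functions of the inputs and the AnalysisConfig, so a
    run with identical inputs regenerates byte-identical reports.
    """

    config: AnalysisConfig
    provenance: Mapping[str, object]
    classified: pd.DataFrame
    report: ClassificationReport
    cohort_tables: Mapping[int, StratumTable]
    reference_tables: Mapping[int, StratumTable]
    results: tuple[ReachRatioResult, ...]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a registration table (user_id, year, zip, age, gender)."""
    df = pd.read_csv(
        path, dtype={"user_id": str, "zip": str, "gender": str}, keep_default_na=False,
        na_values=[],
    )
    df["year"] = df["year"].astype(int)
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def read_crosswalk_dir(path: str | Path, vintage: str = "RUCC2013") -> Crosswalk:
    return Crosswalk.from_dir(path, vintage=vintage)


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    """Read reference counts (year, category, smokers_thousands)."""
    df = pd.read_csv(path)
    df["year"] = df["year"].astype(int)
    return df


def run_pipeline(
    cohort: pd.DataFrame | str | Path,
    crosswalk: Crosswalk | str | Path,
    reference: pd.DataFrame | str | Path,
    config: AnalysisConfig | None = None,
    years: Sequence[int] | None = None,
) -> PipelineRun:
    """Classify, tabulate and compute reach ratios in one pass.

    Accepts in-memory objects or file paths (paths are checksummed into
    the provenance record).  Year coverage between cohort and reference
    is validated before any statistic is computed, so a mismatch produces
    a structured error and no partial results.
    """
    config = config or AnalysisConfig()
    provenance: dict[str, object] = {
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "artifact": "reachra 0.1.0",
        "inputs": {},
    }
    if isinstance(cohort, (str, Path)):
        provenance["inputs"]["cohort"] = _sha256(Path(cohort))  # type: ignore[index]
        cohort = read_cohort_csv(cohort)
    if isinstance(crosswalk, (str, Path)):
        d = Path(crosswalk)
        provenance["inputs"]["crosswalk"] = {  # type: ignore[index]
            f.name: _sha256(f) for f in sorted(d.glob("*.csv"))
        }
        crosswalk = read_crosswalk_dir(d)
    if isinstance(reference, (str, Path)):
        provenance["inputs"]["reference"] = _sha256(Path(reference))  # type: ignore[index]
        reference = read_reference_csv(reference)
    provenance["crosswalk_vintage"] = crosswalk.vintage
    provenance["analysis"] = {
        "alpha": config.alpha,
        "z": config.critical_value,
        "rounding": config.rounding,
        "interval_variant": config.interval_variant,
    }

    if years is not None:
        cohort = cohort[cohort["year"].isin(list(years))]
        reference = reference[reference["year"].isin(list(years))]

    classified, report = classify_cohort(cohort, crosswalk)
    cohort_years = set(
        classified.loc[
            classified["category"] != AreaCategory.UNCLASSIFIED.value, "year"
        ].astype(int)
    )
    reference_years = set(reference["year"].astype(int))
    if not cohort_years <= reference_years:
        raise YearMismatchError(
            missing_in_reference=sorted(cohort_years - reference_years)
        )

    cohort_tables = cohort_stratum_tables(classified)
    reference_tables = {
        y: reference_proportions(reference, y) for y in sorted(cohort_years)
    }
    results = reach_table(cohort_tables, reference_tables, config)
    return PipelineRun(
        config=config,
        provenance=provenance,
        classified=classified,
        report=report,
        cohort_tables=cohort_tables,
        reference_tables=reference_tables,
        results=tuple(results),
    )


def _proportions_frame(run: PipelineRun) -> pd.DataFrame:
    rows = []
    for label, tables in (("reference", run.reference_tables), ("cohort", run.cohort_tables)):
        for year in sorted(tables):
            for cat in CATEGORY_ORDER:
                rows.append(
                    (
                        label,
                        year,
                        cat.value,
                        round_half_even(100.0 * tables[year].proportion(cat), 2),
                    )
                )
    return pd.DataFrame(rows, columns=["population", "year", "category", "percent"])


def _reach_text(results: Sequence[ReachRatioResult], decimals: int) -> str:
    """Year-by-stratum ReRa grid, '* ' marking CIs that exclude 1."""
    if not results:
        return "category\n"
    years = sorted({r.year for r in results})
    by = {(r.year, r.category): r for r in results}
    header = ["category"] + [str(y) for y in years]
    lines = ["\t".join(header)]
    for cat in CATEGORY_ORDER:
        cells = [cat.value]
        for y in years:
            r = by.get((y, cat))
            cells.append(r.display(decimals) if r else "")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_reports(run: PipelineRun, out_dir: str | Path, fmt: str = "both") -> list[Path]:
    """Write proportion, reach-ratio and classification reports.

    ``fmt`` is "csv", "text" or "both".  CSV files are machine-readable
    (significance as a boolean column); text files mirror the publication
    layout, rendering each cell as ``x.xx (lo-hi)`` with an asterisk for
    intervals excluding 1.  Decimal separator is always ".".
    """
    if fmt not in ("csv", "text", "both"):
        raise ReachraError(f"unknown report format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    props = _proportions_frame(run)
    res = results_frame(list(run.results), run.config)
    if fmt in ("csv", "both"):
        for name, df in (
            ("proportions.csv", props),
            ("reach.csv", res),
            ("classification.csv", run.report.to_frame()),
        ):
            p = out / name
            df.to_csv(p, index=False)
            written.append(p)
    if fmt in ("text", "both"):
        p = out / "proportions.txt"
        p.write_text(
            props.pivot_table(
                index=["population", "category"], columns="year", values="percent",
                sort=False,
            ).to_string() + "\n"
            if len(props)
            else "population category percent\n"
        )
        written.append(p)
        p = out / "reach.txt"
        p.write_text(_reach_text(list(run.results), run.config.rounding))
        written.append(p)
        p = out / "classification.txt"
        p.write_text(run.report.to_text())
        written.append(p)
    return written
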