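"""Ingestion and transformation of heritability effect sizes.

A meta-analysis of narrow-sense heritability (h2) starts from a table with
one row per published estimate: the estimate itself, its standard error (or
a 95% confidence interval from which the SE can be recovered), the sample
size, and the grouping labels and categorical moderators used downstream.
This module validates that table into :class:`EffectSizeRecord` objects,
applies the standard effect-size conversions (parent-offspring regression
slopes to h2, CI half-width to SE), and implements the Fisher-z sensitivity
transform with its associated trimming rules.

Estimates outside the theoretical [0, 1] bound are *kept* for the
untransformed analyses: negative parent-offspring slopes and >1 estimates
are informative about estimation bias.  They are removed only for the
Fisher-z transform, where arctanh is undefined at |h2| >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "EffectSizeRecord",
    "TransformedRecord",
    "ParseResult",
    "Rejection",
    "FisherZExclusion",
    "SchemaError",
    "parse_effect_table",
    "se_from_ci",
    "h2_from_regression",
    "fisher_z",
    "apply_trimming",
    "write_records",
    "write_rejections",
    "fisher_variance_n_minus_3",
]

# Enumerated moderator levels.  Reference levels (used downstream for
# treatment coding) are listed first.
ENVIRONMENTAL_SETTINGS = ("artificial", "natural")
AGES = ("adult", "juvenile", "mixed")
LAB_METHODS = ("TRF_southern", "TRF_ingel", "qPCR", "other")
STAT_METHODS = ("correlation", "pedigree", "twin", "SNP", "mixed_model")
PARENTAL_SEX = ("nonspecific", "fathers_only", "mothers_only")
REPEATED = ("yes", "no")

_LEVELS = {
    "environmental_setting": ENVIRONMENTAL_SETTINGS,
    "age_at_measurement": AGES,
    "laboratory_method": LAB_METHODS,
    "statistical_method": STAT_METHODS,
    "parental_sex": PARENTAL_SEX,
    "repeated_measurement": REPEATED,
}


class SchemaError(ValueError):
    """A required column is missing or the table is structurally invalid."""


class FisherZExclusion(ValueError):
    """Record cannot be Fisher-z transformed; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class EffectSizeRecord:
    """One heritability estimate with its sampling variance and moderators.

    ``h2`` may lie outside [0, 1]; ``se`` must be strictly positive.  The
    sampling variance is always ``se ** 2`` (the meta-analytic weight).
    """

    estimate_id: str
    study_id: str
    species: str
    h2: float
    se: float
    publication_year: int
    environmental_setting: str
    age_at_measurement: str
    laboratory_method: str
    statistical_method: str
    parental_sex: str
    repeated_measurement: str
    n: int | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.estimate_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.h2):
            raise ValueError(f"{self.estimate_id}: non-finite h2")
        for name, levels in _LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValueError(
                    f"{self.estimate_id}: {name}={value!r} not in {levels}"
                )
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.estimate_id}: n must be positive")

    @property
    def sampling_variance(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class TransformedRecord(EffectSizeRecord):
    """A record on the Fisher-z scale: z = arctanh(h2), var_z keyed to n."""

    z: float = 0.0
    var_z: float = 0.0


@dataclass(frozen=True)
class Rejection:
    estimate_id: str
    reason: str


@dataclass
class ParseResult:
    records: list[EffectSizeRecord]
    rejections: list[Rejection] = field(default_factory=list)


def se_from_ci(estimate: float, ci_upper: float) -> float:
    """Recover a standard error from the upper 95% CI limit.

    Uses only the upper half-width: ``(ci_upper - estimate) / 1.96``.
    """
    if ci_upper < estimate:
        raise ValueError(
            f"malformed interval: upper limit {ci_upper} below estimate {estimate}"
        )
    return (ci_upper - estimate) / 1.96


def h2_from_regression(slope: float, parent_type: str) -> float:
    """Convert a parent-offspring regression slope to heritability.

    The mid-parent slope estimates h2 directly; a single-parent slope
    estimates h2/2, hence is doubled.  Sign is preserved: negative slopes
    yield negative h2 and stay in the dataset.
    """
    if parent_type == "midparent":
        return slope
    if parent_type == "single_parent":
        return 2.0 * slope
    raise ValueError(f"unknown parent_type {parent_type!r}")


def fisher_variance_n_minus_3(n: int) -> float:
    """Standard large-sample variance of Fisher's z: 1 / (n - 3)."""
    if n <= 3:
        raise FisherZExclusion("variance undefined (n <= 3)")
    return 1.0 / (n - 3)


def fisher_z(
    record: EffectSizeRecord,
    variance_rule: Callable[[int], float] = fisher_variance_n_minus_3,
) -> TransformedRecord:
    """Fisher-z transform one record, or raise :class:`FisherZExclusion`.

    arctanh is undefined at |h2| >= 1, so out-of-bound estimates are
    excluded, as are records lacking the sample size the variance rule
    needs.  The variance rule is pluggable because the appropriate sampling
    variance for a transformed heritability (as opposed to a correlation)
    is a modelling choice; the default is the standard 1/(n-3).
    """
    if abs(record.h2) >= 1.0:
        raise FisherZExclusion("|h2| >= 1: arctanh undefined")
    if record.n is None:
        raise FisherZExclusion("missing sample size")
    var_z = variance_rule(record.n)
    z = math.atanh(record.h2)
    return TransformedRecord(
        **{f.name: getattr(record, f.name) for f in fields(EffectSizeRecord)},
        z=z,
        var_z=var_z,
    )


def apply_trimming(
    records: Sequence[EffectSizeRecord],
    variance_rule: Callable[[int], float] = fisher_variance_n_minus_3,
) -> tuple[list[EffectSizeRecord], list[Rejection]]:
    """Split records into (transformable, removed-with-reason).

    The retained set feeds both the transformed sensitivity model (on the
    z scale) and the trimmed sensitivity model (same rows, raw h2 scale).
    Idempotent: trimming an already-trimmed set removes nothing.
    """
    retained: list[EffectSizeRecord] = []
    removed: list[Rejection] = []
    for rec in records:
        try:
            fisher_z(rec, variance_rule)
        except FisherZExclusion as exc:
            removed.append(Rejection(rec.estimate_id, exc.reason))
        else:
            retained.append(rec)
    return retained, removed


_REQUIRED = (
    "estimate_id",
    "study_id",
    "species",
    "publication_year",
    "environmental_setting",
    "age_at_measurement",
    "laboratory_method",
    "statistical_method",
    "parental_sex",
    "repeated_measurement",
)


def parse_effect_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
) -> ParseResult:
    """Read a CSV of effect sizes into validated records.

    ``schema`` maps *our* column names to the names used in the file, so a
    deposited table can be ingested without editing it.  Rows that fail
    validation are collected into the rejection report with a reason; a
    duplicate ``estimate_id`` is a hard error because it breaks the
    estimate-level random effect.

    SE resolution: an ``se`` value wins if present; otherwise a 95% CI
    upper limit (column ``ci_upper``) fills the gap; rows with neither are
    rejected with reason ``"no SE or CI"``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {v: k for k, v in schema.items()}
        frame = frame.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if "h2" not in frame.columns:
        missing.append("h2")
    if "se" not in frame.columns and "ci_upper" not in frame.columns:
        missing.append("se")
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    ids = frame["estimate_id"]
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"duplicate estimate_id(s): {', '.join(dupes)}")

    records: list[EffectSizeRecord] = []
    rejections: list[Rejection] = []
    study_of: dict[str, str] = {}
    for _, row in frame.iterrows():
        eid = row["estimate_id"] or "<blank>"
        try:
            h2 = float(row["h2"])
        except (ValueError, TypeError):
            rejections.append(Rejection(eid, f"non-numeric h2 {row['h2']!r}"))
            continue
        se = _resolve_se(row, h2)
        if se is None:
            rejections.append(Rejection(eid, "no SE or CI"))
            continue
        if isinstance(se, str):  # carries a reason
            rejections.append(Rejection(eid, se))
            continue
        n = _optional_int(row.get("n", ""))
        try:
            rec = EffectSizeRecord(
                estimate_id=eid,
                study_id=row["study_id"],
                species=row["species"],
                h2=h2,
                se=se,
                n=n,
                publication_year=int(float(row["publication_year"])),
                environmental_setting=row["environmental_setting"],
                age_at_measurement=row["age_at_measurement"],
                laboratory_method=row["laboratory_method"],
                statistical_method=row["statistical_method"],
                parental_sex=row["parental_sex"],
                repeated_measurement=row["repeated_measurement"],
            )
        except ValueError as exc:
            rejections.append(Rejection(eid, str(exc)))
            continue
        prior_study = study_of.setdefault(eid, rec.study_id)
        if prior_study != rec.study_id:  # unreachable given dupe check; defensive
            raise SchemaError(f"estimate {eid} maps to two studies")
        records.append(rec)
    return ParseResult(records, rejections)


def _resolve_se(row: pd.Series, h2: float) -> float | str | None:
    raw_se = str(row.get("se", "")).strip()
    if raw_se:
        try:
            return float(raw_se)
        except ValueError:
            return f"non-numeric se {raw_se!r}"
    raw_ci = str(row.get("ci_upper", "")).strip()
    if raw_ci:
        try:
            upper = float(raw_ci)
        except ValueError:
            return f"non-numeric ci_upper {raw_ci!r}"
        try:
            se = se_from_ci(h2, upper)
        except ValueError as exc:
            return str(exc)
        if se == 0:
            return "zero-width confidence interval"
        return se
    return None


def _optional_int(value: object) -> int | None:
    text = str(value).strip()
    if not text:
        return None
    return int(float(text))


def records_to_frame(records: Iterable[EffectSizeRecord]) -> pd.DataFrame:
    """Tabular view of records, one row per estimate."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        d["sampling_variance"] = r.sampling_variance
        rows.append(d)
    return pd.DataFrame(rows)


def write_records(records: Iterable[EffectSizeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_rejections(rejections: Iterable[Rejection], path: str | Path) -> None:
    pd.DataFrame(
        [(r.estimate_id, r.reason) for r in rejections],
        columns=["estimate_id", "reason"],
    ).to_csv(path, sep="\t", index=False)
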