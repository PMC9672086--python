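"""Questionnaire scoring, severity bands, eligibility and cohort descriptives.

Implements the study instruments around guided internet-based CBT for
binge-eating disorder (BED):

* BED-Q — a 9-item BED severity screen; items 1-7 (frequency codes 0-5)
  form a 0-35 sum score with six severity bands; item 8 (compensatory
  behaviour) and item 9 (distress, yes/no) never enter the sum.
* MDI — the Major Depression Inventory, 10 items scored 0-5, total 0-50
  with cut-offs 21/26/31 for mild/moderate/severe depression.
* Programme completion — Low (<6 sessions), High (6-9, or 10 without
  follow-up), Full (all 10 sessions plus the follow-up questionnaire).
* Eligibility — severe BED (BED-Q >= 22) or MDI > 40 excludes.

Also provides the cohort CSV reader/writer and the descriptive tables
(completion frequencies by age group, cohort demographics).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class ValidationError(ValueError):
    """An instrument response or patient record violates its constraints."""


class SeverityBand(enum.IntEnum):
    """Ordered BED-Q severity bands (0-35 sum score)."""

    NONE = 0          # score 0
    SUBCLINICAL = 1   # 1-9
    MILD = 2          # 10-14
    MODERATE = 3      # 15-21
    SEVERE = 4        # 22-28
    EXTREMELY_SEVERE = 5  # 29-35


class MdiBand(enum.IntEnum):
    """Ordered depression bands of the MDI total score."""

    NONE = 0      # < 21
    MILD = 1      # 21-25
    MODERATE = 2  # 26-30
    SEVERE = 3    # >= 31


class CompletionCategory(enum.IntEnum):
    """Ordered programme completion categories."""

    LOW = 0
    HIGH = 1
    FULL = 2


#: SDT extrinsic-motivation regulation types, controlled -> autonomous
MOTIVATION_LEVELS = ("external", "introjection", "identification", "integration")
MOTIVATION_INDEX = {name: i for i, name in enumerate(MOTIVATION_LEVELS)}

#: default age cut separating young adults from adults (years)
YOUNG_ADULT_CUT = 25

BEDQ_SEVERE_CUT = 22  # lower edge of the severe band; exclusion threshold
MDI_EXCLUSION_CUT = 40  # MDI strictly above this excludes


@dataclass(frozen=True)
class BedqResponse:
    """One BED-Q questionnaire response."""

    items_1_7: tuple[int, ...]
    item_8: int = 0
    item_9_distress: bool = False

    def __post_init__(self) -> None:
        if len(self.items_1_7) != 7:
            raise ValidationError(f"BED-Q needs exactly 7 symptom items, got {len(self.items_1_7)}")
        for i, item in enumerate(self.items_1_7, start=1):
            if not 0 <= item <= 5:
                raise ValidationError(f"BED-Q item {i} out of range 0..5: {item}")
        if not 0 <= self.item_8 <= 5:
            raise ValidationError(f"BED-Q item 8 out of range 0..5: {self.item_8}")


@dataclass(frozen=True)
class MdiResponse:
    """One MDI questionnaire response (ten 0-5 Likert items)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValidationError(f"MDI needs exactly 10 items, got {len(self.items)}")
        for i, item in enumerate(self.items, start=1):
            if not 0 <= item <= 5:
                raise ValidationError(f"MDI item {i} out of range 0..5: {item}")


def score_bedq(resp: BedqResponse) -> int:
    """BED-Q sum score over items 1-7 (0-35); items 8 and 9 never enter."""
    return int(sum(resp.items_1_7))


def classify_bedq_severity(score: int) -> SeverityBand:
    """Map a BED-Q sum score onto the six severity bands."""
    if not 0 <= score <= 35:
        raise ValidationError(f"BED-Q score out of range 0..35: {score}")
    if score == 0:
        return SeverityBand.NONE
    if score <= 9:
        return SeverityBand.SUBCLINICAL
    if score <= 14:
        return SeverityBand.MILD
    if score <= 21:
        return SeverityBand.MODERATE
    if score <= 28:
        return SeverityBand.SEVERE
    return SeverityBand.EXTREMELY_SEVERE


def score_mdi(resp: MdiResponse) -> tuple[int, MdiBand]:
    """MDI total (0-50) and depression band (cut-offs 21/26/31)."""
    total = int(sum(resp.items))
    return total, classify_mdi_band(total)


def classify_mdi_band(total: int) -> MdiBand:
    if not 0 <= total <= 50:
        raise ValidationError(f"MDI total out of range 0..50: {total}")
    if total < 21:
        return MdiBand.NONE
    if total <= 25:
        return MdiBand.MILD
    if total <= 30:
        return MdiBand.MODERATE
    return MdiBand.SEVERE


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reasons: tuple[str, ...] = ()


def check_eligibility(bedq_score: int, mdi_score: int) -> Eligibility:
    """Screening rule: severe/extremely severe BED or MDI > 40 excludes."""
    reasons = []
    if classify_bedq_severity(bedq_score) >= SeverityBand.SEVERE:
        reasons.append(f"severe BED (BED-Q {bedq_score} >= {BEDQ_SEVERE_CUT})")
    if not 0 <= mdi_score <= 50:
        raise ValidationError(f"MDI score out of range 0..50: {mdi_score}")
    if mdi_score > MDI_EXCLUSION_CUT:
        reasons.append(f"MDI > {MDI_EXCLUSION_CUT} (MDI {mdi_score})")
    return Eligibility(eligible=not reasons, reasons=tuple(reasons))


def completion_category(
    sessions: int, followup: bool, *, full_requires_followup: bool = True
) -> CompletionCategory:
    """Programme completion: Low < 6 sessions, Full = 10 plus follow-up, else High.

    Ten sessions without the follow-up questionnaire fall back to High
    (Full is defined by the conjunction); set ``full_requires_followup``
    False to treat 10 sessions alone as Full.
    """
    if not 0 <= sessions <= 10:
        raise ValidationError(f"sessions out of range 0..10: {sessions}")
    if sessions < 6:
        return CompletionCategory.LOW
    if sessions == 10 and (followup or not full_requires_followup):
        return CompletionCategory.FULL
    return CompletionCategory.HIGH


@dataclass
class PatientRecord:
    """One cohort participant.

    Post-treatment scores may be missing (``None``) for non-completers;
    analyses drop incomplete pairs pairwise and report the count.
    """

    id: str
    age: float
    sex: str
    bmi: float
    age_group: str
    motivation_aims: str
    motivation_online: str
    therapy_aims_text: str
    why_online_text: str
    sessions_completed: int
    followup_done: bool
    bedq_pre: int | None = None
    bedq_post: int | None = None
    edeq_pre: float | None = None
    edeq_post: float | None = None
    mdi_pre: int | None = None
    mdi_post: int | None = None
    vas_pre: int | None = None
    vas_post: int | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError(f"patient {self.id}: age must be >= 18, got {self.age}")
        if self.bmi <= 0:
            raise ValidationError(f"patient {self.id}: BMI must be positive")
        if self.age_group not in ("adult", "young_adult"):
            raise ValidationError(f"patient {self.id}: unknown age_group {self.age_group!r}")
        for attr in ("motivation_aims", "motivation_online"):
            if getattr(self, attr) not in MOTIVATION_INDEX:
                raise ValidationError(
                    f"patient {self.id}: {attr} must be one of {MOTIVATION_LEVELS}"
                )
        if not 0 <= self.sessions_completed <= 10:
            raise ValidationError(f"patient {self.id}: sessions_completed out of range 0..10")
        for attr, lo, hi in (
            ("bedq_pre", 0, 35), ("bedq_post", 0, 35),
            ("mdi_pre", 0, 50), ("mdi_post", 0, 50),
            ("vas_pre", 0, 100), ("vas_post", 0, 100),
        ):
            val = getattr(self, attr)
            if val is not None and not lo <= val <= hi:
                raise ValidationError(f"patient {self.id}: {attr}={val} out of range {lo}..{hi}")
        for attr in ("edeq_pre", "edeq_post"):
            val = getattr(self, attr)
            if val is not None and val < 0:
                raise ValidationError(f"patient {self.id}: {attr} must be >= 0")

    @property
    def completion(self) -> CompletionCategory:
        return completion_category(self.sessions_completed, self.followup_done)


def age_group_for(age: float, cut: int = YOUNG_ADULT_CUT) -> str:
    """Age stratum: young_adult below ``cut`` years, adult otherwise."""
    return "young_adult" if age < cut else "adult"


COHORT_COLUMNS = [
    "id", "age", "sex", "bmi", "age_group", "motivation_aims", "motivation_online",
    "therapy_aims_text", "why_online_text", "sessions_completed", "followup_done",
    "bedq_pre", "bedq_post", "edeq_pre", "edeq_post",
    "mdi_pre", "mdi_post", "vas_pre", "vas_post",
]

_INT_OPTIONAL = ("bedq_pre", "bedq_post", "mdi_pre", "mdi_post", "vas_pre", "vas_post")
_FLOAT_OPTIONAL = ("edeq_pre", "edeq_post")


def read_cohort(path: str | Path | io.IOBase) -> list[PatientRecord]:
    """Parse a cohort CSV (RFC 4180, UTF-8, empty cell = missing) into records.

    The header must match :data:`COHORT_COLUMNS` exactly.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if list(df.columns) != COHORT_COLUMNS:
        raise ValidationError(
            f"cohort header mismatch: expected {COHORT_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(COHORT_COLUMNS, row))
        kwargs: dict = {
            "id": d["id"],
            "age": float(d["age"]),
            "sex": d["sex"],
            "bmi": float(d["bmi"]),
            "age_group": d["age_group"],
            "motivation_aims": d["motivation_aims"],
            "motivation_online": d["motivation_online"],
            "therapy_aims_text": d["therapy_aims_text"],
            "why_online_text": d["why_online_text"],
            "sessions_completed": int(d["sessions_completed"]),
            "followup_done": _parse_bool(d["followup_done"]),
        }
        for col in _INT_OPTIONAL:
            kwargs[col] = int(float(d[col])) if d[col] != "" else None
        for col in _FLOAT_OPTIONAL:
            kwargs[col] = float(d[col]) if d[col] != "" else None
        records.append(PatientRecord(**kwargs))
    return records


def _parse_bool(cell: str) -> bool:
    if cell.strip().lower() in ("1", "true", "yes"):
        return True
    if cell.strip().lower() in ("0", "false", "no"):
        return False
    raise ValidationError(f"cannot parse boolean cell {cell!r}")


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical column order."""
    rows = []
    for rec in records:
        rows.append({f.name: getattr(rec, f.name) for f in fields(rec)})
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to the cohort CSV dialect (empty cell = missing)."""
    df = cohort_to_frame(records).copy()
    df["followup_done"] = df["followup_done"].map({True: "1", False: "0"})
    df.to_csv(path, index=False, encoding="utf-8")


def completion_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Completion-rate frequencies and within-age-group percentages.

    Rows are ordered Full, High, Low within each age group; the percent
    column is 100 * frequency / age-group total, rounded to 2 decimals.
    """
    if not records:
        raise ValidationError("completion_table needs a nonempty cohort")
    counts: dict[tuple[str, CompletionCategory], int] = {}
    group_totals: dict[str, int] = {}
    for rec in records:
        key = (rec.age_group, rec.completion)
        counts[key] = counts.get(key, 0) + 1
        group_totals[rec.age_group] = group_totals.get(rec.age_group, 0) + 1
    rows = []
    for group in sorted(group_totals):
        for cat in (CompletionCategory.FULL, CompletionCategory.HIGH, CompletionCategory.LOW):
            freq = counts.get((group, cat), 0)
            rows.append({
                "age_group": group,
                "completion": cat.name.capitalize(),
                "frequency": freq,
                "pct_of_age_group": round(100.0 * freq / group_totals[group], 2),
            })
    return pd.DataFrame(rows, columns=["age_group", "completion", "frequency", "pct_of_age_group"])


def completion_percentages(frequencies: Sequence[int]) -> list[float]:
    """Within-group percentages (2 decimals) from raw category frequencies."""
    total = sum(frequencies)
    if total == 0:
        raise ValidationError("cannot compute percentages of an all-zero frequency vector")
    return [round(100.0 * f / total, 2) for f in frequencies]


def descriptives(records: Sequence[PatientRecord]) -> dict:
    """Cohort demographics block: n, % male, age/BMI/MDI summaries, n young adults."""
    if not records:
        raise ValidationError("descriptives needs a nonempty cohort")
    n = len(records)
    n_male = sum(1 for r in records if r.sex.lower() in ("m", "male"))
    ages = [r.age for r in records]
    bmis = [r.bmi for r in records]
    mdis = [r.mdi_pre for r in records if r.mdi_pre is not None]
    return {
        "n": n,
        "n_male": n_male,
        "pct_male": round(100.0 * n_male / n, 1),
        "age_mean": sum(ages) / n,
        "age_range": (min(ages), max(ages)),
        "bmi_mean": sum(bmis) / n,
        "bmi_range": (min(bmis), max(bmis)),
        "mdi_mean": sum(mdis) / len(mdis) if mdis else None,
        "mdi_range": (min(mdis), max(mdis)) if mdis else None,
        "n_young_adults": sum(1 for r in records if r.age_group == "young_adult"),
    }
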