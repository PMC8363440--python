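"""Clinical efficacy grading for angina and ECG treatment outcomes.

Each patient is assigned exactly one of four grades.  For angina, grading
is by the fractional decrease ``d = (pre - post) / pre`` of the total
angina symptom score (an opaque summed score; the instrument is an input):
obviously effective for ``d >= 0.60``, effective for ``0.30 <= d < 0.60``,
ineffective for ``0 < d < 0.30`` and aggravated when the score did not
decrease (``d <= 0``).  Boundaries are inclusive ("at least 30%/60%").

For the ECG, a record that returned to the normal range is obviously
effective; otherwise a post-treatment ST-segment rise above 0.05 mV or a
T wave recovering from flat to upright is effective; an ST fall of more
than 0.05 mV, a fully reversed T wave (upright <-> inverted) or new ectopic
rhythm is aggravated; anything else (no significant change) is ineffective.
Aggravation is checked before "ineffective" so a frank deterioration is
never labelled "no significant change".

The total effective rate is the percentage of patients graded obviously
effective or effective, rounded to one decimal, half away from zero.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "EfficacyGrade",
    "TWave",
    "AnginaRecord",
    "EcgRecord",
    "UngradableError",
    "grade_angina",
    "grade_ecg",
    "tally",
    "effective_rate",
    "chi2_2x2",
    "read_angina_csv",
    "read_ecg_csv",
    "write_tally_csv",
]


class EfficacyGrade(enum.Enum):
    OBVIOUSLY_EFFECTIVE = "obviously_effective"
    EFFECTIVE = "effective"
    INEFFECTIVE = "ineffective"
    AGGRAVATED = "aggravated"


class TWave(enum.Enum):
    FLAT = "flat"
    UPRIGHT = "upright"
    INVERTED = "inverted"


class UngradableError(ValueError):
    pass


@dataclass(frozen=True)
class AnginaRecord:
    patient_id: str
    pre_score: float
    post_score: float


@dataclass(frozen=True)
class EcgRecord:
    """Post-vs-pre ECG changes for one patient.

    ``st_change_mv`` is the signed post-minus-pre ST level in mV (positive
    means recovery toward baseline).
    """

    patient_id: str
    st_change_mv: float
    returned_to_normal: bool
    t_wave_pre: TWave
    t_wave_post: TWave
    ectopic_rhythm: bool

    def __post_init__(self) -> None:
        for f in ("t_wave_pre", "t_wave_post"):
            v = getattr(self, f)
            if not isinstance(v, TWave):
                object.__setattr__(self, f, TWave(v))


def grade_angina(r: AnginaRecord) -> EfficacyGrade:
    """Grade by fractional decrease of the total angina score."""
    if not r.pre_score > 0:
        raise UngradableError(
            f"patient {r.patient_id!r}: pre_score must be positive to grade"
        )
    d = (r.pre_score - r.post_score) / r.pre_score
    if d >= 0.60:
        return EfficacyGrade.OBVIOUSLY_EFFECTIVE
    if d >= 0.30:
        return EfficacyGrade.EFFECTIVE
    if d > 0:
        return EfficacyGrade.INEFFECTIVE
    return EfficacyGrade.AGGRAVATED


def grade_ecg(r: EcgRecord) -> EfficacyGrade:
    """Grade the ECG outcome; precedence obviously > effective > aggravated > ineffective."""
    if r.returned_to_normal:
        return EfficacyGrade.OBVIOUSLY_EFFECTIVE
    if r.st_change_mv > 0.05 or (
        r.t_wave_pre is TWave.FLAT and r.t_wave_post is TWave.UPRIGHT
    ):
        return EfficacyGrade.EFFECTIVE
    reversed_t = {r.t_wave_pre, r.t_wave_post} == {TWave.UPRIGHT, TWave.INVERTED}
    if r.st_change_mv < -0.05 or reversed_t or r.ectopic_rhythm:
        return EfficacyGrade.AGGRAVATED
    return EfficacyGrade.INEFFECTIVE


def tally(grades: Iterable[EfficacyGrade]) -> dict[EfficacyGrade, int]:
    counts = Counter(grades)
    return {g: counts.get(g, 0) for g in EfficacyGrade}


def effective_rate(counts: Mapping[EfficacyGrade, int], n_total: int | None = None) -> float:
    """Total effective rate (%) = 100 * (obviously + effective) / n_total.

    Rounded to one decimal, half away from zero — the convention that
    matches clinical reporting of these rates.
    """
    total = sum(counts.values())
    if n_total is None:
        n_total = total
    elif n_total != total:
        raise ValueError(f"counts sum to {total}, but n_total={n_total}")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    eff = counts.get(EfficacyGrade.OBVIOUSLY_EFFECTIVE, 0) + counts.get(
        EfficacyGrade.EFFECTIVE, 0
    )
    pct = Decimal(100 * eff) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table
    [[a, b], [c, d]]; returns (statistic, p value).  Generic helper."""
    from scipy.stats import chi2_contingency

    stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    return float(stat), float(p)


def read_angina_csv(path: str | Path) -> list[AnginaRecord]:
    """Read angina records from CSV with columns patient_id, pre_score, post_score."""
    df = pd.read_csv(path, comment="#")
    _require(df, path, ["patient_id", "pre_score", "post_score"])
    return [
        AnginaRecord(str(r.patient_id), float(r.pre_score), float(r.post_score))
        for r in df.itertuples(index=False)
    ]


def read_ecg_csv(path: str | Path) -> list[EcgRecord]:
    """Read ECG records from CSV with columns patient_id, st_change_mv,
    returned_to_normal, t_wave_pre, t_wave_post, ectopic_rhythm."""
    df = pd.read_csv(path, comment="#")
    _require(
        df, path,
        ["patient_id", "st_change_mv", "returned_to_normal",
         "t_wave_pre", "t_wave_post", "ectopic_rhythm"],
    )
    return [
        EcgRecord(
            str(r.patient_id),
            float(r.st_change_mv),
            _as_bool(r.returned_to_normal),
            TWave(str(r.t_wave_pre).strip().lower()),
            TWave(str(r.t_wave_post).strip().lower()),
            _as_bool(r.ectopic_rhythm),
        )
        for r in df.itertuples(index=False)
    ]


def write_tally_csv(
    tallies: Mapping[str, Mapping[EfficacyGrade, int]],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write grade tallies and effective rates, one column per instrument."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        names = list(tallies)
        fh.write("grade," + ",".join(names) + "\n")
        for g in EfficacyGrade:
            fh.write(g.value + "," + ",".join(str(tallies[n][g]) for n in names) + "\n")
        fh.write(
            "effective_rate_pct,"
            + ",".join(f"{effective_rate(tallies[n]):.1f}" for n in names)
            + "\n"
        )


def _require(df: pd.DataFrame, path, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {v!r}")
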