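"""Per-runner pacing features from raw checkpoint passage times.

From a split table (one row per runner: elapsed times at checkpoints
cp1..cp5 plus finish time, all in hours) this module derives the
features the downstream models consume:

* ``T_n``   — section time, the difference of consecutive passage times;
* ``WT_n``  — weighted time, ``T_n / IRDC_n``: the section effort
  extrapolated to whole-race scale using the section's share of total
  race difficulty (a runner holding the same relative intensity over
  the whole race would finish in about ``WT_n`` hours);
* ``WTV_{n,n+2}`` — weighted-time variability, ``WT_{n+2}/WT_n - 1``
  between two successive sections of the *same* slope sign (uphill with
  uphill, downhill with downhill, skipping the opposite-slope section
  in between); positive values mean slowing on comparable terrain;
* ``CPR_n`` — checkpoint percentile rank: the runner's ascending-time
  rank fraction in the field pooled across race modalities at that
  checkpoint (both modalities share the first five sections), so the
  fastest runner has the smallest CPR;
* a performance quartile label, Q1 (fastest quarter by CPR) vs Q2-4.

All time arithmetic is in decimal hours; the CSV reader accepts both
"HH:MM:SS" strings and decimal-hour numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .course import CourseProfile, Rounding, irdc

__all__ = [
    "SplitRecord",
    "parse_time_value",
    "read_split_table",
    "section_times",
    "weighted_time",
    "weighted_time_variability",
    "checkpoint_percentile_rank",
    "assign_quartiles",
    "build_feature_table",
    "WTV_PAIRS",
    "CPR_CHECKPOINTS",
]

logger = logging.getLogger(__name__)

# Same-slope section pairs for the three terrain segments: ascent #1
# pairs the first and second uphills (s1, s3), descent the two downhills
# (s2, s4), ascent #2 the second and third uphills (s3, s5).  The
# intervening opposite-slope section is skipped by construction.
WTV_PAIRS: tuple[tuple[int, int], ...] = ((1, 3), (2, 4), (3, 5))

# Checkpoints at which percentile ranks feed the models (end of the
# opening section of each terrain segment).
CPR_CHECKPOINTS: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True)
class SplitRecord:
    """One runner's raw timing row.

    ``cp_times`` are elapsed hours from the start at checkpoints
    cp1..cpk; missing passages are NaN.  Present times must be strictly
    increasing and the finish time must not precede the last passage.
    """

    runner_id: str
    modality: str
    sex: str
    cp_times: tuple[float, ...]
    finish_time: float

    def __post_init__(self) -> None:
        present = [(i, t) for i, t in enumerate(self.cp_times) if not _is_missing(t)]
        for (_, a), (_, b) in zip(present, present[1:]):
            if b <= a:
                raise ValueError(
                    f"runner {self.runner_id}: checkpoint times not strictly "
                    f"increasing ({a} then {b})"
                )
        if present and not _is_missing(self.finish_time):
            if self.finish_time < present[-1][1]:
                raise ValueError(
                    f"runner {self.runner_id}: finish time {self.finish_time} "
                    f"precedes last checkpoint passage {present[-1][1]}"
                )


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def parse_time_value(value) -> float:
    """Parse one time cell to decimal hours.

    Accepts "HH:MM:SS" (hours may exceed 24), plain numbers (already
    decimal hours) and empty/NaN cells (missing).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if not s or s.lower() in {"na", "nan", "dnf"}:
        return math.nan
    if ":" in s:
        parts = s.split(":")
        if len(parts) != 3:
            raise ValueError(f"cannot parse time {value!r}: expected HH:MM:SS")
        h, m, sec = (float(p) for p in parts)
        return h + m / 60.0 + sec / 3600.0
    return float(s)


def read_split_table(path: str | Path, n_checkpoints: int = 5) -> pd.DataFrame:
    """Read a split CSV into decimal-hour form.

    Expected columns: ``runner_id, modality, sex, cp1..cp{k}, finish``.
    """
    df = pd.read_csv(path, dtype={"runner_id": str})
    cp_cols = [f"cp{i}" for i in range(1, n_checkpoints + 1)]
    missing_cols = [c for c in ("runner_id", "modality", "finish", *cp_cols) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"split table missing columns: {missing_cols}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    for c in (*cp_cols, "finish"):
        df[c] = df[c].map(parse_time_value)
    return df


def section_times(record: SplitRecord) -> tuple[float, ...]:
    """Section times T_n as successive differences of passage times.

    T_1 is the first passage time itself (the start is cp0 = 0).  A
    missing checkpoint makes both adjacent sections undefined.
    """
    times = record.cp_times
    out: list[float] = []
    prev = 0.0
    for t in times:
        if _is_missing(t) or _is_missing(prev):
            out.append(math.nan)
        else:
            out.append(t - prev)
        prev = t
    return tuple(out)


def weighted_time(t_n: float, irdc_n: float) -> float:
    """Weighted time WT_n = T_n / IRDC_n (hours)."""
    if _is_missing(t_n):
        return math.nan
    if t_n <= 0:
        raise ValueError(f"section time must be positive, got {t_n}")
    if not 0 < irdc_n <= 1:
        raise ValueError(f"IRDC must be in (0, 1], got {irdc_n}")
    return t_n / irdc_n


def weighted_time_variability(wt_n: float, wt_n_plus_2: float) -> float:
    """Relative weighted-time change WT_{n+2}/WT_n - 1 between two
    same-slope sections; positive = slowing as the race progresses."""
    if _is_missing(wt_n) or _is_missing(wt_n_plus_2):
        return math.nan
    if wt_n <= 0 or wt_n_plus_2 <= 0:
        raise ValueError("weighted times must be positive")
    return wt_n_plus_2 / wt_n - 1.0


def checkpoint_percentile_rank(passage_times: Sequence[float] | pd.Series) -> np.ndarray:
    """Percentile rank fraction at one checkpoint over the pooled field.

    Returns rank(ascending time) / n_ranked for every entry, NaN where
    the passage time is missing; the fastest runner gets 1/n, the
    slowest 1.0.  Tied times share the mean of their ranks.
    """
    times = np.asarray(passage_times, dtype=float)
    out = np.full(times.shape, np.nan)
    mask = ~np.isnan(times)
    n = int(mask.sum())
    if n == 0:
        return out
    out[mask] = rankdata(times[mask], method="average") / n
    return out


def assign_quartiles(cpr_values: Sequence[float] | pd.Series) -> np.ndarray:
    """Label the fastest quarter of the field Q1, the rest Q2_4.

    The boundary is inclusive at rank ceil(0.25 * n): with 947 ranked
    runners Q1 holds 237 (rank 237 has CPR 237/947 = 0.2503, still Q1).
    Missing CPR yields a missing label.
    """
    cpr = np.asarray(cpr_values, dtype=float)
    mask = ~np.isnan(cpr)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("assign_quartiles: no ranked values")
    threshold = math.ceil(0.25 * n) / n
    out = np.full(cpr.shape, None, dtype=object)
    out[mask] = np.where(cpr[mask] <= threshold + 1e-12, "Q1", "Q2_4")
    return out


def _irdc_vector(course: CourseProfile, rounding: Rounding) -> np.ndarray:
    return np.array(
        [irdc(sec, course, rounding=rounding) for sec in course.sections]
    )


def build_feature_table(
    splits: pd.DataFrame,
    courses: Mapping[str, CourseProfile],
    *,
    rounding: Rounding = "full",
    validate: bool = True,
) -> pd.DataFrame:
    """Join section times, WT, WTV, pooled CPR, quartile and TT.

    ``splits`` has one row per runner (``runner_id, modality, sex,
    cp1..cpk, finish``, decimal hours); ``courses`` maps each modality
    present to its course profile.  Features whose constituents are
    missing stay missing for that feature only; rows are never dropped
    wholesale.  The quartile label is taken from CPR at cp1, the field's
    earliest common performance marker.
    """
    modalities = splits["modality"].unique()
    unknown = [m for m in modalities if m not in courses]
    if unknown:
        raise ValueError(f"no course profile for modalities: {unknown}")

    n_cp = min(courses[m].n_checkpoints for m in modalities)
    cp_cols = [f"cp{i}" for i in range(1, n_cp + 1)]

    if validate:
        for _, row in splits.iterrows():
            SplitRecord(
                runner_id=str(row["runner_id"]),
                modality=str(row["modality"]),
                sex=str(row.get("sex", "unknown")),
                cp_times=tuple(float(row[c]) for c in cp_cols),
                finish_time=float(row["finish"]),
            )

    out = splits[["runner_id", "modality"]].copy()
    out["sex"] = splits["sex"] if "sex" in splits.columns else "unknown"

    # section times: successive differences with cp0 = 0
    cp = splits[cp_cols].to_numpy(dtype=float)
    t = np.diff(np.hstack([np.zeros((len(splits), 1)), cp]), axis=1)
    for i in range(n_cp):
        out[f"T_{i + 1}"] = t[:, i]

    # weighted times with per-modality IRDC
    wt = np.full_like(t, np.nan)
    for m in modalities:
        sel = (splits["modality"] == m).to_numpy()
        wt[sel] = t[sel] / _irdc_vector(courses[m], rounding)[:n_cp]
    for i in range(n_cp):
        out[f"WT_{i + 1}"] = wt[:, i]

    for a, b in WTV_PAIRS:
        if b <= n_cp:
            out[f"WTV_{a}{b}"] = wt[:, b - 1] / wt[:, a - 1] - 1.0

    # pooled percentile ranks across modalities at each checkpoint
    for k in CPR_CHECKPOINTS:
        if k <= n_cp:
            out[f"CPR_{k}"] = checkpoint_percentile_rank(cp[:, k - 1])

    out["quartile"] = assign_quartiles(out["CPR_1"])
    out["TT"] = splits["finish"].to_numpy(dtype=float)

    n_partial = int(out.drop(columns=["runner_id", "modality", "sex", "quartile"]).isna().any(axis=1).sum())
    if n_partial:
        logger.info("feature table: %d of %d rows have at least one missing feature",
                    n_partial, len(out))
    return out
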