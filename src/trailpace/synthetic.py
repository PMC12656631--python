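"""Synthetic race fields with the statistical structure the models assume.

The generator's core premise mirrors the weighted-time model itself:
each runner carries a latent ability ``A`` expressed on the
weighted-time scale (hours to finish the whole race at section-1
relative intensity), and section times are difficulty-proportional,

    T_n = IRDC_n * A * f_n * (1 + eps_n),

where ``f_n`` is a cumulative same-slope fatigue drift (uphill pace
decays across successive uphill sections, downhill across downhills)
and ``eps_n`` is multiplicative section noise.  The finish time adds a
lump for the course beyond the last shared checkpoint, proportional to
ability.  In the noiseless, driftless limit every weighted time equals
``A`` exactly and all pacing-variability values are zero.

Default parameters emulate the two-modality cohort the models were
developed on: field sizes 764 (marathon "4K") and 183 (ultra "8K"),
ability lognormal around 7.3 h / 16.85 h, drift producing ~30% uphill
slowing between the first two uphill sections and none between the
later two, and noise sized so the first-ascent slowing shows a paired
effect size near -2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .course import CourseProfile, Rounding, builtin_courses, irdc
from .features import build_feature_table
from .regression import segment_columns

__all__ = ["ModalityConfig", "SyntheticConfig", "simulate_field", "simulate_linear_tt"]


@dataclass(frozen=True)
class ModalityConfig:
    """Per-modality generative parameters.

    ``ability_mean``/``ability_cv`` parameterize the lognormal latent
    weighted-time ability (hours); ``remainder_factor`` scales the
    unmodelled course beyond the last shared checkpoint as a fraction
    of ability.
    """

    field_size: int
    ability_mean: float
    ability_cv: float
    remainder_factor: float

    def __post_init__(self) -> None:
        if self.field_size < 4:
            raise ValueError("field_size must be >= 4")
        if self.ability_mean <= 0 or self.ability_cv < 0:
            raise ValueError("ability_mean must be > 0 and ability_cv >= 0")
        if self.remainder_factor < 0:
            raise ValueError("remainder_factor must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative configuration; the seed is mandatory.

    ``ascent_drift``/``descent_drift`` give the multiplicative pace
    factor at each successive section of that slope sign (first entry
    is the reference 1.0).
    """

    seed: int
    modalities: Mapping[str, ModalityConfig] = field(
        default_factory=lambda: {
            "4K": ModalityConfig(field_size=764, ability_mean=7.3,
                                 ability_cv=0.14, remainder_factor=0.374),
            "8K": ModalityConfig(field_size=183, ability_mean=16.85,
                                 ability_cv=0.16, remainder_factor=0.576),
        }
    )
    male_fraction: float = 871 / 947
    ascent_drift: tuple[float, ...] = (1.0, 1.3, 1.3)
    descent_drift: tuple[float, ...] = (1.0, 1.15)
    noise_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SyntheticConfig requires an explicit seed")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(f <= 0 for f in self.ascent_drift + self.descent_drift):
            raise ValueError("drift factors must be positive")


def _drift_factors(course: CourseProfile, config: SyntheticConfig) -> np.ndarray:
    """Per-section fatigue factor, indexed by that section's occurrence
    order within its own slope sign."""
    factors = []
    counts = {"positive": 0, "negative": 0}
    for sec in course.sections:
        i = counts[sec.net_slope]
        counts[sec.net_slope] += 1
        table = config.ascent_drift if sec.net_slope == "positive" else config.descent_drift
        factors.append(table[i] if i < len(table) else table[-1])
    return np.array(factors)


def _truncated_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Multiplicative noise 1 + eps with eps ~ N(0, sd), clipped so
    section times stay positive."""
    if sd == 0:
        return np.ones(shape)
    return np.clip(1.0 + rng.normal(0.0, sd, size=shape), 0.05, None)


def simulate_field(
    config: SyntheticConfig,
    courses: Mapping[str, CourseProfile] | None = None,
    *,
    rounding: Rounding = "full",
) -> pd.DataFrame:
    """Simulate a complete split table for every configured modality.

    Returns a DataFrame in split-table layout (``runner_id, modality,
    sex, cp1..cpk, finish``; decimal hours), deterministic in the
    config seed.
    """
    courses = courses if courses is not None else builtin_courses()
    missing = [m for m in config.modalities if m not in courses]
    if missing:
        raise ValueError(f"no course for modalities: {missing}")

    root = np.random.SeedSequence(config.seed)
    frames = []
    for (modality, mc), ss in zip(sorted(config.modalities.items()),
                                  root.spawn(len(config.modalities))):
        rng = np.random.default_rng(ss)
        course = courses[modality]
        k = course.n_checkpoints
        irdcs = np.array([irdc(sec, course, rounding=rounding) for sec in course.sections])
        drift = _drift_factors(course, config)

        sigma = np.sqrt(np.log1p(mc.ability_cv ** 2))
        mu = np.log(mc.ability_mean) - sigma ** 2 / 2
        ability = rng.lognormal(mu, sigma, size=mc.field_size)

        noise = _truncated_noise(rng, config.noise_sd, (mc.field_size, k))
        t = ability[:, None] * irdcs[None, :] * drift[None, :] * noise
        cp = np.cumsum(t, axis=1)
        remainder = (mc.remainder_factor * ability
                     * _truncated_noise(rng, config.noise_sd, mc.field_size))
        finish = cp[:, -1] + remainder

        sex = np.where(rng.random(mc.field_size) < config.male_fraction,
                       "male", "female")
        frame = pd.DataFrame({
            "runner_id": [f"{modality}-{i + 1:04d}" for i in range(mc.field_size)],
            "modality": modality,
            "sex": sex,
        })
        for j in range(k):
            frame[f"cp{j + 1}"] = cp[:, j]
        frame["finish"] = finish
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_linear_tt(
    config: SyntheticConfig,
    coefficients: Mapping[str, float],
    courses: Mapping[str, CourseProfile] | None = None,
    *,
    segment: str = "ascent1",
    tt_noise_sd: float = 0.3,
    rounding: Rounding = "full",
) -> pd.DataFrame:
    """Simulate a field whose finish time follows a known linear model.

    Splits are generated as in :func:`simulate_field`; the finish time
    is then overwritten with

        TT = constant + b_wt*WT + b_wtv*WTV + b_cpr*CPR + N(0, tt_noise_sd)

    on the given segment's predictor triple, providing ground truth for
    parameter-recovery checks of the regression stage.  ``coefficients``
    uses the canonical {constant, WT, WTV, CPR} keys.
    """
    courses = courses if courses is not None else builtin_courses()
    missing = {"constant", "WT", "WTV", "CPR"} - set(coefficients)
    if missing:
        raise ValueError(f"coefficients missing {sorted(missing)}")
    splits = simulate_field(config, courses, rounding=rounding)
    feats = build_feature_table(splits, courses, rounding=rounding, validate=False)
    wt_col, wtv_col, cpr_col = segment_columns(segment)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
        len(config.modalities) + 1)[-1])
    tt = (coefficients["constant"]
          + coefficients["WT"] * feats[wt_col].to_numpy()
          + coefficients["WTV"] * feats[wtv_col].to_numpy()
          + coefficients["CPR"] * feats[cpr_col].to_numpy()
          + rng.normal(0.0, tt_noise_sd, size=len(feats)))
    out = splits.copy()
    # keep the finish consistent with checkpoint passages
    last_cp = out[[c for c in out.columns if c.startswith("cp")]].max(axis=1)
    out["finish"] = np.maximum(tt, last_cp.to_numpy() + 1e-6)
    return out
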