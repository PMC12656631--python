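"""Real-time finish-time prediction from mid-race splits.

A fitted (or published) ascent-segment model of total time on
(WT_n, WTV_{n,n+2}, CPR_n) can be evaluated for a runner the moment
they pass the closing checkpoint of the segment's later section, using
only their two section times and their current field rank.  Expanding
the weighted-time definitions

    WT_n  = T_n / IRDC_n
    WTV   = (T_{n+2}/IRDC_{n+2}) / (T_n/IRDC_n) - 1
    CPR   = rank / field size

turns the model into a closed-form expression in raw stopwatch times,
which is what a coach at a checkpoint actually has.  Two modes are
supported and never mixed: *replication* pins the published ascent-#1
coefficients together with the 2-decimal course coefficients they were
derived with, while *research* mode expands a freshly fitted model over
full-precision course coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .course import CourseProfile, Rounding, irdc
from .regression import SEGMENTS, RegressionResult, segment_columns

__all__ = [
    "PUBLISHED_MODELS",
    "PredictionRequest",
    "ClosedForm",
    "predict_tt",
    "expand_closed_form",
    "format_hours",
]

# Published coefficient sets per terrain segment (constant, WT, WTV,
# CPR), fitted on the pooled 4K/8K 2017-2019 cohort.  The ascent-#1 set
# is the one behind the published closed-form checkpoint equations.
PUBLISHED_MODELS: dict[str, dict[str, float]] = {
    "ascent1": {"constant": 0.939, "WT": 0.914, "WTV": 4.993, "CPR": 1.468},
    "descent": {"constant": 1.796, "WT": 1.411, "WTV": 3.321, "CPR": -0.465},
    "ascent2": {"constant": 2.295, "WT": 0.746, "WTV": 2.555, "CPR": 0.888},
}


@dataclass(frozen=True)
class PredictionRequest:
    """Mid-race inputs for one runner at a segment's closing checkpoint.

    ``rank_at_cp`` is the runner's current position at the segment's
    opening checkpoint as reported by live timing, against a field of
    ``field_size``; mid-race the final finisher count is unknown, so the
    caller supplies whichever field definition their timing feed uses.
    """

    modality: str
    segment: str
    section_times: Mapping[int, float]  # section index -> T_n (hours)
    rank_at_cp: int
    field_size: int

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if not 1 <= self.rank_at_cp <= self.field_size:
            raise ValueError(
                f"rank {self.rank_at_cp} outside field of {self.field_size}"
            )
        early, late, _ = SEGMENTS[self.segment]
        for n in (early, late):
            t = self.section_times.get(n)
            if t is None:
                raise ValueError(
                    f"segment {self.segment} needs the section-{n} time "
                    f"(checkpoint cp{n})"
                )
            if t <= 0:
                raise ValueError(f"section-{n} time must be positive, got {t}")


def _model_coefs(model) -> dict[str, float]:
    """Normalize a RegressionResult or name->value mapping to the
    canonical {constant, WT, WTV, CPR} keys."""
    if isinstance(model, RegressionResult):
        out = {"constant": model.coef("constant").b}
        wt_col, wtv_col, cpr_col = segment_columns(model.segment)
        out["WT"] = model.coef(wt_col).b
        out["WTV"] = model.coef(wtv_col).b
        out["CPR"] = model.coef(cpr_col).b
        return out
    missing = {"constant", "WT", "WTV", "CPR"} - set(model)
    if missing:
        raise ValueError(f"coefficient mapping missing {sorted(missing)}")
    return {k: float(model[k]) for k in ("constant", "WT", "WTV", "CPR")}


def predict_tt(
    model,
    request: PredictionRequest,
    course: CourseProfile,
    *,
    rounding: Rounding = "full",
) -> float:
    """Predict total race time (hours) by the feature path.

    Computes WT and WTV from the raw section times via the course's
    relative difficulty coefficients, CPR as rank/field_size, and
    evaluates the linear model.  Use ``rounding='published'`` together with
    published coefficients when replicating the printed checkpoint
    equations.
    """
    coefs = _model_coefs(model)
    early, late, _ = SEGMENTS[request.segment]
    irdc_early = irdc(course.section(early), course, rounding=rounding)
    irdc_late = irdc(course.section(late), course, rounding=rounding)
    wt_early = request.section_times[early] / irdc_early
    wt_late = request.section_times[late] / irdc_late
    wtv = wt_late / wt_early - 1.0
    cpr = request.rank_at_cp / request.field_size
    return (coefs["constant"] + coefs["WT"] * wt_early
            + coefs["WTV"] * wtv + coefs["CPR"] * cpr)


@dataclass(frozen=True)
class ClosedForm:
    """A segment model expanded into raw section times.

        TT = b_wt * T_early / irdc_early
           + b_wtv * ((T_late / irdc_late) / (T_early / irdc_early) - 1)
           + b_cpr * rank / field_size
           + constant

    The stored denominators are the course coefficients the model was
    expanded over, so the printed checkpoint equations are recovered
    term-for-term when published coefficients meet 2-decimal course
    coefficients.
    """

    modality: str
    segment: str
    early_section: int
    late_section: int
    constant: float
    b_wt: float
    irdc_early: float
    b_wtv: float
    irdc_late: float
    b_cpr: float

    def evaluate(self, t_early: float, t_late: float,
                 rank: int, field_size: int) -> float:
        wt_early = t_early / self.irdc_early
        wt_late = t_late / self.irdc_late
        return (self.constant
                + self.b_wt * wt_early
                + self.b_wtv * (wt_late / wt_early - 1.0)
                + self.b_cpr * rank / field_size)

    def describe(self) -> str:
        return (
            f"TT_{self.modality} = {self.b_wt:g} * T{self.early_section}/{self.irdc_early:g}"
            f" + {self.b_wtv:g} * ((T{self.late_section}/{self.irdc_late:g})"
            f"/(T{self.early_section}/{self.irdc_early:g}) - 1)"
            f" + {self.b_cpr:g} * rank/n + {self.constant:g}"
        )


def expand_closed_form(
    model,
    course: CourseProfile,
    modality: str | None = None,
    *,
    segment: str = "ascent1",
    rounding: Rounding = "published",
) -> ClosedForm:
    """Expand a segment model symbolically into raw section times.

    Only ascent-type segments are expandable (their WTV is a ratio of
    two uphill weighted times).  ``model`` is a RegressionResult or a
    {constant, WT, WTV, CPR} mapping such as ``PUBLISHED_MODELS['ascent1']``.
    """
    if segment not in ("ascent1", "ascent2"):
        raise ValueError(f"closed form only defined for ascent segments, not {segment!r}")
    modality = modality or course.name
    if modality != course.name:
        raise ValueError(
            f"modality {modality!r} does not match course {course.name!r}"
        )
    coefs = _model_coefs(model)
    early, late, _ = SEGMENTS[segment]
    return ClosedForm(
        modality=modality,
        segment=segment,
        early_section=early,
        late_section=late,
        constant=coefs["constant"],
        b_wt=coefs["WT"],
        irdc_early=irdc(course.section(early), course, rounding=rounding),
        b_wtv=coefs["WTV"],
        irdc_late=irdc(course.section(late), course, rounding=rounding),
        b_cpr=coefs["CPR"],
    )


def format_hours(hours: float) -> str:
    """Decimal hours -> 'H:MM:SS'."""
    total = round(hours * 3600)
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:d}:{m:02d}:{s:02d}"
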