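"""Geo-accumulation index, Hakanson potential ecological risk, and survey
summary statistics.

The geo-accumulation index for element i in a sample is

    I_geo = log2( C_i / (k · C0_i) )

with C0 the geochemical background and k (default 1.5) a correction for
natural background variation.  The single-element potential ecological risk
is the toxicity-weighted enrichment

    E_r = T_r · C_i / C0_i

and the comprehensive index RI is the sum of E_r over the element panel.
Because the classical RI grading assumes Hakanson's original substance set
(ΣT_r = 133, first threshold 150), the thresholds are re-scaled to the
panel in use via the unit toxicity value 150/133 (see
:func:`derive_ri_thresholds`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ReferenceSet, SamplePanel, ValidationError

#: Five-class geo-accumulation grading; upper bounds inclusive.
IGEO_BOUNDS = (0.0, 1.0, 2.0, 3.0)
IGEO_LABELS = ("none", "slight", "moderate", "severe", "extremely_severe")

#: Single-element ecological risk grading; lower bounds inclusive.
ER_BOUNDS = (40.0, 80.0, 160.0, 320.0)
ER_LABELS = ("slight", "moderate", "strong", "very_strong", "extremely_strong")

RI_LABELS = ("low", "moderate", "high", "extremely_high")


@dataclass(frozen=True)
class RIGrading:
    """Panel-rescaled RI grading thresholds.

    ``unit_value`` is the risk-per-unit-toxicity grading value 150/133;
    level2 and level3 double the previous level.
    """

    unit_value: float
    level1: float
    level2: float
    level3: float

    @property
    def bounds(self) -> tuple[float, float, float]:
        return (self.level1, self.level2, self.level3)


@dataclass
class IgeoResult:
    """Per-sample, per-element geo-accumulation values (log2 units) and
    grades."""

    value: pd.DataFrame
    grade: pd.DataFrame


@dataclass
class EcoRiskResult:
    """Single-element risks ``er`` with grades, and (once computed) the
    per-sample comprehensive index ``ri`` with its grading."""

    er: pd.DataFrame
    er_grade: pd.DataFrame
    ri: pd.Series | None = None
    ri_grade: pd.Series | None = None
    grading: RIGrading | None = None


def _grade(values: np.ndarray, bounds, labels, lower_inclusive: bool) -> np.ndarray:
    """Map values to grade labels over half-open intervals.

    ``lower_inclusive=True`` puts a boundary value into the higher class
    (e.g. E_r = 40 → moderate); ``False`` keeps it in the lower class
    (I_geo = 1 → slight).
    """
    side = "right" if lower_inclusive else "left"
    idx = np.searchsorted(np.asarray(bounds), values, side=side)
    return np.asarray(labels, dtype=object)[idx]


def compute_igeo(
    panel: SamplePanel,
    refs: ReferenceSet,
    labels: tuple[str, ...] = IGEO_LABELS,
) -> IgeoResult:
    """Geo-accumulation index per sample and element.

    Requires strictly positive concentrations — substitute non-detects
    first; a zero would send the log to −∞.
    """
    refs.require_elements(panel.elements)
    conc = panel.values()
    if (conc <= 0).any():
        raise ValidationError(
            "nonpositive concentration: run substitute_nondetects before "
            "compute_igeo"
        )
    c0 = refs.background[list(panel.elements)].to_numpy()
    val = np.log2(conc / (refs.igeo_k * c0))
    value = pd.DataFrame(val, index=panel.sample_ids, columns=list(panel.elements))
    grade = pd.DataFrame(
        _grade(val, IGEO_BOUNDS, labels, lower_inclusive=False),
        index=panel.sample_ids,
        columns=list(panel.elements),
    )
    return IgeoResult(value=value, grade=grade)


def compute_er(panel: SamplePanel, refs: ReferenceSet) -> EcoRiskResult:
    """Single-element potential ecological risk E_r = T_r · C / C0."""
    refs.require_elements(panel.elements)
    conc = panel.values()
    c0 = refs.background[list(panel.elements)].to_numpy()
    tr = refs.toxicity_coefficient[list(panel.elements)].to_numpy()
    er = tr * conc / c0
    er_df = pd.DataFrame(er, index=panel.sample_ids, columns=list(panel.elements))
    grade = pd.DataFrame(
        _grade(er, ER_BOUNDS, ER_LABELS, lower_inclusive=True),
        index=panel.sample_ids,
        columns=list(panel.elements),
    )
    return EcoRiskResult(er=er_df, er_grade=grade)


def compute_ri(
    eco: EcoRiskResult, grading: RIGrading | None = None, refs: ReferenceSet | None = None
) -> EcoRiskResult:
    """Comprehensive index RI = Σ_elements E_r with panel-rescaled grading.

    Pass either an explicit :class:`RIGrading` or a reference set from which
    to derive one.
    """
    if grading is None:
        if refs is None:
            raise ValidationError("compute_ri needs a grading or a reference set")
        grading = derive_ri_thresholds(refs)
    ri = eco.er.sum(axis=1)
    labels = _grade(ri.to_numpy(), grading.bounds, RI_LABELS, lower_inclusive=True)
    return EcoRiskResult(
        er=eco.er,
        er_grade=eco.er_grade,
        ri=ri,
        ri_grade=pd.Series(labels, index=ri.index),
        grading=grading,
    )


def derive_ri_thresholds(refs: ReferenceSet) -> RIGrading:
    """Re-scale the RI grading to the element panel in use.

    Hakanson's first-level threshold of 150 corresponds to a substance set
    with ΣT_r = 133, i.e. a grading value of 150/133 per unit toxicity
    coefficient.  The panel's first-level threshold is that unit value times
    its own ΣT_r, rounded half-up to an integer; subsequent levels double.
    """
    tr = refs.toxicity_coefficient
    if len(tr) == 0:
        raise ValidationError("empty element panel")
    unit = 150.0 / 133.0
    level1 = math.floor(unit * float(tr.sum()) + 0.5)
    return RIGrading(
        unit_value=unit, level1=level1, level2=2 * level1, level3=4 * level1
    )


def summarize_panel(panel: SamplePanel, refs: ReferenceSet) -> pd.DataFrame:
    """Descriptive statistics per element, survey-report style.

    Columns: min, max, mean, sd (sample, n−1), cv (= sd/mean), background,
    exceedance_factor (= (mean − C0)/C0) and frac_above_background (share of
    samples with C > C0).
    """
    if panel.n_samples < 2:
        raise ValidationError("summary needs at least 2 samples")
    refs.require_elements(panel.elements)
    conc = pd.DataFrame(
        panel.values(), index=panel.sample_ids, columns=list(panel.elements)
    )
    c0 = refs.background[list(panel.elements)]
    mean = conc.mean()
    sd = conc.std(ddof=1)
    cv = (sd / mean).where(mean != 0, 0.0)
    out = pd.DataFrame(
        {
            "min": conc.min(),
            "max": conc.max(),
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "background": c0,
            "exceedance_factor": (mean - c0) / c0,
            "frac_above_background": (conc.gt(c0, axis=1)).mean(),
        }
    )
    out.index.name = "element"
    return out


def grade_proportions(grade: pd.DataFrame) -> pd.DataFrame:
    """Share of samples in each grade per element (rows: element)."""
    props = {}
    for el in grade.columns:
        props[el] = grade[el].value_counts(normalize=True)
    out = pd.DataFrame(props).T.fillna(0.0)
    out.index.name = "element"
    return out
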