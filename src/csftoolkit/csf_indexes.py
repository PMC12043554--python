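"""CSF immunoglobulin index scores.

Three indexes infer intrathecal IgG synthesis (ISI) from paired serum/CSF
albumin and IgG concentrations:

* ``QIgG``  = CSF IgG / serum IgG (dimensionless; literature cutoff 0.0035);
* ``IgG index`` = QIgG / QAlb, where QAlb = CSF albumin / serum albumin
  (literature cutoff 0.7);
* the Reiber hyperbolic discrimination value
  serum IgG x (QIgG - QLim), in mg/L of intrathecally produced IgG, with
  QLim = 0.93 * sqrt(QAlb^2 + 6e-6) - 1.7e-3 the upper reference limit of
  QIgG expected from passive serum-to-CSF diffusion.  A positive value
  indicates probable synthesis.

QAlb inside QLim may come either from the age-based reference
QAlb = (4 + age/15) / 1000 or from the measured albumin quotient; both are
supported via :class:`ThresholdConfig.qalb_source`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort_io import PatientRecord
from .errors import DomainError

__all__ = [
    "IndexPanel",
    "ThresholdConfig",
    "PanelClassification",
    "q_igg",
    "q_alb_measured",
    "q_alb_age",
    "igg_index",
    "q_lim",
    "reiber_value",
    "compute_panel",
    "classify_panel",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Positivity cutoffs (all comparisons are strict '>').

    ``qigg_cutoff``/``igg_index_cutoff``/``reiber_cutoff`` are the
    literature thresholds; the ``refined_*`` values are the Youden-derived
    recalibrations for the neuro-ICU setting.  The refined Reiber rule is
    expressed on the formula's output scale: value > 5.46 mg/L above the
    diffusion limit.
    """

    qigg_cutoff: float = 0.0035
    igg_index_cutoff: float = 0.7
    reiber_cutoff: float = 0.0  # mg/L; >0 is equivalent to QIgG > QLim
    refined_qigg_cutoff: float = 0.005
    refined_igg_index_cutoff: float = 0.67
    refined_reiber_cutoff: float = 5.46  # mg/L
    qalb_source: str = "age"  # "age" | "measured"

    def __post_init__(self) -> None:
        if self.qalb_source not in ("age", "measured"):
            raise DomainError(f"qalb_source must be 'age' or 'measured', got {self.qalb_source!r}")
        for name in ("refined_qigg_cutoff", "refined_igg_index_cutoff", "refined_reiber_cutoff"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class IndexPanel:
    """All computed quotients and index values for one patient."""

    q_alb_measured: float
    q_alb_age: float
    q_igg: float
    igg_index: float
    q_lim: float
    reiber_value: float  # mg/L; may be negative


@dataclass(frozen=True)
class PanelClassification:
    qigg_positive: bool
    igg_index_positive: bool
    reiber_positive: bool


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be a positive finite number, got {value!r}")


def q_igg(csf_igg: float, serum_igg: float) -> float:
    """IgG quotient from CSF IgG (mg/L) and serum IgG (g/L)."""
    _require_positive(csf_igg=csf_igg, serum_igg=serum_igg)
    return csf_igg / (serum_igg * 1000.0)


def q_alb_measured(csf_albumin: float, serum_albumin: float) -> float:
    """Measured albumin quotient from CSF albumin (mg/L) and serum albumin (g/L)."""
    _require_positive(csf_albumin=csf_albumin, serum_albumin=serum_albumin)
    return csf_albumin / (serum_albumin * 1000.0)


def q_alb_age(age: float) -> float:
    """Age-based reference albumin quotient, (4 + age/15) / 1000."""
    _require_positive(age=age)
    return (4.0 + age / 15.0) / 1000.0


def igg_index(q_igg_value: float, q_alb: float) -> float:
    """IgG index: QIgG normalized by the measured albumin quotient."""
    _require_positive(q_igg=q_igg_value, q_alb=q_alb)
    return q_igg_value / q_alb


def q_lim(q_alb: float) -> float:
    """Hyperbolic upper reference limit for QIgG at a given QAlb.

    0.93 * sqrt(QAlb^2 + 6e-6) - 1.7e-3; monotonically increasing in QAlb
    with asymptote 0.93*QAlb - 1.7e-3.
    """
    _require_positive(q_alb=q_alb)
    return 0.93 * math.sqrt(q_alb * q_alb + 6e-6) - 1.7e-3


def reiber_value(serum_igg: float, q_igg_value: float, q_lim_value: float) -> float:
    """Intrathecal IgG amount in mg/L: serum IgG (g/L) x (QIgG - QLim).

    The sign carries the interpretation: positive means QIgG exceeds the
    diffusion-only upper limit.
    """
    _require_positive(serum_igg=serum_igg)
    return serum_igg * 1000.0 * (q_igg_value - q_lim_value)


def compute_panel(record: PatientRecord, config: ThresholdConfig = ThresholdConfig()) -> IndexPanel:
    """Compute every index for one patient record.

    QLim uses the age-based or measured QAlb per ``config.qalb_source``;
    the IgG index always uses the measured albumin quotient.
    """
    try:
        qa_meas = q_alb_measured(record.csf_albumin, record.serum_albumin)
        qa_age = q_alb_age(record.age)
        qi = q_igg(record.csf_igg, record.serum_igg)
        index = igg_index(qi, qa_meas)
        ql = q_lim(qa_age if config.qalb_source == "age" else qa_meas)
        reiber = reiber_value(record.serum_igg, qi, ql)
    except DomainError as exc:
        raise DomainError(f"patient {record.patient_id!r}: {exc}") from exc
    return IndexPanel(
        q_alb_measured=qa_meas,
        q_alb_age=qa_age,
        q_igg=qi,
        igg_index=index,
        q_lim=ql,
        reiber_value=reiber,
    )


def classify_panel(
    panel: IndexPanel, config: ThresholdConfig = ThresholdConfig(), refined: bool = False
) -> PanelClassification:
    """Classify a panel against literature (refined=False) or refined cutoffs."""
    if refined:
        return PanelClassification(
            qigg_positive=panel.q_igg > config.refined_qigg_cutoff,
            igg_index_positive=panel.igg_index > config.refined_igg_index_cutoff,
            reiber_positive=panel.reiber_value > config.refined_reiber_cutoff,
        )
    return PanelClassification(
        qigg_positive=panel.q_igg > config.qigg_cutoff,
        igg_index_positive=panel.igg_index > config.igg_index_cutoff,
        reiber_positive=panel.reiber_value > config.reiber_cutoff,
    )
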