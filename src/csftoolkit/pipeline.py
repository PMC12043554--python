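"""End-to-end cohort analysis and per-patient decision support.

``run_analysis`` reproduces the structure of a full CSF-index study for
both outcomes (ISI by IEF and the CNS-AD diagnosis group): stratified
summaries, per-index diagnostic performance at literature and refined
cutoffs, ROC / AUC / grey zone per index, a univariable factor screen and
a backward-stepwise multivariable logistic model.  Everything in the
report is recomputable from the cohort and configuration alone.

``decision_support`` applies the grey-zone interpretation of the IgG
index to a single patient, with fixed clinical caveat flags: the output
is a three-way likelihood statement, never a treatment directive.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association_models import FactorSpec, LogisticFit, backward_stepwise, univariable_screen
from .cohort_io import Cohort, PatientRecord, summarize_cohort
from .csf_indexes import IndexPanel, ThresholdConfig, classify_panel, compute_panel
from .diagnostic_performance import (
    DiagnosticPerformance,
    performance_from_table,
    table_from_labels,
)
from .errors import DomainError
from .roc_thresholds import GreyZone, auc_null_test, build_roc, grey_zone, youden_optimal_cutoff

__all__ = ["AnalysisReport", "DecisionOutput", "panel_frame", "run_analysis",
           "decision_support", "DEFAULT_FACTORS"]

INDEX_COLUMNS = ("q_igg", "igg_index", "reiber_value")

#: factor set screened by default (continuous fields dichotomized at the median)
DEFAULT_FACTORS = (
    FactorSpec("age", "below_median", "age below median"),
    FactorSpec("hiv_positive", "as_is_boolean", "HIV positive"),
    FactorSpec("csf_leukocytes", "above_median", "CSF leukocytes above median"),
)


def panel_frame(cohort: Cohort, config: ThresholdConfig = ThresholdConfig()) -> pd.DataFrame:
    """Per-patient index panel plus positivity calls at both cutoff sets."""
    rows = []
    for record in cohort:
        panel = compute_panel(record, config)
        lit = classify_panel(panel, config, refined=False)
        ref = classify_panel(panel, config, refined=True)
        rows.append(
            {
                "patient_id": record.patient_id,
                "isi_positive": record.isi_positive,
                "cns_ad": record.cns_ad,
                **asdict(panel),
                "qigg_positive": lit.qigg_positive,
                "igg_index_positive": lit.igg_index_positive,
                "reiber_positive": lit.reiber_positive,
                "qigg_positive_refined": ref.qigg_positive,
                "igg_index_positive_refined": ref.igg_index_positive,
                "reiber_positive_refined": ref.reiber_positive,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IndexOutcomeResult:
    """One marker evaluated against one outcome."""

    performance: DiagnosticPerformance
    performance_refined: DiagnosticPerformance
    auc: float
    auc_p_value: float
    youden_cutoff: float
    grey_zone: GreyZone


@dataclass
class OutcomeSection:
    outcome: str
    summary: pd.DataFrame
    indexes: dict[str, IndexOutcomeResult]
    univariable: dict[str, LogisticFit]
    multivariable: LogisticFit
    flags: list[str] = field(default_factory=list)


@dataclass
class AnalysisReport:
    sections: dict[str, OutcomeSection]
    panels: pd.DataFrame
    config_hash: str
    seed: int
    version: str = __version__

    def to_json(self, indent: int = 2) -> str:
        """Machine-readable report body (deterministic; no timestamps)."""

        def perf_dict(perf: DiagnosticPerformance) -> dict:
            return {
                "sensitivity": perf.sensitivity.value,
                "specificity": perf.specificity.value,
                "ppv": perf.ppv.value,
                "npv": perf.npv.value,
                "lr_positive": perf.lr_positive,
                "lr_negative": perf.lr_negative,
                "youden": perf.youden,
                "counts": asdict(perf.table),
            }

        body = {"config_hash": self.config_hash, "seed": self.seed, "version": self.version,
                "sections": {}}
        for name, section in self.sections.items():
            body["sections"][name] = {
                "summary": section.summary.to_dict(orient="records"),
                "indexes": {
                    marker: {
                        "performance": perf_dict(res.performance),
                        "performance_refined": perf_dict(res.performance_refined),
                        "auc": res.auc,
                        "auc_p_value": res.auc_p_value,
                        "youden_cutoff": res.youden_cutoff,
                        "grey_zone": {"lower": res.grey_zone.lower, "upper": res.grey_zone.upper},
                    }
                    for marker, res in section.indexes.items()
                },
                "univariable": {
                    label: {
                        "odds_ratio": fit.terms[0].odds_ratio if fit.terms else None,
                        "ci": [fit.terms[0].ci_low, fit.terms[0].ci_high] if fit.terms else None,
                        "p_value": fit.terms[0].p_value if fit.terms else None,
                        "n_used": fit.n_used,
                    }
                    for label, fit in section.univariable.items()
                },
                "multivariable": {
                    "terms": [asdict(t) for t in section.multivariable.terms],
                    "n_used": section.multivariable.n_used,
                    "removal_trace": section.multivariable.removal_trace,
                },
                "flags": section.flags,
            }
        return json.dumps(body, indent=indent, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(config: ThresholdConfig, seed: int) -> str:
    payload = json.dumps({**asdict(config), "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _index_factor(marker: str, config: ThresholdConfig) -> tuple[str, float]:
    cutoffs = {
        "q_igg": config.qigg_cutoff,
        "igg_index": config.igg_index_cutoff,
        "reiber_value": config.reiber_cutoff,
    }
    return f"{marker} above cutoff", cutoffs[marker]


def run_analysis(
    cohort: Cohort,
    config: ThresholdConfig = ThresholdConfig(),
    seed: int = 0,
    factors: tuple[FactorSpec, ...] = DEFAULT_FACTORS,
    index_in_model: str = "igg_index",
) -> AnalysisReport:
    """Run the full analysis for both outcomes.

    ``index_in_model`` names the single CSF index entered into the
    association models (the three indexes are collinear by construction,
    so only the best-performing one is modelled).
    """
    panels = panel_frame(cohort, config)
    refined_cols = {
        "q_igg": "qigg_positive_refined",
        "igg_index": "igg_index_positive_refined",
        "reiber_value": "reiber_positive_refined",
    }
    lit_cols = {
        "q_igg": "qigg_positive",
        "igg_index": "igg_index_positive",
        "reiber_value": "reiber_positive",
    }

    sections: dict[str, OutcomeSection] = {}
    for outcome_name, outcome_col in (("isi", "isi_positive"), ("cns_ad", "cns_ad")):
        labels = panels[outcome_col].to_numpy(dtype=bool)
        flags: list[str] = []
        summary = summarize_cohort(cohort, outcome_col)
        indexes: dict[str, IndexOutcomeResult] = {}
        single_class = not (labels.any() and (~labels).any())
        if single_class:
            flags.append(f"outcome {outcome_col!r} is single-class; index sections skipped")
        else:
            for marker in INDEX_COLUMNS:
                scores = panels[marker].to_numpy(dtype=float)
                curve = build_roc(scores, labels)
                p = auc_null_test(scores, labels, method="normal")
                cutoff, _ = youden_optimal_cutoff(curve)
                gz = grey_zone(curve)
                indexes[marker] = IndexOutcomeResult(
                    performance=performance_from_table(
                        table_from_labels(panels[lit_cols[marker]].to_numpy(bool), labels)
                    ),
                    performance_refined=performance_from_table(
                        table_from_labels(panels[refined_cols[marker]].to_numpy(bool), labels)
                    ),
                    auc=curve.auc,
                    auc_p_value=p,
                    youden_cutoff=cutoff,
                    grey_zone=gz,
                )

        # association models: screened factors plus the retained CSF index
        index_label, _ = _index_factor(index_in_model, config)
        augmented = _cohort_with_index_factor(cohort, panels, index_in_model, lit_cols)
        model_factors = list(factors) + [FactorSpec("__index_factor__", "as_is_boolean",
                                                    index_label)]
        if single_class:
            univariable: dict[str, LogisticFit] = {}
            multivariable = LogisticFit(terms=[], intercept=math.nan, converged=False, n_used=0)
            flags.append("association models skipped (single-class outcome)")
        else:
            univariable = {}
            usable: list[FactorSpec] = []
            for spec in model_factors:
                try:
                    univariable[spec.display_label] = univariable_screen(
                        augmented, outcome_col, [spec]
                    )[spec.display_label]
                    usable.append(spec)
                except DomainError as exc:
                    flags.append(f"factor {spec.display_label!r} excluded: {exc}")
            significant = [
                spec
                for spec in usable
                if univariable[spec.display_label].terms
                and univariable[spec.display_label].terms[0].converged
                and univariable[spec.display_label].terms[0].p_value < 0.05
            ]
            multivariable = backward_stepwise(augmented, outcome_col, significant)

        sections[outcome_name] = OutcomeSection(
            outcome=outcome_name,
            summary=summary,
            indexes=indexes,
            univariable=univariable,
            multivariable=multivariable,
            flags=flags,
        )
    return AnalysisReport(
        sections=sections,
        panels=panels,
        config_hash=_config_hash(config, seed),
        seed=seed,
    )


class _AugmentedCohort(Cohort):
    """Cohort whose frame carries an extra per-patient boolean column."""

    def __init__(self, base: Cohort, column: pd.Series):
        super().__init__(records=base.records, provenance=base.provenance)
        self._extra = column

    def to_frame(self) -> pd.DataFrame:
        frame = super().to_frame()
        frame["__index_factor__"] = self._extra.to_numpy()
        return frame


def _cohort_with_index_factor(cohort, panels, marker, lit_cols) -> Cohort:
    return _AugmentedCohort(cohort, panels[lit_cols[marker]].astype(bool))


@dataclass(frozen=True)
class DecisionOutput:
    category: Optional[str]  # 'unlikely' | 'intermediate' | 'likely' | None if not computable
    igg_index: Optional[float]
    grey_zone: GreyZone
    caveats: tuple[str, ...]


_CAVEATS = (
    "isoelectric focusing remains the gold standard for intrathecal synthesis",
    "a negative IgG index does not exclude intrathecal synthesis",
    "interpret alongside imaging, microbiology (multiplex PCR) and HIV status",
)


def decision_support(
    record: PatientRecord,
    zone: GreyZone = GreyZone(lower=0.67, upper=0.80),
    config: ThresholdConfig = ThresholdConfig(),
) -> DecisionOutput:
    """Classify one patient's IgG index against a grey zone.

    Pure function of (record, zone, config).  A record whose index cannot
    be computed yields an explicit not-computable output rather than a
    silent default.
    """
    try:
        panel: IndexPanel = compute_panel(record, config)
    except DomainError:
        return DecisionOutput(
            category=None,
            igg_index=None,
            grey_zone=zone,
            caveats=_CAVEATS + ("IgG index not computable from the supplied analytes",),
        )
    return DecisionOutput(
        category=zone.classify(panel.igg_index),
        igg_index=panel.igg_index,
        grey_zone=zone,
        caveats=_CAVEATS,
    )
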