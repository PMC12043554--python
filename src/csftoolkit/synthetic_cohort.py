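"""Synthetic neuro-ICU cohort generator.

Emulates the joint structure a CSF-index study needs: an IEF reference
status (ISI) with ~35% prevalence, a CNS autoimmune-disease grouping
(~39%) cross-linked to ISI, class-conditional age / HIV / CSF-leukocyte
distributions, serum analytes, a measured albumin quotient, and an IgG
index drawn per ISI class from log-normal distributions calibrated so
that P(index > 0.7 | ISI+) and P(index > 0.7 | ISI-) hit configured
exceedance targets (defaults 0.57 and 0.06).  CSF analytes are then
back-solved (csf_albumin = QAlb x serum_albumin x 1000, csf_igg =
index x QAlb x serum_igg x 1000) so recomputing the panel from the
generated record recovers the sampled index exactly.

Randomness: one root seed spawns an independent child stream per field
(fixed order), so adding a new field never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort_io import Cohort, PatientRecord
from .errors import ConfigurationError, DomainError

__all__ = ["ClassStats", "GeneratorConfig", "calibrate_lognormal", "generate",
           "generate_with_effects"]


@dataclass(frozen=True)
class ClassStats:
    """Per-ISI-class distribution targets (ISI-positive, ISI-negative)."""

    positive: float
    negative: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the target population: ISI prevalence 0.35, CNS-AD
    prevalence 0.39 with P(ISI+ | CNS-AD) = 0.53, IgG-index exceedance of
    the 0.7 cutoff 57% / 6% per ISI class, class age medians 38 / 54 with
    log-normal spreads fitted to the interquartile ranges, HIV rates
    10/93 / 1/173, CSF leukocyte medians 7 / 2 per mm3, serum albumin
    ~ Normal(36, 11) g/L truncated above 10, serum IgG log-normal with
    median 11 g/L, measured QAlb log-normal with median 0.00722.
    """

    n: int = 266
    prev_isi: float = 0.35
    prev_cnsad: float = 0.39
    p_isi_given_cnsad: float = 0.53
    index_threshold: float = 0.7
    exceed: ClassStats = ClassStats(0.57, 0.06)
    index_sigma: ClassStats = ClassStats(0.35, 0.30)
    age_median: ClassStats = ClassStats(38.0, 54.0)
    age_sigma: ClassStats = ClassStats(0.487, 0.420)  # ln(q75/q25)/(2*z75)
    age_bounds: tuple[float, float] = (18.0, 95.0)
    hiv_rate: ClassStats = ClassStats(10 / 93, 1 / 173)
    leuko_median: ClassStats = ClassStats(7.0, 2.0)
    leuko_sigma: ClassStats = ClassStats(2.1, 1.5)
    serum_albumin_mean: float = 36.0  # g/L
    serum_albumin_sd: float = 11.0
    serum_albumin_floor: float = 10.0
    serum_igg_median: float = 11.0  # g/L
    serum_igg_sigma: float = 0.47
    qalb_median: float = 0.00722
    qalb_sigma: float = 0.60
    missing_rate: float = 0.0  # optional-field missingness, for I/O testing

    def validate(self) -> None:
        for name in ("prev_isi", "prev_cnsad", "p_isi_given_cnsad", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        if not 0.0 < self.prev_cnsad < 1.0:
            raise ConfigurationError("prev_cnsad must be in (0,1)")
        # Bayes-inverted conditionals must be valid probabilities
        for p in self._cnsad_conditionals():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    "prev_isi/prev_cnsad/p_isi_given_cnsad imply a conditional outside [0,1]"
                )

    def _cnsad_conditionals(self) -> tuple[float, float]:
        """(P(CNS-AD | ISI+), P(CNS-AD | ISI-)) by Bayes inversion."""
        if self.prev_isi in (0.0, 1.0):
            return self.prev_cnsad, self.prev_cnsad
        p_pos = self.p_isi_given_cnsad * self.prev_cnsad / self.prev_isi
        p_neg = (1 - self.p_isi_given_cnsad) * self.prev_cnsad / (1 - self.prev_isi)
        return p_pos, p_neg


def calibrate_lognormal(threshold: float, exceed_prob: float, sigma: float) -> float:
    """Location mu such that log-normal(mu, sigma) exceeds ``threshold``
    with probability ``exceed_prob``: mu = ln(t) - sigma * Phi^-1(1 - p)."""
    if threshold <= 0 or sigma <= 0:
        raise DomainError("threshold and sigma must be positive")
    if not 0.0 < exceed_prob < 1.0:
        raise DomainError("exceed_prob must be strictly inside (0,1)")
    return math.log(threshold) - sigma * stats.norm.ppf(1.0 - exceed_prob)


_FIELD_STREAMS = (
    "isi", "cnsad", "age", "sex", "hiv", "leukocytes",
    "serum_albumin", "serum_igg", "qalb", "igg_index", "missing",
)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_FIELD_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_FIELD_STREAMS, children)}


def _pick(stat: ClassStats, isi: np.ndarray) -> np.ndarray:
    return np.where(isi, stat.positive, stat.negative)


def _truncated_lognormal_mu(target_median: float, sigma: float, low: float,
                            high: float) -> float:
    """Location mu such that log-normal(mu, sigma) truncated to [low, high]
    has median ``target_median`` (plain truncation would shift it)."""
    from scipy.optimize import brentq

    def median_gap(mu: float) -> float:
        a = stats.norm.cdf((math.log(low) - mu) / sigma)
        b = stats.norm.cdf((math.log(high) - mu) / sigma)
        m = math.exp(mu + sigma * stats.norm.ppf((a + b) / 2.0))
        return m - target_median

    return brentq(median_gap, math.log(low), math.log(high), xtol=1e-10)


def _truncated_lognormal(rng, target_median, sigma, low, high, size) -> np.ndarray:
    """Inverse-CDF sampling of a truncated log-normal with its median
    corrected to ``target_median`` (vector of per-draw targets allowed)."""
    target_median = np.broadcast_to(np.asarray(target_median, dtype=float), (size,))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (size,))
    pairs = {(m, s): _truncated_lognormal_mu(m, s, low, high)
             for m, s in set(zip(target_median.tolist(), sigma.tolist()))}
    mu = np.array([pairs[(m, s)] for m, s in zip(target_median.tolist(), sigma.tolist())])
    a = stats.norm.cdf((math.log(low) - mu) / sigma)
    b = stats.norm.cdf((math.log(high) - mu) / sigma)
    u = a + (b - a) * rng.random(size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _sample_fields(
    config: GeneratorConfig,
    isi: np.ndarray,
    streams: Mapping[str, np.random.Generator],
) -> dict[str, np.ndarray]:
    n = len(isi)
    p_pos, p_neg = config._cnsad_conditionals()
    cnsad = streams["cnsad"].random(n) < np.where(isi, p_pos, p_neg)

    age = _truncated_lognormal(
        streams["age"],
        _pick(config.age_median, isi),
        _pick(config.age_sigma, isi),
        *config.age_bounds,
        size=n,
    )
    age = np.round(age).astype(int)
    sex = np.where(streams["sex"].random(n) < 0.42, "female", "male")
    hiv = streams["hiv"].random(n) < _pick(config.hiv_rate, isi)
    leuko = np.round(
        np.exp(streams["leukocytes"].normal(np.log(_pick(config.leuko_median, isi)),
                                            _pick(config.leuko_sigma, isi)))
    )
    serum_albumin = config.serum_albumin_mean + config.serum_albumin_sd * streams[
        "serum_albumin"
    ].standard_normal(n)
    while (serum_albumin <= config.serum_albumin_floor).any():
        bad = serum_albumin <= config.serum_albumin_floor
        serum_albumin[bad] = config.serum_albumin_mean + config.serum_albumin_sd * streams[
            "serum_albumin"
        ].standard_normal(int(bad.sum()))
    serum_igg = np.exp(
        streams["serum_igg"].normal(np.log(config.serum_igg_median), config.serum_igg_sigma, n)
    )
    qalb = np.exp(streams["qalb"].normal(np.log(config.qalb_median), config.qalb_sigma, n))

    mu = np.where(
        isi,
        calibrate_lognormal(config.index_threshold, config.exceed.positive,
                            config.index_sigma.positive),
        calibrate_lognormal(config.index_threshold, config.exceed.negative,
                            config.index_sigma.negative),
    )
    igg_index = np.exp(streams["igg_index"].normal(mu, _pick(config.index_sigma, isi)))

    return {
        "cnsad": cnsad, "age": age, "sex": sex, "hiv": hiv, "leuko": leuko,
        "serum_albumin": serum_albumin, "serum_igg": serum_igg,
        "qalb": qalb, "igg_index": igg_index,
    }


def _assemble(
    config: GeneratorConfig,
    isi: np.ndarray,
    fields: dict[str, np.ndarray],
    streams: Mapping[str, np.random.Generator],
    provenance: str,
) -> Cohort:
    n = len(isi)
    miss = streams["missing"].random((n, 2)) < config.missing_rate
    records = []
    for i in range(n):
        qalb = fields["qalb"][i]
        serum_alb = fields["serum_albumin"][i]
        serum_igg = fields["serum_igg"][i]
        records.append(
            PatientRecord(
                patient_id=f"SYN-{i + 1:06d}",
                age=int(fields["age"][i]),
                sex=str(fields["sex"][i]),
                isi_positive=bool(isi[i]),
                cns_ad=bool(fields["cnsad"][i]),
                csf_albumin=qalb * serum_alb * 1000.0,
                csf_igg=fields["igg_index"][i] * qalb * serum_igg * 1000.0,
                serum_albumin=serum_alb,
                serum_igg=serum_igg,
                hiv_positive=None if miss[i, 0] else bool(fields["hiv"][i]),
                csf_leukocytes=None if miss[i, 1] else float(fields["leuko"][i]),
            )
        )
    return Cohort(records=records, provenance=provenance)


def generate(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> Cohort:
    """Draw a cohort of ``config.n`` synthetic patients (deterministic per seed)."""
    config.validate()
    streams = _streams(seed)
    isi = streams["isi"].random(config.n) < config.prev_isi
    fields = _sample_fields(config, isi, streams)
    return _assemble(config, isi, fields, streams, f"synthetic cohort (seed={seed})")


def generate_with_effects(
    config: GeneratorConfig,
    intercept: float,
    coefficients: Mapping[str, float],
    seed: int = 0,
) -> Cohort:
    """Generate with ISI drawn from a logistic model over derived factors.

    ``coefficients`` maps factor names to log-odds-ratio coefficients.
    Supported factors: ``age_below_50``, ``hiv_positive``,
    ``leukocytes_above_4``, ``igg_index_above_cutoff`` (the config's
    index threshold).  Covariates are drawn from the ISI-prevalence-
    weighted mixture of the per-class distributions, then ISI status is
    Bernoulli(logistic(intercept + sum(beta * x))).
    """
    config.validate()
    known = {"age_below_50", "hiv_positive", "leukocytes_above_4", "igg_index_above_cutoff"}
    unknown = set(coefficients) - known
    if unknown:
        raise ConfigurationError(f"unknown factor name(s): {sorted(unknown)}")
    streams = _streams(seed)
    # latent mixture class drives covariate distributions only
    latent = streams["isi"].random(config.n) < config.prev_isi
    fields = _sample_fields(config, latent, streams)
    eta = np.full(config.n, float(intercept))
    factor_values = {
        "age_below_50": fields["age"] < 50,
        "hiv_positive": fields["hiv"],
        "leukocytes_above_4": fields["leuko"] > 4,
        "igg_index_above_cutoff": fields["igg_index"] > config.index_threshold,
    }
    for name, beta in coefficients.items():
        eta += beta * factor_values[name].astype(float)
    p = 1.0 / (1.0 + np.exp(-eta))
    isi = streams["isi"].random(config.n) < p
    if isi.all() or not isi.any():
        raise DomainError("logistic model produced a single-class cohort; adjust intercept")
    # redraw class-linked fields conditional on the realized ISI status
    fields["cnsad"] = streams["cnsad"].random(config.n) < np.where(
        isi, *config._cnsad_conditionals()
    )
    return _assemble(config, isi, fields, streams, f"synthetic cohort with effects (seed={seed})")
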