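"""Synthetic count tables and patient records with known ground truth.

Two generators back the test surface of the whole pipeline:

* binomial count tables with known per-class probabilities, for sampler
  recovery and calibration experiments, and
* record-level dog tables with neuter and diagnosis dates, deliberately
  placing a fraction of diagnoses shortly before the neuter date so the
  status-at-diagnosis reclassification is exercised.

Replicate ``k`` of any simulation is reproducible in isolation: a master
seed feeds a per-replicate spawned stream, so regenerating one replicate
never requires regenerating the others.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_ingest import CLASS_ORDER, CountTable, PatientRecord, SexClass

__all__ = [
    "SimulationSpec",
    "SimulatedTable",
    "simulate_count_tables",
    "simulate_count_table",
    "exchangeable_spec",
    "RecordSimSpec",
    "RecordTruth",
    "simulate_records",
    "COHORT_TOTALS",
]

#: Class denominators matching the packaged cohort profile.
COHORT_TOTALS = {
    SexClass.F: 9_133,
    SexClass.NF: 36_574,
    SexClass.M: 12_555,
    SexClass.NM: 31_828,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Binomial count-table simulation settings: known p_i and denominators."""

    true_p: Mapping[SexClass, float]
    totals: Mapping[SexClass, int]
    n_replicates: int = 1
    seed: int = 0
    disease: str = "SIM"

    def __post_init__(self) -> None:
        if set(self.true_p) != set(self.totals):
            raise ValueError("true_p and totals must cover the same classes")
        if not self.true_p:
            raise ValueError("at least one sex class required")
        for c, p in self.true_p.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"true_p[{c.value}] must lie strictly in (0,1)")
            if self.totals[c] < 1:
                raise ValueError(f"totals[{c.value}] must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimulatedTable:
    """One simulated count table plus the truth that generated it."""

    table: CountTable
    true_p: Mapping[SexClass, float]
    replicate: int

    def true_ratio(self, quantity: str) -> float:
        """Ground-truth RR/OR implied by the generator's probabilities."""
        num, den = {
            "RR_F": (SexClass.NF, SexClass.F),
            "OR_F": (SexClass.NF, SexClass.F),
            "RR_M": (SexClass.NM, SexClass.M),
            "OR_M": (SexClass.NM, SexClass.M),
        }[quantity]
        pn, pd_ = self.true_p[num], self.true_p[den]
        if quantity.startswith("OR"):
            return (pn / (1 - pn)) / (pd_ / (1 - pd_))
        return pn / pd_


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def simulate_count_table(spec: SimulationSpec, replicate: int = 0) -> SimulatedTable:
    """Draw one replicate: cases_i ~ Binomial(total_i, p_i), independently."""
    rng = _replicate_rng(spec.seed, replicate)
    classes = [c for c in CLASS_ORDER if c in spec.true_p]
    cases = {c: int(rng.binomial(spec.totals[c], spec.true_p[c])) for c in classes}
    table = CountTable(
        f"{spec.disease}{replicate:03d}", cases, {c: spec.totals[c] for c in classes}
    )
    return SimulatedTable(table, dict(spec.true_p), replicate)


def simulate_count_tables(spec: SimulationSpec) -> list[SimulatedTable]:
    """All replicates of ``spec`` (replicate k is independently re-creatable)."""
    return [simulate_count_table(spec, k) for k in range(spec.n_replicates)]


def exchangeable_spec(
    rng: np.random.Generator,
    totals: Mapping[SexClass, int] = COHORT_TOTALS,
    base_logit: float = -5.3,
    dev_sd: float = 0.5,
    seed: int = 0,
    disease: str = "SIM",
) -> SimulationSpec:
    """Draw a simulation spec whose class logits are exchangeable.

    Class log-odds are sampled ``Normal(base_logit, dev_sd^2)`` — the same
    exchangeability structure the hierarchical model assumes — which makes
    the design suitable for calibration experiments where credible-interval
    coverage should be nominal when averaged over the truth distribution.
    Defaults put prevalences near 0.5% with the dispersion seen across the
    cohort's sex classes.
    """
    classes = [c for c in CLASS_ORDER if c in totals]
    logits = base_logit + dev_sd * rng.standard_normal(len(classes))
    true_p = {c: float(1.0 / (1.0 + np.exp(-l))) for c, l in zip(classes, logits)}
    return SimulationSpec(true_p, dict(totals), n_replicates=1, seed=seed, disease=disease)


# ---------------------------------------------------------------------------
# record-level simulation


@dataclass(frozen=True)
class RecordSimSpec:
    """Cohort-style record generator settings.

    Defaults mirror the packaged cohort: just over half the dogs female,
    roughly 80%/72% of females/males neutered, neuter ages lognormal with a
    median near 13 months, and a 1995-2010 study window.  Disease incidence
    is a per-class Bernoulli probability (no time-to-event structure — the
    downstream consumer only needs counts and dates around the
    reclassification boundary).  ``prediagnosis_neuter_fraction`` is the
    share of diagnoses in neutered dogs deliberately placed 1-150 days
    before the neuter date, which the status rule must flip back to intact.
    """

    n_dogs: int = 1000
    sex_ratio: float = 0.507
    neuter_probability: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.80, "male": 0.717}
    )
    neuter_age_log_mean: float = float(np.log(13.0))  # months
    neuter_age_log_sd: float = 0.8
    disease_risk: Mapping[str, Mapping[SexClass, float]] = field(
        default_factory=lambda: {"SIMDIS": {c: 0.02 for c in CLASS_ORDER}}
    )
    window: tuple[dt.date, dt.date] = (dt.date(1995, 1, 1), dt.date(2010, 1, 1))
    prediagnosis_neuter_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0,1]")
        for sex, p in self.neuter_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"neuter_probability[{sex}] must lie in [0,1]")
        if not 0.0 <= self.prediagnosis_neuter_fraction <= 1.0:
            raise ValueError("prediagnosis_neuter_fraction must lie in [0,1]")
        if (self.window[1] - self.window[0]).days <= 151:
            raise ValueError(
                "study window must exceed 151 days so pre-neuter diagnoses fit"
            )
        for disease, risks in self.disease_risk.items():
            for c, p in risks.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"disease_risk[{disease}][{c.value}] out of [0,1]")


@dataclass(frozen=True)
class RecordTruth:
    """Generator-side bookkeeping: the post-rule counts the records imply."""

    cases: Mapping[SexClass, int]
    totals: Mapping[SexClass, int]


def simulate_records(
    spec: RecordSimSpec,
) -> tuple[list[PatientRecord], dict[str, RecordTruth]]:
    """Generate dog records plus the ground-truth count table per disease.

    The truth tally applies the study's own accounting: a diagnosed dog is a
    case in its status-at-diagnosis class (intact unless neutered on or
    before the diagnosis date) and contributes its denominator there; an
    undiagnosed dog counts in its final-status class.
    """
    rng = _replicate_rng(spec.seed, 0)
    start, end = spec.window
    window_days = (end - start).days
    diseases = list(spec.disease_risk)

    records: list[PatientRecord] = []
    cases = {d: {c: 0 for c in CLASS_ORDER} for d in diseases}
    totals = {d: {c: 0 for c in CLASS_ORDER} for d in diseases}

    for i in range(spec.n_dogs):
        sex = "female" if rng.random() < spec.sex_ratio else "male"
        neutered = rng.random() < spec.neuter_probability.get(sex, 0.0)
        neuter_date = None
        if neutered:
            # anchor a birth in/around the window, add a lognormal neuter age
            birth = start + dt.timedelta(days=int(rng.integers(-3650, window_days)))
            age_months = rng.lognormal(spec.neuter_age_log_mean, spec.neuter_age_log_sd)
            neuter_date = birth + dt.timedelta(days=int(age_months * 30.44))
            # keep the neuter inside the window, far enough from its start
            # that a 1-150 day pre-neuter diagnosis can also fit inside it
            neuter_date = min(max(neuter_date, start + dt.timedelta(days=151)), end)
        final_cls = SexClass.for_sex(sex, neutered)

        diagnoses: dict[str, dt.date] = {}
        for disease in diseases:
            risk = spec.disease_risk[disease].get(final_cls, 0.0)
            if rng.random() >= risk:
                continue
            if neutered and rng.random() < spec.prediagnosis_neuter_fraction:
                # diagnosis 1-150 days before neutering -> rule flips to intact
                offset = int(rng.integers(1, 151))
                diag = neuter_date - dt.timedelta(days=offset)
                diag = max(diag, start)
            else:
                diag = start + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
            diagnoses[disease] = diag

        records.append(
            PatientRecord(
                id=f"dog{i:05d}",
                sex=sex,
                neutered_ever=neutered,
                neuter_date=neuter_date,
                diagnosis_dates=diagnoses,
            )
        )
        for disease in diseases:
            if disease in diagnoses:
                if neutered and neuter_date <= diagnoses[disease]:
                    cls = final_cls
                else:
                    cls = SexClass.for_sex(sex, neutered=False)
                cases[disease][cls] += 1
                totals[disease][cls] += 1
            else:
                totals[disease][final_cls] += 1

    truth = {
        d: RecordTruth(dict(cases[d]), dict(totals[d])) for d in diseases
    }
    return records, truth
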