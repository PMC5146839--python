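"""End-to-end orchestration: fit every disease, summarize, export.

``run_pipeline`` takes counts (packaged cohort, a counts CSV, or a record
CSV routed through preprocessing), fits the hierarchical model per disease
with deterministically derived per-disease seeds, checks convergence, and
assembles publication-style outputs: a prevalence table, a risk-summary
table (point ± SD with significance markers, NA where a class pair is
missing), caterpillar-plot coordinates, and a structured run log.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_ingest import (
    CLASS_ORDER,
    CountTable,
    SexClass,
    aggregate_records,
    load_cohort_counts,
    read_count_tables,
    read_patient_records,
    tables_to_frame,
)
from .hier_model import ModelConfig, PosteriorDraws, convergence_report, sample_posterior
from .risk_metrics import (
    QUANTITIES,
    PredictedProbability,
    RiskEstimate,
    posterior_ratio,
    predicted_probability,
    prevalence,
)

__all__ = [
    "RunConfig",
    "DiseaseResult",
    "ResultsBundle",
    "ConvergenceError",
    "run_pipeline",
    "fit_disease",
    "disease_seed",
    "prevalence_table",
    "summary_table",
    "caterpillar_table",
    "export_bundle",
    "export_caterpillar",
]

PSRF_THRESHOLD = 1.05


class ConvergenceError(RuntimeError):
    """Raised under strict mode when a disease fails the PSRF adequacy rule."""


@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run.

    Exactly one input source: ``source`` is 'fixture' (packaged cohort),
    'counts' (CSV of per-disease counts) or 'records' (record-level CSV,
    preprocessed to counts first).
    """

    source: str = "fixture"
    path: str | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    outdir: str | None = None
    formats: tuple[str, ...] = ("csv", "json")
    strict: bool = False
    make_plot: bool = True

    def __post_init__(self) -> None:
        if self.source not in ("fixture", "counts", "records"):
            raise ValueError("source must be 'fixture', 'counts' or 'records'")
        if self.source != "fixture" and not self.path:
            raise ValueError(f"source {self.source!r} requires a path")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Build from a YAML mapping; keyword overrides win over file values."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        model_kwargs = raw.pop("model", {})
        model_kwargs.update(overrides.pop("model", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(model=ModelConfig(**model_kwargs), **raw)


@dataclass(frozen=True)
class DiseaseResult:
    disease: str
    table: CountTable
    draws: PosteriorDraws
    psrf: Mapping[str, float]
    converged: bool
    estimates: Mapping[str, RiskEstimate]
    predicted: Mapping[SexClass, PredictedProbability]
    seed: int


@dataclass(frozen=True)
class ResultsBundle:
    results: tuple[DiseaseResult, ...]
    config: RunConfig
    log: Mapping[str, object]

    def result(self, disease: str) -> DiseaseResult:
        for r in self.results:
            if r.disease == disease:
                return r
        raise KeyError(disease)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(r.disease for r in self.results)


def disease_seed(master_seed: int, index: int) -> int:
    """Deterministic per-disease child seed (stable under reruns, < 2^31)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def fit_disease(table: CountTable, model: ModelConfig, seed: int) -> DiseaseResult:
    """Fit one disease and assemble its estimates and diagnostics."""
    config = dataclasses.replace(model, master_seed=seed)
    draws = sample_posterior(table, config)
    psrf = convergence_report(draws)
    converged = all(v < PSRF_THRESHOLD for v in psrf.values())
    estimates = {q: posterior_ratio(draws, q) for q in QUANTITIES}
    predicted = {c: predicted_probability(draws, c) for c in table.classes}
    return DiseaseResult(
        table.disease, table, draws, psrf, converged, estimates, predicted, seed
    )


def _load_tables(config: RunConfig) -> dict[str, CountTable]:
    if config.source == "fixture":
        return load_cohort_counts()
    if config.source == "counts":
        return read_count_tables(config.path)
    records = read_patient_records(config.path)
    diseases = sorted({d for r in records for d in r.diagnosis_dates})
    if not diseases:
        raise ValueError(f"{config.path}: records carry no diagnoses")
    return {d: aggregate_records(records, d) for d in diseases}


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Fit every disease of the configured source and build the report bundle."""
    tables = _load_tables(config)
    if not tables:
        raise ValueError("no diseases to analyze")
    results = []
    for i, (disease, table) in enumerate(tables.items()):
        seed = disease_seed(config.model.master_seed, i)
        results.append(fit_disease(table, config.model, seed))

    failed = [r.disease for r in results if not r.converged]
    log = {
        "master_seed": config.model.master_seed,
        "model": dataclasses.asdict(config.model),
        "n_kept_draws": config.model.n_kept,
        "diseases": {
            r.disease: {
                "seed": r.seed,
                "chain_seeds": list(r.draws.chain_seeds),
                "psrf": dict(r.psrf),
                "accept_rates": dict(r.draws.accept_rates),
                "converged": r.converged,
            }
            for r in results
        },
        "non_converged": failed,
    }
    bundle = ResultsBundle(tuple(results), config, log)
    if config.strict and failed:
        raise ConvergenceError(
            f"PSRF >= {PSRF_THRESHOLD} for: {', '.join(failed)}"
        )
    return bundle


# ---------------------------------------------------------------------------
# tabular summaries


def prevalence_table(tables: Mapping[str, CountTable]) -> pd.DataFrame:
    """Per-class prevalences plus each disease's share of its study denominator.

    The overall percentage divides a disease's cases by the total of its
    *available* classes, which reproduces the female-only denominator
    convention for pyometra.
    """
    rows = []
    for disease, t in tables.items():
        row: dict[str, object] = {"disease": disease}
        for c in CLASS_ORDER:
            row[f"prev_{c.value}"] = (
                prevalence(t.cases[c], t.totals[c]) if c in t.classes else np.nan
            )
        row["percent_of_population"] = round(100.0 * t.n_cases / t.n_total, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(bundle: ResultsBundle) -> pd.DataFrame:
    """Risk-summary analog of the publication table: one row per disease."""
    rows = []
    for r in bundle.results:
        row: dict[str, object] = {"disease": r.disease}
        for q in QUANTITIES:
            est = r.estimates[q]
            row[q] = est.point if est.applicable else np.nan
            row[f"{q}_sd"] = est.sd if est.applicable else np.nan
            row[f"{q}_sig"] = est.significant if est.applicable else None
            row[f"{q}_label"] = str(est)
        row["min_psrf"] = min(r.psrf.values())
        row["max_psrf"] = max(r.psrf.values())
        rows.append(row)
    return pd.DataFrame(rows)


def caterpillar_table(bundle: ResultsBundle) -> pd.DataFrame:
    """Tidy predicted-probability coordinates: one row per (disease, class)."""
    rows = [
        {
            "disease": r.disease,
            "sex_class": c.value,
            "mean": pp.mean,
            "ci_low": pp.ci_low,
            "ci_high": pp.ci_high,
        }
        for r in bundle.results
        for c, pp in r.predicted.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exports


def export_caterpillar(bundle: ResultsBundle, outdir) -> tuple[pd.DataFrame, Path]:
    """Write the tidy caterpillar table and a rendered point-interval figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = caterpillar_table(bundle)
    df.to_csv(outdir / "caterpillar.csv", index=False)

    diseases = list(bundle.diseases)
    offsets = {c.value: k for k, c in enumerate(CLASS_ORDER)}
    colors = {"F": "#c0392b", "NF": "#e67e22", "M": "#2980b9", "NM": "#27ae60"}
    fig, ax = plt.subplots(figsize=(7, 0.55 * len(diseases) + 1.5))
    for cls, sub in df.groupby("sex_class"):
        y = [diseases.index(d) + 0.18 * (offsets[cls] - 1.5) for d in sub["disease"]]
        mean = sub["mean"].to_numpy()
        ax.errorbar(
            mean, y,
            xerr=[mean - sub["ci_low"].to_numpy(), sub["ci_high"].to_numpy() - mean],
            fmt="o", ms=3, lw=1, capsize=1.5, label=cls, color=colors[cls],
        )
    ax.set_yticks(range(len(diseases)))
    ax.set_yticklabels(diseases)
    ax.invert_yaxis()
    ax.set_xlabel("predicted probability of disease (mean, 95% CI)")
    ax.legend(title="sex class", fontsize=8)
    fig.tight_layout()
    figpath = outdir / "caterpillar.png"
    fig.savefig(figpath, dpi=150)
    plt.close(fig)
    return df, figpath


def export_bundle(bundle: ResultsBundle, outdir) -> dict[str, Path]:
    """Write counts, draws, estimates, summaries and the run log to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    tables = {r.disease: r.table for r in bundle.results}
    counts = tables_to_frame(tables.values())
    written["counts"] = outdir / "counts.csv"
    counts.to_csv(written["counts"], index=False)

    written["prevalence"] = outdir / "prevalence.csv"
    prevalence_table(tables).to_csv(written["prevalence"], index=False)

    summary = summary_table(bundle)
    if "csv" in bundle.config.formats:
        written["summary"] = outdir / "summary.csv"
        summary.to_csv(written["summary"], index=False)

    est_rows = [
        {
            "disease": r.disease,
            "quantity": q,
            "point": est.point,
            "sd": est.sd,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "significant": est.significant if est.applicable else None,
            "n_draws": est.n_draws,
            "applicable": est.applicable,
        }
        for r in bundle.results
        for q, est in r.estimates.items()
    ]
    est_df = pd.DataFrame(est_rows)
    written["estimates_csv"] = outdir / "estimates.csv"
    est_df.to_csv(written["estimates_csv"], index=False)
    if "json" in bundle.config.formats:
        written["estimates_json"] = outdir / "estimates.json"
        est_df.to_json(written["estimates_json"], orient="records", indent=1)

    draws_dir = outdir / "draws"
    draws_dir.mkdir(exist_ok=True)
    for r in bundle.results:
        p = draws_dir / f"{r.disease}.csv"
        r.draws.to_frame().to_csv(p, index=False)
        written[f"draws_{r.disease}"] = p

    written["log"] = outdir / "run_log.json"
    with open(written["log"], "w", encoding="utf-8") as fh:
        json.dump(bundle.log, fh, indent=1)

    if bundle.config.make_plot:
        _, figpath = export_caterpillar(bundle, outdir)
        written["caterpillar"] = figpath
    return written
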