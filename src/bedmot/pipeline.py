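"""End-to-end analysis orchestration: score -> group -> test -> tabulate.

For each motivational question (therapy aims / why online) and each age
stratum, patient statements are polarity-scored, grouped by SDT
motivation level, and pushed through the ordinal inference chain
(Jonckheere-Terpstra trend + Brown-Forsythe homoscedasticity + Kendall
tau-b with the dual effect-size rule).  Sentiment-vs-outcome rank
correlations and the time-by-group mixed ANOVAs complete the grids.

The output bundle mirrors the study's table shapes: a trend grid, a
correlation grid, an ANOVA grid, the completion-frequency table and a
descriptives block, plus run metadata with every warning encountered.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .instruments import (
    MOTIVATION_INDEX,
    PatientRecord,
    ValidationError,
    completion_table,
    descriptives,
    read_cohort,
)
from .lexicon import Lexicon, load_lexicon_dir
from .ordinal_stats import (
    StatError,
    brown_forsythe,
    composite_decision,
    jonckheere_terpstra,
    kendall_tau_b,
    mixed_anova,
    normality_check,
)
from .sentiment import POOLING_METHODS, score_document

logger = logging.getLogger(__name__)

QUESTIONS = ("therapy_aims", "why_online")
STRATA = ("all", "adult", "young_adult")
VARIABLES = (
    "polarity", "bedq_pre", "edeq_pre", "bmi_pre", "mdi_pre", "vas_pre",
    "completion_rate", "bedq_diff", "edeq_diff",
)
#: variables correlated against polarity in the outcome grid
CORRELATION_VARIABLES = ("bedq_pre", "edeq_pre", "completion_rate", "bedq_diff", "edeq_diff")
ANOVA_OUTCOMES = ("bedq", "edeq", "mdi", "vas")

TREND_COLUMNS = [
    "variable", "question", "age_group", "n", "T_JT", "p_TJT", "F_BF", "p_FBF",
    "tau_b", "ci_low", "ci_high", "stars", "overall", "degenerate_reason",
]
CORRELATION_COLUMNS = ["variable", "question", "age_group", "n", "tau_b", "ci_low", "ci_high"]
ANOVA_COLUMNS = ["question", "outcome", "numDF", "denDF", "F", "p", "degenerate_reason"]


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    """Knobs of one analysis run."""

    pooling: str = "gmean"
    questions: tuple[str, ...] = QUESTIONS
    strata: tuple[str, ...] = STRATA
    variables: tuple[str, ...] = VARIABLES
    alpha: float = 0.05
    rmpe: float = 0.2
    bootstrap_B: int = 2000
    n_perm: int = 10_000
    jt_method: str = "normal_approx"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pooling not in POOLING_METHODS:
            raise ConfigError(f"pooling must be one of {POOLING_METHODS}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.rmpe <= 0:
            raise ConfigError("rmpe must be > 0")
        for name, allowed, got in (
            ("questions", QUESTIONS, self.questions),
            ("strata", STRATA, self.strata),
            ("variables", VARIABLES, self.variables),
        ):
            got = tuple(got)
            if not got:
                raise ConfigError(f"{name} selection must be nonempty")
            unknown = set(got) - set(allowed)
            if unknown:
                raise ConfigError(f"unknown {name}: {sorted(unknown)}")
            setattr(self, name, got)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ResultsBundle:
    """All grids plus run metadata from one pipeline execution."""

    trend_grid: pd.DataFrame
    correlation_grid: pd.DataFrame
    anova_grid: pd.DataFrame
    completion: pd.DataFrame
    descriptives: dict
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "trend_grid": self.trend_grid.to_dict(orient="records"),
            "correlation_grid": self.correlation_grid.to_dict(orient="records"),
            "anova_grid": self.anova_grid.to_dict(orient="records"),
            "completion": self.completion.to_dict(orient="records"),
            "descriptives": self.descriptives,
            "metadata": self.metadata,
        }


def _cell_seed(base_seed: int, *parts: str) -> int:
    """Stable per-cell seed below 2^31, independent of iteration order."""
    tag = zlib.crc32("|".join(parts).encode())
    return int((base_seed * 1_000_003 + tag) % (2 ** 31))


def _stratum_records(records: Sequence[PatientRecord], stratum: str) -> list[PatientRecord]:
    if stratum == "all":
        return list(records)
    return [r for r in records if r.age_group == stratum]


def _motivation_code(rec: PatientRecord, question: str) -> int:
    label = rec.motivation_aims if question == "therapy_aims" else rec.motivation_online
    return MOTIVATION_INDEX[label]


def _variable_value(rec: PatientRecord, variable: str, polarity: dict) -> float | None:
    if variable == "polarity":
        return polarity[rec.id]
    if variable == "bmi_pre":
        return rec.bmi
    if variable == "completion_rate":
        return float(int(rec.completion))
    if variable == "bedq_diff":
        if rec.bedq_pre is None or rec.bedq_post is None:
            return None
        return float(rec.bedq_post - rec.bedq_pre)
    if variable == "edeq_diff":
        if rec.edeq_pre is None or rec.edeq_post is None:
            return None
        return float(rec.edeq_post - rec.edeq_pre)
    value = getattr(rec, variable)
    return None if value is None else float(value)


def run_analysis(
    cohort: str | Path | Sequence[PatientRecord],
    lexicon: str | Path | Lexicon,
    config: AnalysisConfig | None = None,
) -> ResultsBundle:
    """Run the full analysis and return a :class:`ResultsBundle`.

    ``cohort`` may be a CSV path or a sequence of records; ``lexicon`` a
    directory (three-TSV layout) or a loaded :class:`Lexicon`.  The run
    is deterministic per (cohort, lexicon, config, seed): every
    stochastic step derives its seed from the config seed and the cell
    identity.  Degenerate cells (e.g. an empty stratum-level
    combination) are reported with a reason; the run continues.
    """
    config = config or AnalysisConfig()
    if not isinstance(lexicon, Lexicon):
        lexicon = load_lexicon_dir(lexicon)
    records = list(cohort) if not isinstance(cohort, (str, Path)) else read_cohort(cohort)
    if not records:
        raise ValidationError("cohort is empty")

    warnings: list[str] = []
    logger.info("seed=%d", config.seed)
    logger.info("analysing cohort of %d records", len(records))

    # per-question polarity per patient
    polarity: dict[str, dict[str, float]] = {}
    for question in QUESTIONS:
        attr = "therapy_aims_text" if question == "therapy_aims" else "why_online_text"
        polarity[question] = {
            r.id: score_document(getattr(r, attr), lexicon, config.pooling).value
            for r in records
        }

    n_missing_post = sum(1 for r in records if r.bedq_post is None)
    if n_missing_post:
        warnings.append(f"{n_missing_post} records lack post-treatment scores (dropped pairwise)")

    trend_rows = []
    normality_notes = []
    for question in config.questions:
        for stratum in config.strata:
            subset = _stratum_records(records, stratum)
            for variable in config.variables:
                trend_rows.append(
                    _trend_cell(subset, question, stratum, variable,
                                polarity[question], config, warnings, normality_notes)
                )

    corr_rows = []
    for question in config.questions:
        for stratum in config.strata:
            subset = _stratum_records(records, stratum)
            for variable in CORRELATION_VARIABLES:
                corr_rows.append(
                    _correlation_cell(subset, question, stratum, variable,
                                      polarity[question], config, warnings)
                )

    anova_rows = []
    for question in config.questions:
        for outcome in ANOVA_OUTCOMES:
            anova_rows.append(_anova_cell(records, question, outcome, warnings))

    bundle = ResultsBundle(
        trend_grid=pd.DataFrame(trend_rows, columns=TREND_COLUMNS),
        correlation_grid=pd.DataFrame(corr_rows, columns=CORRELATION_COLUMNS),
        anova_grid=pd.DataFrame(anova_rows, columns=ANOVA_COLUMNS),
        completion=completion_table(records),
        descriptives=descriptives(records),
        metadata={
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "pooling": "partitioned_signed_gmean" if config.pooling == "gmean" else config.pooling,
            "n_records": len(records),
            "bedmot_version": __version__,
            "family_size": len(trend_rows) + len(corr_rows) + len(anova_rows),
            "raw_p_values": True,  # no multiple-testing correction applied
            "warnings": warnings,
            "normality": normality_notes,
        },
    )
    for w in warnings:
        logger.warning("%s", w)
    return bundle


def _trend_cell(subset, question, stratum, variable, pol, config, warnings, normality_notes):
    row = {
        "variable": variable, "question": question, "age_group": stratum,
        "n": 0, "T_JT": np.nan, "p_TJT": np.nan, "F_BF": np.nan, "p_FBF": np.nan,
        "tau_b": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "stars": 0, "overall": False, "degenerate_reason": "",
    }
    pairs = [
        (_variable_value(r, variable, pol), _motivation_code(r, question))
        for r in subset
    ]
    pairs = [(v, c) for v, c in pairs if v is not None and not np.isnan(v)]
    if not pairs:
        row["degenerate_reason"] = "no observations in cell"
        warnings.append(f"degenerate cell {variable}/{question}/{stratum}: no observations")
        return row
    values = np.array([v for v, _ in pairs])
    codes = np.array([c for _, c in pairs])
    row["n"] = len(values)

    levels = sorted(set(codes))
    groups = [values[codes == lvl] for lvl in levels]
    if len(groups) < 2:
        row["degenerate_reason"] = "fewer than 2 motivation levels present"
        warnings.append(f"degenerate cell {variable}/{question}/{stratum}: single level")
        return row

    seed = _cell_seed(config.seed, question, stratum, variable)
    trend = jonckheere_terpstra(groups, method=config.jt_method,
                                n_perm=config.n_perm, seed=seed)
    row["T_JT"], row["p_TJT"] = trend.z, trend.p
    try:
        var_test = brown_forsythe(groups)
        row["F_BF"], row["p_FBF"] = var_test.F, var_test.p
    except StatError as exc:
        var_test = None
        row["degenerate_reason"] = f"variance test: {exc}"
        warnings.append(f"cell {variable}/{question}/{stratum}: {exc}")
    tau = kendall_tau_b(values, codes, B=config.bootstrap_B, seed=seed)
    if not tau.degenerate:
        row["tau_b"], row["ci_low"], row["ci_high"] = tau.tau_b, tau.ci_low, tau.ci_high
    if var_test is not None:
        verdict = composite_decision(trend, var_test, tau,
                                     alpha=config.alpha, rmpe=config.rmpe)
        row["stars"], row["overall"] = verdict.stars, verdict.overall
        if tau.degenerate:
            row["degenerate_reason"] = tau.reason or "degenerate tau"

    try:
        _, p_norm, _ = normality_check(values)
        normality_notes.append({
            "variable": variable, "question": question, "age_group": stratum,
            "shapiro_p": p_norm,
        })
    except StatError as exc:
        normality_notes.append({
            "variable": variable, "question": question, "age_group": stratum,
            "shapiro_p": None, "note": str(exc),
        })
    return row


def _correlation_cell(subset, question, stratum, variable, pol, config, warnings):
    row = {
        "variable": variable, "question": question, "age_group": stratum,
        "n": 0, "tau_b": np.nan, "ci_low": np.nan, "ci_high": np.nan,
    }
    pairs = [
        (pol[r.id], _variable_value(r, variable, pol)) for r in subset
    ]
    pairs = [(p, v) for p, v in pairs if v is not None and not np.isnan(v)]
    if len(pairs) < 3:
        warnings.append(
            f"correlation cell {variable}/{question}/{stratum}: fewer than 3 pairs")
        return row
    x = np.array([p for p, _ in pairs])
    y = np.array([v for _, v in pairs])
    seed = _cell_seed(config.seed, "corr", question, stratum, variable)
    tau = kendall_tau_b(x, y, B=config.bootstrap_B, seed=seed)
    row["n"] = len(pairs)
    if tau.degenerate:
        warnings.append(f"correlation cell {variable}/{question}/{stratum}: {tau.reason}")
        return row
    row["tau_b"], row["ci_low"], row["ci_high"] = tau.tau_b, tau.ci_low, tau.ci_high
    return row


def _anova_cell(records, question, outcome, warnings):
    row = {"question": question, "outcome": outcome,
           "numDF": 0, "denDF": 0, "F": np.nan, "p": np.nan, "degenerate_reason": ""}
    pre_attr, post_attr = f"{outcome}_pre", f"{outcome}_post"
    triples = [
        (getattr(r, pre_attr), getattr(r, post_attr), _motivation_code(r, question))
        for r in records
    ]
    triples = [(a, b, g) for a, b, g in triples if a is not None and b is not None]
    if not triples:
        row["degenerate_reason"] = "no complete pre/post pairs"
        warnings.append(f"ANOVA {outcome}/{question}: no complete pairs")
        return row
    pre = np.array([a for a, _, _ in triples], dtype=float)
    post = np.array([b for _, b, _ in triples], dtype=float)
    grp = np.array([g for _, _, g in triples])
    # drop levels too small to contribute a within-group variance
    keep_levels = [lvl for lvl in np.unique(grp) if np.sum(grp == lvl) >= 2]
    dropped = set(np.unique(grp)) - set(keep_levels)
    if dropped:
        warnings.append(
            f"ANOVA {outcome}/{question}: dropped levels {sorted(int(d) for d in dropped)} "
            "with < 2 complete pairs")
    mask = np.isin(grp, keep_levels)
    if len(keep_levels) < 2:
        row["degenerate_reason"] = "fewer than 2 usable motivation levels"
        warnings.append(f"ANOVA {outcome}/{question}: fewer than 2 usable levels")
        return row
    res = mixed_anova(pre[mask], post[mask], grp[mask])
    row.update({"numDF": res.numDF, "denDF": res.denDF, "F": res.F, "p": res.p})
    return row


def format_p(p: float) -> str:
    """p-value formatting for the CSV grids: scientific below 1e-3."""
    if p != p:  # NaN
        return ""
    if 0 < p < 1e-3:
        return f"{p:.1e}"
    return f"{p:.2f}"


def _format_grid(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col.startswith("p_") or col == "p":
            out[col] = out[col].map(format_p)
        elif out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if v != v else f"{v:.2f}")
    return out


def write_bundle(
    bundle: ResultsBundle,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "json"),
) -> dict[str, Path]:
    """Write the bundle as CSV grids, a JSON bundle, and a run log."""
    unknown = set(formats) - {"csv", "json"}
    if unknown:
        raise ConfigError(f"unknown output formats: {sorted(unknown)}")
    if not formats:
        raise ConfigError("at least one output format is required")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: dict[str, Path] = {}
    if "csv" in formats:
        for name, df in (
            ("trend_grid", bundle.trend_grid),
            ("correlation_grid", bundle.correlation_grid),
            ("anova_grid", bundle.anova_grid),
            ("completion", bundle.completion),
        ):
            path = out_dir / f"{name}.csv"
            _format_grid(df).to_csv(path, index=False)
            written[name] = path
    if "json" in formats:
        path = out_dir / "bundle.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(bundle.to_json_dict(), fh, indent=1, default=_json_default)
        written["bundle"] = path

    log_path = out_dir / "run.log"
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write(f"seed: {bundle.metadata.get('seed')}\n")
        fh.write(f"bedmot version: {bundle.metadata.get('bedmot_version')}\n")
        fh.write(f"records: {bundle.metadata.get('n_records')}\n")
        fh.write(f"pooling: {bundle.metadata.get('pooling')}\n")
        for w in bundle.metadata.get("warnings", []):
            fh.write(f"warning: {w}\n")
    written["log"] = log_path
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
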