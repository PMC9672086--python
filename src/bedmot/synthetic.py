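"""Synthetic cohort, lexicon and free-text generator.

The real patient data behind this analysis (free-text treatment
motivation statements plus questionnaire outcomes) are not shareable, so
this module emits cohorts with the statistical structure the analysis
assumes, making every pipeline stage testable end to end:

* two ordinal motivation labels per patient on the 4-level SDT scale,
  with label distributions defaulting to the study's printed counts
  (therapy aims 0/50/50/48 of 148; why-online 31/21/81/15 of 148);
* free-text statements whose scored polarity rises with motivation level
  (the default link is calibrated so the population tau-b between gmean
  polarity and therapy-aims level is about 0.31);
* pre/post instrument outcomes with a treatment effect but, by default,
  no motivation-type effect (the study's null);
* programme adherence with a young-adult-only negative link to
  why-online polarity.

Everything is deterministic per seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .instruments import (
    MOTIVATION_LEVELS,
    PatientRecord,
    age_group_for,
    write_cohort,
)
from .lexicon import Lexicon, save_lexicon
from .sentiment import score_document

#: default latent-polarity increment per motivation level; calibrated so the
#: population tau-b between gmean-pooled polarity and therapy-aims level
#: is ~0.31 under the default text-generation settings (see
#: :func:`calibrate_polarity_link`).
DEFAULT_POLARITY_LINK = 0.61

_VOWELS = "aeiouyæøå"
_CONSONANTS = "bdfghjklmnprstv"


class GeneratorError(ValueError):
    """Invalid generator configuration."""


def _norm_probs(v) -> tuple[float, ...]:
    arr = np.asarray(v, dtype=float)
    s = arr.sum()
    if s <= 0:
        raise GeneratorError("probability vector must have positive mass")
    return tuple(arr / s)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study conditions: n = 148 with 19 young
    adults, motivation label counts per the printed distributions, a
    polarity-motivation link targeting tau-b ~ 0.31, a treatment effect
    on every instrument, no motivation effect on outcomes, and a
    negative young-adult polarity-adherence link.
    """

    n: int = 148
    young_fraction: float = 19 / 148
    motivation_probs_aims: tuple[float, ...] = (0, 50, 50, 48)
    motivation_probs_online: tuple[float, ...] = (31, 21, 81, 15)
    polarity_baseline: float = -1.0
    polarity_link: float = DEFAULT_POLARITY_LINK
    polarity_noise_sd: float = 1.0
    tokens_per_statement: int = 20
    filler_rate: float = 0.3
    negation_rate: float = 0.1
    male_fraction: float = 17 / 148
    outcome_pre_params: dict = field(default_factory=lambda: {
        # instrument: (mean, sd, low, high) — truncated-normal pre scores.
        # BED-Q pre sits in the mild-moderate bands (eligible range),
        # MDI respects the >40 exclusion, dispersions chosen for
        # testability (the study prints only the MDI mean of 23).
        "bedq": (16.0, 3.0, 10, 21),
        "edeq": (3.5, 1.0, 0.0, 6.0),
        "mdi": (23.0, 8.0, 2, 40),
        "vas": (50.0, 15.0, 5, 95),
    })
    treatment_effect: dict = field(default_factory=lambda: {
        # mean pre-to-post improvement; VAS improves upward hence negative
        "bedq": 4.0, "edeq": 0.8, "mdi": 4.0, "vas": -8.0,
    })
    post_noise_sd: dict = field(default_factory=lambda: {
        "bedq": 3.0, "edeq": 0.8, "mdi": 5.0, "vas": 10.0,
    })
    motivation_outcome_effect: float = 0.0
    young_adherence_link: float = -0.5
    missing_post_rate: float = 0.2
    bmi_params: tuple[float, float, float, float] = (37.5, 6.0, 21.5, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise GeneratorError("cohort size must be >= 4")
        if not 0 <= self.young_fraction <= 1:
            raise GeneratorError("young_fraction must lie in [0, 1]")
        if self.polarity_noise_sd <= 0:
            raise GeneratorError("polarity_noise_sd must be > 0")
        if len(self.motivation_probs_aims) != 4 or len(self.motivation_probs_online) != 4:
            raise GeneratorError("motivation probability vectors need 4 entries")
        self.motivation_probs_aims = _norm_probs(self.motivation_probs_aims)
        self.motivation_probs_online = _norm_probs(self.motivation_probs_online)
        for name, (mean, sd, lo, hi) in self.outcome_pre_params.items():
            if sd <= 0 or lo >= hi:
                raise GeneratorError(f"bad pre-score parameters for {name}")
        # eligibility must be satisfiable by construction
        b_lo = self.outcome_pre_params["bedq"][2]
        m_lo = self.outcome_pre_params["mdi"][2]
        if b_lo >= 22 or m_lo > 40:
            raise GeneratorError("pre-score ranges violate the eligibility rules")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GeneratorError(f"unknown config keys: {sorted(unknown)}")
        for key in ("motivation_probs_aims", "motivation_probs_online", "bmi_params"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pseudo_words(rng: np.random.Generator, count: int, taken: set[str]) -> list[str]:
    """Deterministic pronounceable nonsense words, unique and not in ``taken``."""
    words = []
    while len(words) < count:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syll)
        )
        if word not in taken:
            taken.add(word)
            words.append(word)
    return words


def generate_lexicon(
    seed: int,
    n_valence: int = 240,
    n_modifiers: int = 12,
    n_negators: int = 6,
    out_dir: str | Path | None = None,
) -> Lexicon:
    """Deterministic synthetic lexicon with valences gridded over [-5, 5].

    Valence tokens, modifiers and negators are disjoint word classes so
    the realized polarity of generated statements stays controllable.
    If ``out_dir`` is given the three TSV files are written there.
    """
    if n_valence < 2:
        raise GeneratorError("need at least 2 valence tokens")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    valence_words = _pseudo_words(rng, n_valence, taken)
    modifier_words = _pseudo_words(rng, n_modifiers, taken)
    negator_words = _pseudo_words(rng, n_negators, taken)
    grid = np.round(np.linspace(-5.0, 5.0, n_valence), 4)
    lex = Lexicon(
        valences=dict(zip(valence_words, grid.tolist())),
        modifiers={w: round(f, 2) for w, f in zip(
            modifier_words, np.linspace(0.5, 2.0, n_modifiers)
        )},
        negators=set(negator_words),
    )
    if out_dir is not None:
        save_lexicon(lex, out_dir)
    return lex


class _StatementSampler:
    """Caches the lexicon layout needed for fast statement sampling."""

    def __init__(self, lexicon: Lexicon):
        if not lexicon.valences:
            raise GeneratorError("cannot generate statements from an empty lexicon")
        items = sorted(lexicon.valences.items(), key=lambda kv: (kv[1], kv[0]))
        self.tokens = [t for t, _ in items]
        self.valences = np.array([v for _, v in items])
        self.negators = sorted(lexicon.negators)
        self.window = lexicon.negation_window

    def nearest(self, value: float) -> str:
        return self.tokens[int(np.argmin(np.abs(self.valences - value)))]


def generate_statement(
    latent_polarity: float,
    lexicon: Lexicon | _StatementSampler,
    rng: np.random.Generator,
    tokens_per_statement: int = 20,
    filler_rate: float = 0.3,
    negation_rate: float = 0.1,
    token_spread: float = 1.5,
    fillers: list[str] | None = None,
) -> str:
    """One synthetic free-text answer with scored polarity ~ ``latent_polarity``.

    Valence-bearing tokens are drawn with target values Normal(latent,
    ``token_spread``) and quantized to the nearest lexicon token; fillers
    (words absent from the lexicon) appear at ``filler_rate``; at
    ``negation_rate`` a negator is emitted followed by the token nearest
    the *negated* target, so the rule engine's sign flip restores the
    intended contribution.  After a negated token, fillers pad out the
    negation window so the flip never bleeds into later tokens.
    No fluency is attempted — the text exists to carry a polarity signal.
    """
    sampler = lexicon if isinstance(lexicon, _StatementSampler) else _StatementSampler(lexicon)
    if fillers is None:
        # q/x/z never occur in generated lexicon words, so these can
        # never collide with a valence-bearing token
        fillers = ["zaq", "xebo", "quzi", "zyxa", "qomi", "xul", "zeq", "xaqo"]
    words: list[str] = []
    guard = 0  # fillers still owed to pad a negation window
    emitted = 0
    while emitted < tokens_per_statement:
        if guard > 0:
            words.append(fillers[int(rng.integers(len(fillers)))])
            guard -= 1
            emitted += 1
            continue
        if rng.random() < filler_rate:
            words.append(fillers[int(rng.integers(len(fillers)))])
            emitted += 1
            continue
        target = float(np.clip(rng.normal(latent_polarity, token_spread), -5.0, 5.0))
        if sampler.negators and rng.random() < negation_rate:
            words.append(sampler.negators[int(rng.integers(len(sampler.negators)))])
            words.append(sampler.nearest(-target))
            guard = max(sampler.window - 1, 0)
            emitted += 1
        else:
            words.append(sampler.nearest(target))
            emitted += 1
    # plain declarative sentences of ~8 words; no '?' or '!' so the
    # interrogative and exclamation rules stay inert on generated text
    sentences = [" ".join(words[i:i + 8]) for i in range(0, len(words), 8)]
    return ". ".join(s.capitalize() for s in sentences) + "."


@dataclass
class GroundTruth:
    """Latent quantities aligned one-to-one with the emitted records."""

    level_aims: list[int]
    level_online: list[int]
    latent_polarity_aims: list[float]
    latent_polarity_online: list[float]
    adherence_propensity: list[float]
    notes: str = (
        "outcome dispersions are chosen for testability, not fidelity; "
        "the source study prints only the MDI mean and score ranges"
    )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# cohort completion mass targets: Low ~ 36.7%, High ~ 38.1%, Full ~ 25.2%
_P_LOW, _P_HIGH = 0.367, 0.381


def generate_cohort(
    config: GeneratorConfig,
    lexicon: Lexicon | None = None,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a full synthetic cohort (records + ground truth).

    If no lexicon is passed, one is generated from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if lexicon is None:
        lexicon = generate_lexicon(config.seed)
    sampler = _StatementSampler(lexicon)
    n = config.n
    n_young = int(round(config.young_fraction * n))

    young = np.zeros(n, dtype=bool)
    young[rng.choice(n, size=n_young, replace=False)] = True
    age = np.where(
        young,
        rng.uniform(18.0, 25.0, n),
        _truncnorm(rng, 42.0, 12.0, 25.0, 68.0, n),
    )
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    bmi = _truncnorm(rng, *config.bmi_params, size=n)

    lvl_aims = rng.choice(4, size=n, p=config.motivation_probs_aims)
    lvl_online = rng.choice(4, size=n, p=config.motivation_probs_online)

    def latent(levels):
        return np.clip(
            config.polarity_baseline
            + config.polarity_link * levels
            + rng.normal(0.0, config.polarity_noise_sd, n),
            -4.8, 4.8,
        )

    lat_aims = latent(lvl_aims)
    lat_online = latent(lvl_online)

    texts_aims = [
        generate_statement(
            lat_aims[i], sampler, rng,
            tokens_per_statement=config.tokens_per_statement,
            filler_rate=config.filler_rate,
            negation_rate=config.negation_rate,
        )
        for i in range(n)
    ]
    texts_online = [
        generate_statement(
            lat_online[i], sampler, rng,
            tokens_per_statement=config.tokens_per_statement,
            filler_rate=config.filler_rate,
            negation_rate=config.negation_rate,
        )
        for i in range(n)
    ]

    # adherence: standard-normal propensity, shifted for young adults by
    # the (standardized) why-online latent polarity times the link
    z_pol = (lat_online - lat_online.mean()) / max(lat_online.std(), 1e-9)
    eps = rng.normal(0.0, 1.0, n)
    link = np.where(young, config.young_adherence_link, 0.0)
    propensity = eps + link * z_pol
    u = stats.norm.cdf(propensity / np.sqrt(1.0 + link ** 2))
    sessions = np.empty(n, dtype=int)
    low_mask = u < _P_LOW
    high_mask = (u >= _P_LOW) & (u < _P_LOW + _P_HIGH)
    full_mask = ~(low_mask | high_mask)
    sessions[low_mask] = rng.integers(0, 6, int(low_mask.sum()))
    sessions[high_mask] = rng.integers(6, 10, int(high_mask.sum()))
    sessions[full_mask] = 10
    followup = np.where(sessions == 10, rng.random(n) < 0.85, False)

    pre: dict[str, np.ndarray] = {}
    post: dict[str, np.ndarray] = {}
    for inst, (mean, sd, lo, hi) in config.outcome_pre_params.items():
        pre_vals = _truncnorm(rng, mean, sd, lo, hi, n)
        shift = (
            config.treatment_effect[inst]
            - config.motivation_outcome_effect * lvl_aims
        )
        post_vals = pre_vals - shift + rng.normal(0.0, config.post_noise_sd[inst], n)
        full_lo, full_hi = _INSTRUMENT_RANGE[inst]
        post_vals = np.clip(post_vals, full_lo, full_hi)
        if inst != "edeq":
            pre_vals = np.round(pre_vals)
            post_vals = np.round(post_vals)
        pre[inst], post[inst] = pre_vals, post_vals

    # post scores go missing mostly for low completers (early drop-outs)
    missing_post = (sessions < 6) & (rng.random(n) < config.missing_post_rate)

    records: list[PatientRecord] = []
    for i in range(n):
        def _post(inst, cast):
            return None if missing_post[i] else cast(post[inst][i])

        records.append(PatientRecord(
            id=f"S{i + 1:03d}",
            age=round(float(age[i]), 1),
            sex=str(sex[i]),
            bmi=round(float(bmi[i]), 1),
            age_group=age_group_for(float(age[i])),
            motivation_aims=MOTIVATION_LEVELS[lvl_aims[i]],
            motivation_online=MOTIVATION_LEVELS[lvl_online[i]],
            therapy_aims_text=texts_aims[i],
            why_online_text=texts_online[i],
            sessions_completed=int(sessions[i]),
            followup_done=bool(followup[i]),
            bedq_pre=int(pre["bedq"][i]),
            bedq_post=_post("bedq", int),
            edeq_pre=float(round(pre["edeq"][i], 2)),
            edeq_post=None if missing_post[i] else float(round(post["edeq"][i], 2)),
            mdi_pre=int(pre["mdi"][i]),
            mdi_post=_post("mdi", int),
            vas_pre=int(pre["vas"][i]),
            vas_post=_post("vas", int),
        ))

    truth = GroundTruth(
        level_aims=[int(v) for v in lvl_aims],
        level_online=[int(v) for v in lvl_online],
        latent_polarity_aims=[float(v) for v in lat_aims],
        latent_polarity_online=[float(v) for v in lat_online],
        adherence_propensity=[float(v) for v in propensity],
    )
    return records, truth


_INSTRUMENT_RANGE = {
    "bedq": (0, 35),
    "edeq": (0.0, 12.0),
    "mdi": (0, 50),
    "vas": (0, 100),
}


def write_simulation(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit cohort.csv, lexicon/ TSVs, groundtruth.json and a config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lexicon = generate_lexicon(config.seed, out_dir=out_dir / "lexicon")
    records, truth = generate_cohort(config, lexicon=lexicon)
    cohort_path = out_dir / "cohort.csv"
    write_cohort(records, cohort_path)
    truth.to_json(out_dir / "groundtruth.json")
    with open(out_dir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=1)
    return {
        "cohort": cohort_path,
        "lexicon": out_dir / "lexicon",
        "groundtruth": out_dir / "groundtruth.json",
        "config": out_dir / "config.json",
    }


def calibrate_polarity_link(
    target_tau: float = 0.31,
    config: GeneratorConfig | None = None,
    n_probe: int = 4000,
    seed: int = 0,
    tol: float = 0.005,
) -> float:
    """Find the polarity link giving population tau-b ~ ``target_tau``.

    Bisects the latent link: for each candidate, a large probe sample of
    (therapy-aims level, gmean-scored statement polarity) pairs is drawn
    and tau-b measured.  tau is monotone in the link, so bisection over
    [0, 3] converges; the probe size keeps Monte-Carlo error on tau well
    below ``tol``.
    """
    from scipy.stats import kendalltau

    base = config or GeneratorConfig()
    lexicon = generate_lexicon(seed)
    sampler = _StatementSampler(lexicon)

    def population_tau(link: float) -> float:
        rng = np.random.default_rng(seed)
        levels = rng.choice(4, size=n_probe, p=base.motivation_probs_aims)
        lat = np.clip(
            base.polarity_baseline + link * levels
            + rng.normal(0.0, base.polarity_noise_sd, n_probe),
            -4.8, 4.8,
        )
        scores = [
            score_document(
                generate_statement(
                    lat[i], sampler, rng,
                    tokens_per_statement=base.tokens_per_statement,
                    filler_rate=base.filler_rate,
                    negation_rate=base.negation_rate,
                ),
                lexicon, "gmean",
            ).value
            for i in range(n_probe)
        ]
        return float(kendalltau(scores, levels, variant="b").statistic)

    lo, hi = 0.0, 3.0
    for _ in range(20):
        mid = (lo + hi) / 2.0
        tau = population_tau(mid)
        if abs(tau - target_tau) < tol:
            return mid
        if tau < target_tau:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
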