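"""Ordinal inference chain for motivation-type groupings.

The self-determination-theory motivation types form an ordered sequence
(external < introjection < identification < integration), so group
differences are tested with ordered-alternative and rank-association
methods rather than plain ANOVA:

* :func:`jonckheere_terpstra` — signed trend test over ordered groups,
  built from pairwise Mann-Whitney counts, with tie-corrected normal
  approximation or (exhaustive) permutation p-values.
* :func:`brown_forsythe` — homoscedasticity test on absolute deviations
  from group medians; when variances are similar the mean-rank ordering
  statement extends to group medians.
* :func:`kendall_tau_b` — tie-aware rank correlation as effect size,
  with a seeded percentile-bootstrap confidence interval.
* :func:`effect_size_verdict` — the dual effect-size rule: |tau| must
  exceed the recommended minimal practical effect size (RMPE, 0.2) and
  the 95% CI must not span both -RMPE and +RMPE (the inverse-significance
  guard).
* :func:`composite_decision` — a grouping counts as significant only if
  it passes both the stochastic-dominance test and the effect-size rule.
* :func:`mixed_anova` — two-way mixed ANOVA (time within, group between)
  for pre/post outcomes; the time-by-group interaction is the motivation
  effect on treatment outcome.
* :func:`normality_check` — Shapiro-Wilk with detrended QQ deviations,
  reported alongside the main results, never gating them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

ALPHA = 0.05
RMPE = 0.2
#: effect-size ladder: minimal / moderate / strong |tau| thresholds
EFFECT_LADDER = (0.2, 0.5, 0.8)
#: permutation test switches to exhaustive enumeration at or below this
EXHAUSTIVE_LIMIT = 100_000


class StatError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class TrendTestResult:
    """Signed Jonckheere-Terpstra result; positive z means ascending trend."""

    statistic: float  # raw J (sum of pairwise Mann-Whitney counts)
    z: float
    p: float
    method: str  # normal_approx | permutation | exhaustive
    n_perm: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class VarianceTestResult:
    F: float
    df1: int
    df2: int
    p: float

    @property
    def homoscedastic(self) -> bool:
        return self.p > ALPHA


@dataclass(frozen=True)
class TauResult:
    """Kendall tau-b with a bootstrap percentile CI.

    ``degenerate`` is set (and the numeric fields are NaN) when tau-b is
    undefined, i.e. one margin is entirely tied.
    """

    tau_b: float
    ci_low: float
    ci_high: float
    n: int
    ci_method: str = "bootstrap_percentile"
    B: int = 0
    seed: int | None = None
    degenerate: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class SignificanceVerdict:
    stochastic_ok: bool
    homoscedastic: bool
    effect_ok: bool
    stars: int
    overall: bool
    medians_extend: bool
    reason: str | None = None


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    numDF: int
    denDF: int
    p: float


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise StatError("need at least 2 groups")
    for i, g in enumerate(out):
        if g.size == 0:
            raise StatError(f"group {i} is empty")
    return out


def _jt_pair_matrix(x: np.ndarray) -> np.ndarray:
    """H[a, b] = 1 if x[b] > x[a], 0.5 if tied, 0 otherwise."""
    gt = (x[None, :] > x[:, None]).astype(float)
    eq = (x[None, :] == x[:, None]).astype(float)
    return gt + 0.5 * eq


def _jt_statistic(H: np.ndarray, labels: np.ndarray) -> float:
    mask = labels[:, None] < labels[None, :]
    return float(H[mask].sum())


def _jt_statistic_batch(H: np.ndarray, label_matrix: np.ndarray, chunk: int = 2000) -> np.ndarray:
    out = np.empty(label_matrix.shape[0])
    for start in range(0, label_matrix.shape[0], chunk):
        G = label_matrix[start:start + chunk]
        L = G[:, :, None] < G[:, None, :]
        out[start:start + chunk] = np.einsum("rab,ab->r", L, H)
    return out


def _jt_moments(pooled: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the J statistic."""
    N = int(pooled.size)
    mu = (N * N - float(np.sum(sizes ** 2))) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    n = sizes.astype(float)
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = 0.0
    if N > 2:
        term2 = (
            np.sum(n * (n - 1) * (n - 2)) * np.sum(t * (t - 1) * (t - 2))
        ) / (36.0 * N * (N - 1) * (N - 2))
    term3 = (np.sum(n * (n - 1)) * np.sum(t * (t - 1))) / (8.0 * N * (N - 1))
    return mu, float(term1 + term2 + term3)


def _count_arrangements(sizes: np.ndarray) -> float:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _enumerate_labelings(sizes: np.ndarray) -> np.ndarray:
    """All distinct assignments of positions 0..N-1 to groups of the given sizes."""
    N = int(sizes.sum())
    rows: list[np.ndarray] = []

    def recurse(remaining: tuple[int, ...], labels: np.ndarray, group: int) -> None:
        if group == len(sizes) - 1:
            row = labels.copy()
            row[list(remaining)] = group
            rows.append(row)
            return
        for combo in itertools.combinations(remaining, int(sizes[group])):
            nxt = tuple(i for i in remaining if i not in set(combo))
            labels2 = labels.copy()
            labels2[list(combo)] = group
            recurse(nxt, labels2, group + 1)

    recurse(tuple(range(N)), np.full(N, -1), 0)
    return np.asarray(rows)


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    method: str = "normal_approx",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TrendTestResult:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    The raw statistic is J = sum over ordered group pairs i < j of the
    Mann-Whitney count of (a in group i, b in group j) pairs with
    b > a, ties counted 0.5.  The sign convention makes z positive for an
    ascending trend in the given group order; reversing the order negates
    z.  Two-sided p-values throughout.

    ``method='normal_approx'`` standardises J with the tie-corrected null
    variance.  ``method='permutation'`` relabels observations across
    groups (group sizes fixed) under ``seed``; if the number of distinct
    arrangements is at most :data:`EXHAUSTIVE_LIMIT` the enumeration is
    exhaustive and the p-value exact.
    """
    gs = _as_groups(groups)
    pooled = np.concatenate(gs)
    sizes = np.array([g.size for g in gs])
    labels = np.repeat(np.arange(len(gs)), sizes)
    H = _jt_pair_matrix(pooled)
    J = _jt_statistic(H, labels)
    mu, var = _jt_moments(pooled, sizes)

    if var <= 0:  # every observation identical: no evidence either way
        return TrendTestResult(statistic=J, z=0.0, p=1.0, method=method)

    sigma = math.sqrt(var)
    z = (J - mu) / sigma

    if method == "normal_approx":
        # continuity correction: J lives on a lattice (step 1, or 0.5 with
        # ties), so the two-sided tail is taken half a step inside |J - mu|
        step = 1.0 if np.unique(pooled).size == pooled.size else 0.5
        d = max(abs(J - mu) - step / 2.0, 0.0)
        p = 2.0 * stats.norm.sf(d / sigma)
        return TrendTestResult(statistic=J, z=z, p=min(p, 1.0), method=method)
    if method != "permutation":
        raise StatError(f"unknown method {method!r}")

    if _count_arrangements(sizes) <= EXHAUSTIVE_LIMIT:
        label_matrix = _enumerate_labelings(sizes)
        J_null = _jt_statistic_batch(H, label_matrix)
        p = float(np.mean(np.abs(J_null - mu) >= abs(J - mu) - 1e-9))
        return TrendTestResult(statistic=J, z=z, p=p, method="exhaustive")

    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    label_matrix = labels[perm]
    J_null = _jt_statistic_batch(H, label_matrix)
    p = float(np.mean(np.abs(J_null - mu) >= abs(J - mu) - 1e-9))
    return TrendTestResult(statistic=J, z=z, p=p, method="permutation", n_perm=n_perm, seed=seed)


def brown_forsythe(groups: Sequence[Sequence[float]]) -> VarianceTestResult:
    """Brown-Forsythe homoscedasticity test (Levene on median deviations)."""
    gs = _as_groups(groups)
    for i, g in enumerate(gs):
        if g.size < 2:
            raise StatError(f"group {i} needs >= 2 observations for a variance test")
    k = len(gs)
    n = sum(g.size for g in gs)
    deviations = np.concatenate([np.abs(g - np.median(g)) for g in gs])
    if np.ptp(deviations) == 0:
        # all absolute deviations equal: no dispersion signal at all
        return VarianceTestResult(F=0.0, df1=k - 1, df2=n - k, p=1.0)
    F, p = stats.levene(*gs, center="median")
    return VarianceTestResult(F=float(F), df1=k - 1, df2=n - k, p=float(p))


def kendall_tau_b(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 2000,
    seed: int | None = None,
) -> TauResult:
    """Kendall's tau-b with a seeded percentile-bootstrap 95% CI.

    tau-b applies the standard tie corrections, which matters here: the
    motivation scale has only 4 levels, so ties are heavy.  The CI
    resamples (x, y) pairs; degenerate resamples (an all-tied margin) are
    dropped from the percentile computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise StatError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TauResult(
            tau_b=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            n=n, B=B, seed=seed, degenerate=True,
            reason="tau-b undefined: one margin entirely tied",
        )
    tau = float(stats.kendalltau(x, y, variant="b").statistic)

    rng = np.random.default_rng(seed)
    draws = _tau_b_bootstrap_draws(x, y, B, rng)
    valid = draws[~np.isnan(draws)]
    if valid.size:
        lo, hi = np.percentile(valid, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return TauResult(tau_b=tau, ci_low=float(lo), ci_high=float(hi), n=n, B=B, seed=seed)


def _tau_b_bootstrap_draws(
    x: np.ndarray, y: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """tau-b over ``B`` bootstrap resamples of (x, y) pairs.

    A resample is fully described by its multinomial count vector c over
    the original pairs, and both C - D and the tie counts are quadratic
    forms c' M c in the precomputed pairwise sign matrices, so all draws
    reduce to three (B, n) x (n, n) matrix products.  Draws with an
    all-tied margin are NaN (tau-b undefined there).
    """
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    P = sx * sy
    Zx = (sx == 0).astype(float)
    Zy = (sy == 0).astype(float)
    C = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
    cd = np.einsum("bi,bi->b", C @ P, C) / 2.0
    n1 = (np.einsum("bi,bi->b", C @ Zx, C) - n) / 2.0  # tied pairs in x
    n2 = (np.einsum("bi,bi->b", C @ Zy, C) - n) / 2.0
    n0 = n * (n - 1) / 2.0
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, cd / denom, np.nan)


def _tau_b_batch(X: np.ndarray, Y: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Row-wise tau-b over (B, n) sample matrices via pairwise sign counts.

    Rows with an all-tied margin yield NaN (tau-b undefined there).
    """
    B, n = X.shape
    iu = np.triu_indices(n, k=1)
    out = np.empty(B)
    for start in range(0, B, chunk):
        xb = X[start:start + chunk]
        yb = Y[start:start + chunk]
        sx = np.sign(xb[:, :, None] - xb[:, None, :])[:, iu[0], iu[1]]
        sy = np.sign(yb[:, :, None] - yb[:, None, :])[:, iu[0], iu[1]]
        cd = np.sum(sx * sy, axis=1)  # concordant minus discordant
        n0 = iu[0].size
        n1 = np.sum(sx == 0, axis=1)  # tied pairs in x
        n2 = np.sum(sy == 0, axis=1)
        denom = np.sqrt((n0 - n1).astype(float) * (n0 - n2).astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            out[start:start + chunk] = np.where(denom > 0, cd / denom, np.nan)
    return out


def effect_size_verdict(tau: TauResult, rmpe: float = RMPE) -> tuple[bool, int, str | None]:
    """The dual effect-size rule on a tau-b estimate.

    ``effect_ok`` requires (1) |tau| strictly beyond the RMPE threshold
    and (2) the 95% CI must not reach both -rmpe and +rmpe — otherwise an
    inversely-signed association of practical size is still plausible.
    ``stars`` counts the ladder thresholds (0.2 / 0.5 / 0.8) strictly
    exceeded by |tau|, zero when effect_ok is false.
    """
    if tau.degenerate:
        return False, 0, tau.reason or "degenerate tau"
    if rmpe <= 0:
        raise StatError("rmpe must be > 0")
    abs_tau = abs(tau.tau_b)
    if abs_tau <= rmpe:
        return False, 0, f"|tau|={abs_tau:.3f} does not exceed RMPE={rmpe}"
    if tau.ci_low <= -rmpe and tau.ci_high >= rmpe:
        return False, 0, "95% CI reaches both -RMPE and +RMPE (inverse-significance guard)"
    stars = sum(1 for thr in EFFECT_LADDER if abs_tau > thr)
    return True, stars, None


def composite_decision(
    trend: TrendTestResult,
    variance: VarianceTestResult,
    tau: TauResult,
    alpha: float = ALPHA,
    rmpe: float = RMPE,
) -> SignificanceVerdict:
    """Combine the three tests: significant only under stochastic dominance
    AND practical effect size; homoscedasticity tells whether the ordering
    statement extends from mean ranks to group medians."""
    stochastic_ok = trend.p <= alpha
    effect_ok, stars, reason = effect_size_verdict(tau, rmpe=rmpe)
    homoscedastic = variance.p > alpha
    overall = stochastic_ok and effect_ok
    return SignificanceVerdict(
        stochastic_ok=stochastic_ok,
        homoscedastic=homoscedastic,
        effect_ok=effect_ok,
        stars=stars,
        overall=overall,
        medians_extend=overall and homoscedastic,
        reason=reason,
    )


def p_stars(p: float) -> str:
    """Standard asterisk rating for p-values (0.05 / 0.01 / 0.001)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def mixed_anova(
    pre: Sequence[float],
    post: Sequence[float],
    group: Sequence,
) -> AnovaResult:
    """Two-way mixed ANOVA interaction: time (within) x group (between).

    Classical sums-of-squares decomposition for two timepoints; with two
    times the interaction test is equivalent to a one-way ANOVA on the
    change scores.  numDF = k - 1, denDF = n - k for k groups and n
    subjects with complete pairs.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    if not (pre.size == post.size == group.size):
        raise StatError("pre, post and group must be aligned per subject")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post, group = pre[keep], post[keep], group[keep]
    levels, codes = np.unique(group, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise StatError("need >= 2 groups")
    n = pre.size
    counts = np.bincount(codes)
    if counts.min() < 2:
        lvl = levels[int(np.argmin(counts))]
        raise StatError(f"group {lvl!r} has < 2 complete pre/post pairs")

    y = np.concatenate([pre, post])  # time 0 then time 1
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    subj_mean = (pre + post) / 2.0
    ss_between_subj = float(2.0 * ((subj_mean - gm) ** 2).sum())
    group_mean = np.array([y.reshape(2, -1)[:, codes == j].mean() for j in range(k)])
    ss_group = float(np.sum(2.0 * counts * (group_mean - gm) ** 2))
    time_mean = np.array([pre.mean(), post.mean()])
    ss_time = float(np.sum(n * (time_mean - gm) ** 2))
    cell = np.array([[pre[codes == j].mean(), post[codes == j].mean()] for j in range(k)])
    ss_cells = float(np.sum(counts[:, None] * (cell - gm) ** 2))
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter

    num_df = k - 1
    den_df = n - k
    ms_inter = ss_inter / num_df
    ms_error = ss_error / den_df if den_df > 0 else 0.0
    if ms_error <= 1e-12:
        if abs(ms_inter) <= 1e-12:
            return AnovaResult(effect="time:group", F=0.0, numDF=num_df, denDF=den_df, p=1.0)
        return AnovaResult(effect="time:group", F=float("inf"), numDF=num_df, denDF=den_df, p=0.0)
    F = max(ms_inter, 0.0) / ms_error
    p = float(stats.f.sf(F, num_df, den_df))
    return AnovaResult(effect="time:group", F=float(F), numDF=num_df, denDF=den_df, p=p)


def normality_check(sample: Sequence[float]) -> tuple[float, float, np.ndarray]:
    """Shapiro-Wilk W and p plus detrended QQ deviations.

    The detrended QQ vector is the ordered sample minus the normal
    quantiles fitted by mean and standard deviation (Blom plotting
    positions) — the flat-line diagnostic analogue of a QQ plot.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise StatError(f"normality check supports 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise StatError("sample is constant; normality undefined (zero variance)")
    W, p = stats.shapiro(x)
    ordered = np.sort(x)
    n = x.size
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    fitted = x.mean() + x.std(ddof=1) * stats.norm.ppf(probs)
    return float(W), float(p), ordered - fitted


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for an (n_subjects, k_items) score matrix.

    Provided as an internal-consistency check for synthetic item data;
    not part of the cohort inference chain.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise StatError("need an (n, k>=2) item matrix")
    k = items.shape[1]
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise StatError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
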