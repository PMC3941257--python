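"""Evaluation statistics for comparing two risk scores on one cohort.

Implements the full analysis pipeline: univariate logistic regression
(odds ratio per score point), Hosmer-Lemeshow calibration, AUC with
DeLong or bootstrap confidence intervals, the DeLong paired test for
correlated AUCs, categorical reclassification tables, and the net
reclassification improvement (NRI) with its asymptotic z-test.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import ConvergenceError, DegenerateInputError, ValidationError
from .riskscore import RiskCategory, RiskLabel

__all__ = [
    "LogisticFit",
    "CalibrationResult",
    "AUCResult",
    "AUCComparison",
    "ReclassificationTable",
    "NRIResult",
    "ScorePerformance",
    "ComparisonReport",
    "CIMethod",
    "fit_univariate_logistic",
    "hosmer_lemeshow",
    "auc_with_ci",
    "compare_auc_delong",
    "reclassification",
    "nri",
    "nri_from_categories",
    "evaluate_pair",
]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


class CIMethod(enum.Enum):
    DELONG = "delong"
    BOOTSTRAP = "bootstrap"


@dataclass(frozen=True)
class LogisticFit:
    odds_ratio_per_point: float
    ci95: tuple[float, float]
    intercept: float
    slope: float
    slope_se: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class CalibrationResult:
    hl_statistic: float
    df: int
    p_value: float
    groups: tuple[tuple[int, int, float], ...]  # (n, observed, expected)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    ci_method: CIMethod
    n_boot: int | None = None


@dataclass(frozen=True)
class AUCComparison:
    auc1: float
    auc2: float
    difference: float
    z: float
    p_value: float


@dataclass(frozen=True)
class ReclassificationTable:
    """3x3 cross tabulations (old stratum rows, new stratum columns),
    one matrix for events and one for nonevents, ordered
    LOW < AVERAGE < ELEVATED."""

    events: tuple[tuple[int, ...], ...]
    nonevents: tuple[tuple[int, ...], ...]

    @property
    def n_events(self) -> int:
        return int(np.sum(self.events))

    @property
    def n_nonevents(self) -> int:
        return int(np.sum(self.nonevents))


@dataclass(frozen=True)
class NRIResult:
    nri: float
    event_up: float
    event_down: float
    nonevent_up: float
    nonevent_down: float
    z: float
    p_value: float


@dataclass(frozen=True)
class ScorePerformance:
    logistic: LogisticFit
    calibration: CalibrationResult
    auc: AUCResult


@dataclass(frozen=True)
class ComparisonReport:
    definition: str
    n: int
    n_events: int
    sits: ScorePerformance
    extended: ScorePerformance
    auc_comparison: AUCComparison
    reclassification: ReclassificationTable
    nri: NRIResult


def _as_outcome_array(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=bool)
    if y.ndim != 1:
        raise ValidationError("outcomes must be one-dimensional")
    return y


def _check_both_classes(y: np.ndarray) -> None:
    if y.all() or (~y).all():
        raise ValidationError("both outcome classes must be present")


# ---------------------------------------------------------------------------
# logistic regression

def fit_univariate_logistic(
    scores, outcomes, *, tol: float = 1e-8, max_iter: int = 100
) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression by IRLS.

    Returns the odds ratio per one-point score increase with its Wald 95%
    confidence interval.  Convergence: relative change in log-likelihood
    below ``tol`` within ``max_iter`` Newton steps; complete separation
    surfaces as a :class:`~sichscore.errors.ConvergenceError`.
    """
    x = np.asarray(scores, dtype=float)
    y = _as_outcome_array(outcomes).astype(float)
    if x.shape != y.shape:
        raise ValidationError("scores and outcomes must have equal length")
    _check_both_classes(y.astype(bool))

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = X @ beta
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.isfinite(ll_old) and np.abs(ll - ll_old) <= tol * (np.abs(ll_old) + tol):
            converged = True
            break
        ll_old = ll

    if not converged or np.max(np.abs(beta)) > 30.0:
        raise ConvergenceError(
            "logistic fit did not converge (possible complete separation)"
        )

    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = float(np.sqrt(cov[1, 1]))
    slope = float(beta[1])
    return LogisticFit(
        odds_ratio_per_point=float(np.exp(slope)),
        ci95=(float(np.exp(slope - _Z975 * se)), float(np.exp(slope + _Z975 * se))),
        intercept=float(beta[0]),
        slope=slope,
        slope_se=se,
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# calibration

def hosmer_lemeshow(
    predicted, outcomes, n_groups: int = 10
) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit statistic.

    Subjects are grouped by quantiles of predicted probability with ties
    kept together; the statistic sums (O - E)^2 / (E (1 - E/n_g)) over
    groups and is referred to a chi-square with (groups - 2) df.
    """
    p = np.asarray(predicted, dtype=float)
    y = _as_outcome_array(outcomes).astype(float)
    if p.shape != y.shape:
        raise ValidationError("predicted and outcomes must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("predicted probabilities must lie in [0, 1]")
    n = len(p)
    if n < n_groups:
        raise ValidationError(f"need at least {n_groups} subjects, got {n}")

    # quantile bin edges on the predicted values; duplicate edges merge so
    # tied predictions always land in the same group
    qs = np.quantile(p, np.linspace(0, 1, n_groups + 1)[1:-1])
    edges = np.unique(qs)
    group_idx = np.searchsorted(edges, p, side="right")

    groups = []
    stat = 0.0
    for g in np.unique(group_idx):
        mask = group_idx == g
        ng = int(mask.sum())
        obs = float(y[mask].sum())
        exp = float(p[mask].sum())
        if exp <= 0.0 or exp >= ng:
            raise DegenerateInputError(
                f"group with expected events {exp:g} of {ng}: "
                "statistic undefined; try fewer groups"
            )
        stat += (obs - exp) ** 2 / (exp * (1.0 - exp / ng))
        groups.append((ng, int(obs), exp))

    df = len(groups) - 2
    p_value = float(stats.chi2.sf(stat, df)) if df >= 1 else float("nan")
    return CalibrationResult(
        hl_statistic=float(stat), df=df, p_value=p_value, groups=tuple(groups)
    )


# ---------------------------------------------------------------------------
# AUC / DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """AUC and DeLong structural components (midrank formulation).

    Returns (auc, v10, v01) with v10 indexed by positives and v01 by
    negatives; ties count one half.
    """
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_with_ci(
    scores,
    outcomes,
    method: CIMethod | str = CIMethod.DELONG,
    n_boot: int = 1000,
    seed: int | None = None,
) -> AUCResult:
    """AUC (Mann-Whitney with ties at one half) and a 95% CI.

    ``DELONG`` uses the structural-component variance with a normal
    interval truncated to [0, 1]; ``BOOTSTRAP`` uses the percentile
    interval over seeded case resampling.
    """
    if isinstance(method, str):
        method = CIMethod(method.lower())
    x = np.asarray(scores, dtype=float)
    y = _as_outcome_array(outcomes)
    if x.shape != y.shape:
        raise ValidationError("scores and outcomes must have equal length")
    _check_both_classes(y)

    auc, v10, v01 = _delong_components(x, y)
    var = _delong_variance(v10, v01)

    if method is CIMethod.DELONG:
        half = _Z975 * np.sqrt(var)
        return AUCResult(
            auc=auc,
            variance=var,
            ci95=(max(0.0, auc - half), min(1.0, auc + half)),
            ci_method=method,
        )

    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    rng = np.random.default_rng(seed)
    n = len(x)
    reps = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.all() or (~yb).all():  # single-class resample: redraw
            continue
        reps[filled], _, _ = _delong_components(x[idx], yb)
        filled += 1
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return AUCResult(
        auc=auc,
        variance=float(np.var(reps, ddof=1)),
        ci95=(float(lo), float(hi)),
        ci_method=method,
        n_boot=n_boot,
    )


def compare_auc_delong(scores1, scores2, outcomes) -> AUCComparison:
    """Paired DeLong z-test for the difference of two correlated AUCs
    measured on the same subjects."""
    x1 = np.asarray(scores1, dtype=float)
    x2 = np.asarray(scores2, dtype=float)
    y = _as_outcome_array(outcomes)
    if not (x1.shape == x2.shape == y.shape):
        raise ValidationError("score vectors and outcomes must have equal length")
    _check_both_classes(y)

    auc1, v10_1, v01_1 = _delong_components(x1, y)
    auc2, v10_2, v01_2 = _delong_components(x2, y)
    m, n = len(v10_1), len(v01_1)
    var1 = _delong_variance(v10_1, v01_1)
    var2 = _delong_variance(v10_2, v01_2)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10_1, v10_2, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01_1, v01_2, ddof=1)[0, 1]) / n

    diff = auc2 - auc1
    var_diff = var1 + var2 - 2.0 * cov
    if var_diff <= 0.0:
        if abs(diff) > 1e-12:
            warnings.warn("non-positive variance of AUC difference; z set to 0")
        return AUCComparison(auc1=auc1, auc2=auc2, difference=diff, z=0.0, p_value=1.0)
    z = diff / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AUCComparison(auc1=auc1, auc2=auc2, difference=diff, z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# reclassification / NRI

_LABEL_INDEX = {RiskLabel.LOW: 0, RiskLabel.AVERAGE: 1, RiskLabel.ELEVATED: 2}


def _label_of(item) -> RiskLabel:
    if isinstance(item, RiskCategory):
        return item.label
    if isinstance(item, RiskLabel):
        return item
    if isinstance(item, str):
        return RiskLabel(item.lower())
    raise ValidationError(f"cannot interpret risk category {item!r}")


def reclassification(old_cat, new_cat, outcomes) -> ReclassificationTable:
    """Cross-tabulate old vs new risk strata, separately for events and
    nonevents."""
    y = _as_outcome_array(outcomes)
    if not (len(old_cat) == len(new_cat) == len(y)):
        raise ValidationError("category vectors and outcomes must have equal length")
    ev = np.zeros((3, 3), dtype=int)
    ne = np.zeros((3, 3), dtype=int)
    for o, nw, yi in zip(old_cat, new_cat, y):
        i = _LABEL_INDEX[_label_of(o)]
        j = _LABEL_INDEX[_label_of(nw)]
        (ev if yi else ne)[i, j] += 1
    return ReclassificationTable(
        events=tuple(map(tuple, ev.tolist())),
        nonevents=tuple(map(tuple, ne.tolist())),
    )


def _up_down(matrix: np.ndarray) -> tuple[int, int]:
    up = int(np.triu(matrix, k=1).sum())
    down = int(np.tril(matrix, k=-1).sum())
    return up, down


def nri(table: ReclassificationTable) -> NRIResult:
    """Categorical net reclassification improvement.

    NRI = (P(up|event) - P(down|event)) - (P(up|nonevent) - P(down|nonevent));
    the z statistic is the asymptotic test
    z = NRI / sqrt((p_up_e + p_down_e)/n_e + (p_up_ne + p_down_ne)/n_ne).
    """
    ev = np.asarray(table.events)
    ne = np.asarray(table.nonevents)
    n_e = int(ev.sum())
    n_ne = int(ne.sum())
    if n_e == 0 or n_ne == 0:
        raise ValidationError("need at least one event and one nonevent")

    eu, ed = _up_down(ev)
    nu, nd = _up_down(ne)
    p_eu, p_ed = eu / n_e, ed / n_e
    p_nu, p_nd = nu / n_ne, nd / n_ne
    value = (p_eu - p_ed) - (p_nu - p_nd)
    var = (p_eu + p_ed) / n_e + (p_nu + p_nd) / n_ne
    if var > 0:
        z = value / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    return NRIResult(
        nri=float(value),
        event_up=p_eu,
        event_down=p_ed,
        nonevent_up=p_nu,
        nonevent_down=p_nd,
        z=float(z),
        p_value=p,
    )


def nri_from_categories(old_cat, new_cat, outcomes) -> NRIResult:
    """NRI computed directly from raw category vectors."""
    return nri(reclassification(old_cat, new_cat, outcomes))


# ---------------------------------------------------------------------------
# full pairwise evaluation

def _performance(
    scores: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    seed: int | None,
    hl_groups: int,
) -> ScorePerformance:
    fit = fit_univariate_logistic(scores, y)
    predicted = expit(fit.intercept + fit.slope * np.asarray(scores, dtype=float))
    calib = hosmer_lemeshow(predicted, y, n_groups=hl_groups)
    auc = auc_with_ci(scores, y, CIMethod.BOOTSTRAP, n_boot=n_boot, seed=seed)
    return ScorePerformance(logistic=fit, calibration=calib, auc=auc)


def evaluate_pair(
    sits_scores,
    ext_scores,
    outcomes,
    *,
    definition: str = "ninds",
    n_boot: int = 1000,
    seed: int | None = None,
    hl_groups: int = 10,
) -> ComparisonReport:
    """Assemble the full paired evaluation of the two scores for one SICH
    definition: per-point odds ratios, calibration, bootstrap AUC CIs, the
    DeLong comparison, the 3x3 reclassification table, and the NRI."""
    from .riskscore import ScoreKind, ScoreResult, stratify

    y = _as_outcome_array(outcomes)
    s1 = np.asarray(sits_scores)
    s2 = np.asarray(ext_scores)
    if not (s1.shape == s2.shape == y.shape):
        raise ValidationError("inputs must have equal length")

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seed1, seed2 = (int(s.generate_state(1)[0]) for s in ss.spawn(2))

    perf1 = _performance(s1, y, n_boot, seed1, hl_groups)
    perf2 = _performance(s2, y, n_boot, seed2, hl_groups)
    comparison = compare_auc_delong(s1, s2, y)

    old_cat = [
        stratify(ScoreResult(int(t), (), ScoreKind.SITS)).label for t in s1
    ]
    new_cat = [
        stratify(ScoreResult(int(t), (), ScoreKind.EXTENDED)).label for t in s2
    ]
    table = reclassification(old_cat, new_cat, y)
    nri_result = nri(table)

    return ComparisonReport(
        definition=definition,
        n=len(y),
        n_events=int(y.sum()),
        sits=perf1,
        extended=perf2,
        auc_comparison=comparison,
        reclassification=table,
        nri=nri_result,
    )
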