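"""Behavioral analysis stage.

Implements the full behavioral pipeline: two-factor scoring of the six
post-task ratings, per-condition mixed-effects choice regressions yielding
the relative weight of communal concern, the relative self-payoff
comparison, repeated-measures ANOVA with Greenhouse-Geisser correction,
within-participant linear-trend contrasts, paired comparisons, and the
Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import (
    CHOICE_ALTRUISTIC,
    CHOICE_STRATEGIC,
    CONDITION_ORDER,
    EfficiencyCondition,
    relative_self_payoff,
)

__all__ = [
    "COMMUNAL_VARS",
    "OBLIGATION_VARS",
    "FACTOR_VARS",
    "RatingProfile",
    "FactorScores",
    "RelativeWeight",
    "StatResult",
    "DegenerateInputError",
    "rescale_second_order_belief",
    "factor_scores",
    "delta_factor_table",
    "relative_weight",
    "relative_weights",
    "choice_probability_table",
    "rm_anova_gg",
    "linear_trend",
    "pairwise_comparisons",
    "mann_whitney",
    "self_payoff_comparison",
]

log = logging.getLogger(__name__)

#: Variables loading on the communal factor.
COMMUNAL_VARS = ("care", "gratitude", "guilt")
#: Variables loading on the obligation factor.
OBLIGATION_VARS = ("second_order_belief", "obligation")
#: All factored variables; indebtedness is excluded from factoring.
FACTOR_VARS = COMMUNAL_VARS + OBLIGATION_VARS

RATING_VARS = FACTOR_VARS + ("indebtedness",)


class DegenerateInputError(ValueError):
    """Raised when an input has no usable variation."""


@dataclass
class RatingProfile:
    """Six subjective ratings for one benefactor type x cost cell.

    ``second_order_belief`` is stored on the 0-100 scale (raw 0-25 ratings
    are multiplied by 4; see :func:`rescale_second_order_belief`).
    """

    participant_id: str
    benefactor_type: str
    cost: int
    care: float
    second_order_belief: float
    gratitude: float
    guilt: float
    obligation: float
    indebtedness: float


@dataclass
class FactorScores:
    """Standardized two-factor scores plus the fitted loading structure."""

    scores: pd.DataFrame  # input rows + pc_communal, pc_obligation
    loading_matrix: pd.DataFrame  # 5 variables x 2 factors
    variance_explained: float


@dataclass
class RelativeWeight:
    participant_id: str
    condition: EfficiencyCondition
    beta_communal: float
    beta_obligation: float

    @property
    def relative_weight(self) -> float:
        return relative_weight(self.beta_communal, self.beta_obligation)


@dataclass
class StatResult:
    """Generic container for test output (F, t, U, or Z style results)."""

    effect_name: str
    estimate: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    statistic: float | None = None
    df1: float | None = None
    df2: float | None = None
    epsilon: float | None = None
    p: float | None = None
    effect_size: float | None = None
    note: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "effect_name": self.effect_name,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "statistic": self.statistic,
            "df1": self.df1,
            "df2": self.df2,
            "epsilon": self.epsilon,
            "p": self.p,
            "effect_size": self.effect_size,
            "note": self.note,
        }
        return out


def rescale_second_order_belief(raw: float | np.ndarray) -> float | np.ndarray:
    """Map raw 0-25 second-order-belief ratings onto the 0-100 scale."""
    return np.asarray(raw, dtype=float) * 4 if np.ndim(raw) else float(raw) * 4


# ---------------------------------------------------------------------------
# Factor scoring
# ---------------------------------------------------------------------------

def factor_scores(ratings: pd.DataFrame) -> FactorScores:
    """Score the fixed-structure two-factor model of the five rated variables.

    The communal factor loads on care/gratitude/guilt; the obligation factor
    on second-order belief/obligation; cross-loadings are fixed at zero and
    indebtedness is excluded.  Each block's factor is the least-squares
    rank-1 fit (first principal component) of the standardized block, so
    scores are invariant to affine rescaling of any input variable.

    Parameters
    ----------
    ratings
        One row per profile with at least the columns in ``FACTOR_VARS``.

    Returns
    -------
    FactorScores
        ``scores`` carries the input rows plus standardized ``pc_communal``
        and ``pc_obligation``; ``variance_explained`` is the proportion of
        the five standardized variables' total variance captured by the two
        block factors.
    """
    missing = [v for v in FACTOR_VARS if v not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    if len(ratings) < 2:
        raise ValueError("need at least 2 rating profiles to fit factors")

    X = ratings.loc[:, list(FACTOR_VARS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in rating variables")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(FACTOR_VARS, sd):
        if s == 0:
            raise DegenerateInputError(
                f"variable {name!r} has zero variance; cannot be factored"
            )
    Z = (X - X.mean(axis=0)) / sd

    blocks = {"communal": COMMUNAL_VARS, "obligation": OBLIGATION_VARS}
    loadings = pd.DataFrame(
        0.0, index=list(FACTOR_VARS), columns=list(blocks)
    )
    scores = {}
    explained = 0.0
    n = Z.shape[0]
    for fac, vars_ in blocks.items():
        cols = [FACTOR_VARS.index(v) for v in vars_]
        Zb = Z[:, cols]
        u, s, vt = np.linalg.svd(Zb, full_matrices=False)
        v1 = vt[0]
        if v1.sum() < 0:  # orient so designated loadings come out positive
            v1 = -v1
        raw = Zb @ v1
        raw_sd = raw.std(ddof=1)
        if raw_sd == 0:
            raise DegenerateInputError(
                f"factor {fac!r} has zero score variance"
            )
        scores[fac] = (raw - raw.mean()) / raw_sd
        # loadings on the correlation scale: s1 * v1 / sqrt(n - 1)
        loadings.loc[list(vars_), fac] = s[0] * v1 / np.sqrt(n - 1)
        explained += s[0] ** 2
    variance_explained = float(explained / ((n - 1) * len(FACTOR_VARS)))

    out = ratings.copy()
    out["pc_communal"] = scores["communal"]
    out["pc_obligation"] = scores["obligation"]
    return FactorScores(
        scores=out,
        loading_matrix=loadings,
        variance_explained=variance_explained,
    )


def delta_factor_table(factors: pd.DataFrame) -> pd.DataFrame:
    """Altruistic-minus-strategic factor scores per (participant, cost).

    ``factors`` must carry participant_id, benefactor_type, cost,
    pc_communal, pc_obligation (e.g. the ``scores`` frame returned by
    :func:`factor_scores`).
    """
    req = {"participant_id", "benefactor_type", "cost",
           "pc_communal", "pc_obligation"}
    missing = req - set(factors.columns)
    if missing:
        raise ValueError(f"factor table missing columns: {sorted(missing)}")
    wide = factors.pivot_table(
        index=["participant_id", "cost"],
        columns="benefactor_type",
        values=["pc_communal", "pc_obligation"],
    )
    for bt in (CHOICE_ALTRUISTIC, CHOICE_STRATEGIC):
        if bt not in wide["pc_communal"].columns:
            raise ValueError(f"factor scores missing benefactor type {bt!r}")
    out = pd.DataFrame(
        {
            "dc": wide[("pc_communal", CHOICE_ALTRUISTIC)]
            - wide[("pc_communal", CHOICE_STRATEGIC)],
            "do": wide[("pc_obligation", CHOICE_ALTRUISTIC)]
            - wide[("pc_obligation", CHOICE_STRATEGIC)],
        }
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Per-condition choice regressions -> relative weight of communal concern
# ---------------------------------------------------------------------------

def relative_weight(beta_communal: float, beta_obligation: float) -> float:
    """``|b_c| / (|b_c| + |b_o|)``; NaN when both betas are exactly zero."""
    bc, bo = abs(beta_communal), abs(beta_obligation)
    if bc + bo == 0:
        return float("nan")
    return bc / (bc + bo)


def _penalized_logit(y: np.ndarray, X: np.ndarray, l2: float = 1.0) -> np.ndarray:
    """Ridge-penalized logistic fit (intercept unpenalized).

    The penalty keeps coefficients finite under complete separation, a mild
    stand-in for the shrinkage a mixed model would provide.
    """
    Xd = np.column_stack([np.ones(len(y)), X])
    pen = np.r_[0.0, np.full(X.shape[1], l2)]

    def negll(b):
        eta = Xd @ b
        return (
            np.logaddexp(0, eta).sum() - y @ eta + 0.5 * (pen * b**2).sum()
        )

    def grad(b):
        p = 1.0 / (1.0 + np.exp(-(Xd @ b)))
        return Xd.T @ (p - y) + pen * b

    res = optimize.minimize(
        negll, np.zeros(Xd.shape[1]), jac=grad, method="L-BFGS-B"
    )
    return res.x[1:]


def _fit_condition_mixed(sub: pd.DataFrame, pids: list[str]) -> pd.DataFrame:
    """Mixed logistic fit of choice on (dc, do) with by-participant slopes.

    Returns per-participant betas as fixed effect + conditional random
    slope (posterior mean).
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    model = BinomialBayesMixedGLM.from_formula(
        "y ~ dc + do",
        {"dc": "0 + C(participant_id):dc", "do": "0 + C(participant_id):do"},
        sub,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit_vb()
    fe = dict(zip(model.exog_names, fit.fe_mean))
    re_c = {p: 0.0 for p in pids}
    re_o = {p: 0.0 for p in pids}
    pat = re.compile(r"^C\(participant_id\)\[(.+)\]:(dc|do)$")
    for name, val in zip(model.vc_names, fit.vc_mean):
        m = pat.match(name)
        if m is None:  # pragma: no cover - defensive
            raise RuntimeError(f"unexpected random-effect name {name!r}")
        pid, term = m.groups()
        (re_c if term == "dc" else re_o)[pid] = float(val)
    if not (np.all(np.isfinite(fit.fe_mean)) and np.all(np.isfinite(fit.vc_mean))):
        raise RuntimeError("mixed fit produced non-finite estimates")
    return pd.DataFrame(
        {
            "participant_id": pids,
            "beta_communal": [fe["dc"] + re_c[p] for p in pids],
            "beta_obligation": [fe["do"] + re_o[p] for p in pids],
        }
    )


def _fit_condition_independent(
    sub: pd.DataFrame, pids: list[str]
) -> pd.DataFrame:
    rows = []
    for pid, grp in sub.groupby("participant_id", sort=False):
        b = _penalized_logit(
            grp["y"].to_numpy(float), grp[["dc", "do"]].to_numpy(float)
        )
        rows.append((pid, b[0], b[1]))
    out = pd.DataFrame(
        rows, columns=["participant_id", "beta_communal", "beta_obligation"]
    )
    return out.set_index("participant_id").loc[pids].reset_index()


def relative_weights(
    trials: pd.DataFrame,
    factors: pd.DataFrame,
    method: str = "mixed",
) -> pd.DataFrame:
    """Per-participant relative weight of communal concern per condition.

    For each efficiency condition, the probability of choosing the
    altruistic benefactor is regressed on the altruistic-minus-strategic
    factor-score differences (``dc``, ``do``) in a logistic mixed model with
    by-participant random slopes; per-participant betas are the fixed effect
    plus that participant's conditional random slope.  ``method='independent'``
    instead fits one penalized logistic regression per participant (the
    sensitivity-check mode).

    Returns a tidy frame: participant_id, condition, beta_communal,
    beta_obligation, relative_weight.
    """
    if method not in ("mixed", "independent"):
        raise ValueError(f"unknown method {method!r}")
    deltas = delta_factor_table(factors) if "dc" not in factors.columns else factors
    data = trials.dropna(subset=["choice"]).merge(
        deltas[["participant_id", "cost", "dc", "do"]],
        on=["participant_id", "cost"],
        how="left",
    )
    if data[["dc", "do"]].isna().any().any():
        raise ValueError(
            "missing factor scores for some (participant, cost) cells"
        )
    pids = sorted(trials["participant_id"].unique())
    if len(pids) < 2:
        raise ValueError("mixed choice regression needs >= 2 participants")
    data["y"] = (data["choice"] == CHOICE_ALTRUISTIC).astype(int)

    frames = []
    for cond in CONDITION_ORDER:
        sub = data[data["condition"] == cond.value]
        if set(sub["participant_id"]) != set(pids):
            raise ValueError(
                f"every participant needs trials in condition {cond.value}"
            )
        if method == "mixed":
            try:
                betas = _fit_condition_mixed(sub, pids)
            except Exception as exc:  # singular/failed fit -> fallback
                log.warning(
                    "mixed fit failed in %s (%s); falling back to "
                    "independent per-participant regressions",
                    cond.value,
                    exc,
                )
                betas = _fit_condition_independent(sub, pids)
        else:
            betas = _fit_condition_independent(sub, pids)
        betas = betas.assign(condition=cond.value)
        frames.append(betas)
    out = pd.concat(frames, ignore_index=True)
    out["relative_weight"] = [
        relative_weight(bc, bo)
        for bc, bo in zip(out["beta_communal"], out["beta_obligation"])
    ]
    return out[
        ["participant_id", "condition", "beta_communal",
         "beta_obligation", "relative_weight"]
    ]


def choice_probability_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant x condition table of P(choose altruistic).

    Missing choices are excluded; columns follow the canonical condition
    order.
    """
    ok = trials.dropna(subset=["choice"]).copy()
    ok["y"] = (ok["choice"] == CHOICE_ALTRUISTIC).astype(float)
    table = ok.pivot_table(
        index="participant_id", columns="condition", values="y"
    )
    return table[[c.value for c in CONDITION_ORDER]]


# ---------------------------------------------------------------------------
# Repeated-measures tests
# ---------------------------------------------------------------------------

def _as_matrix(values) -> tuple[np.ndarray, list[str]]:
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float), [str(c) for c in values.columns]
    arr = np.asarray(values, dtype=float)
    return arr, [str(i) for i in range(arr.shape[1])]


def rm_anova_gg(values, effect_name: str = "condition") -> StatResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``values`` is a complete participant x level table (DataFrame or 2-D
    array).  Epsilon is computed from the double-centered sample covariance
    of the level columns; F is referred to an F distribution with
    epsilon-scaled degrees of freedom.  Partial eta squared is returned as
    the effect size.
    """
    Y, levels = _as_matrix(values)
    if np.isnan(Y).any():
        raise ValueError("missing cells in repeated-measures table")
    n, k = Y.shape
    if k < 2:
        raise ValueError("need >= 2 within-subject levels")
    if n < 3:
        raise ValueError("need >= 3 participants")

    grand = Y.mean()
    col_means = Y.mean(axis=0)
    row_means = Y.mean(axis=1)
    ss_cond = n * ((col_means - grand) ** 2).sum()
    resid = Y - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2

    # Greenhouse-Geisser epsilon from the double-centered covariance.
    S = np.cov(Y, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    denom = (k - 1) * (Sc**2).sum()
    eps = 1.0 if denom == 0 else float(np.trace(Sc) ** 2 / denom)
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else float("inf")
        p = 1.0 if ms_cond == 0 else 0.0
        note = "zero error variance"
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df1 * eps, df2 * eps))
        note = ""
    eta_p2 = 0.0 if ss_cond + ss_err == 0 else ss_cond / (ss_cond + ss_err)
    return StatResult(
        effect_name=effect_name,
        statistic=f,
        df1=df1 * eps,
        df2=df2 * eps,
        epsilon=eps,
        p=p,
        effect_size=float(eta_p2),
        note=note,
        extra={"uncorrected_df": (df1, df2), "levels": levels},
    )


#: Within-participant linear contrast over the three ordered conditions.
LINEAR_CONTRAST = np.array([-1.0, 0.0, 1.0])


def linear_trend(values, effect_name: str = "linear trend") -> StatResult:
    """Linear-trend contrast across exactly three ordered levels.

    Per-participant contrast scores use weights (-1, 0, +1); the trend is
    tested with a one-sample t (reported as F = t^2 on df (1, n-1)).
    A zero-variance, nonzero-mean contrast is reported as an exact trend
    (infinite F, p = 0, flagged in ``note``).
    """
    Y, _ = _as_matrix(values)
    if Y.shape[1] != 3:
        raise ValueError("linear_trend requires exactly 3 ordered levels")
    if np.isnan(Y).any():
        raise ValueError("missing cells in repeated-measures table")
    n = Y.shape[0]
    scores = Y @ LINEAR_CONTRAST
    mean = scores.mean()
    sd = scores.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        if mean == 0:
            return StatResult(
                effect_name=effect_name, estimate=0.0, statistic=0.0,
                df1=1, df2=n - 1, p=1.0, note="no linear component",
            )
        return StatResult(
            effect_name=effect_name, estimate=float(mean),
            statistic=float("inf"), df1=1, df2=n - 1, p=0.0,
            note="exact trend (zero contrast variance)",
        )
    se = sd / np.sqrt(n)
    t = mean / se
    f = t**2
    p = float(stats.f.sf(f, 1, n - 1))
    eta_p2 = f / (f + (n - 1))
    return StatResult(
        effect_name=effect_name, estimate=float(mean), se=float(se),
        statistic=float(f), df1=1, df2=n - 1, p=p,
        effect_size=float(eta_p2),
    )


def pairwise_comparisons(values) -> list[StatResult]:
    """Paired mean differences (later minus earlier column) for all pairs.

    Returns mean difference, SE, t-based 95% CI and two-tailed p per pair,
    uncorrected (matching the primary reporting style).
    """
    Y, levels = _as_matrix(values)
    if np.isnan(Y).any():
        raise ValueError("missing cells in repeated-measures table")
    n = Y.shape[0]
    if n < 3:
        raise ValueError("need >= 3 participants")
    out = []
    for i, j in itertools.combinations(range(Y.shape[1]), 2):
        d = Y[:, j] - Y[:, i]
        mean = d.mean()
        sd = d.std(ddof=1)
        se = sd / np.sqrt(n)
        if se == 0:
            t = 0.0 if mean == 0 else float("inf")
            p = 1.0 if mean == 0 else 0.0
            ci = (mean, mean)
            note = "zero paired variance"
        else:
            t = mean / se
            p = float(2 * stats.t.sf(abs(t), n - 1))
            half = stats.t.ppf(0.975, n - 1) * se
            ci = (mean - half, mean + half)
            note = ""
        out.append(
            StatResult(
                effect_name=f"{levels[j]} - {levels[i]}",
                estimate=float(mean), se=float(se),
                ci_low=float(ci[0]), ci_high=float(ci[1]),
                statistic=float(t), df1=1, df2=n - 1, p=p, note=note,
            )
        )
    return out


def mann_whitney(x, y, effect_name: str = "mann-whitney") -> StatResult:
    """Two-sided Mann-Whitney U test.

    Reports the U statistic for ``x``, the tie-corrected normal-approximation
    Z, and the two-tailed p.  With both samples of size <= 8 and no ties the
    p-value is the exact enumeration p; otherwise the normal approximation
    (no continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    nn = n1 + n2
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    z = 0.0 if var == 0 else (u1 - mu) / np.sqrt(var)
    has_ties = tie_term > 0
    if n1 <= 8 and n2 <= 8 and not has_ties:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").pvalue
        )
        note = "exact"
    else:
        p = 1.0 if var == 0 else float(2 * stats.norm.sf(abs(z)))
        note = "normal approximation, tie-corrected"
    # rank-biserial correlation as effect size
    rb = 2 * u1 / (n1 * n2) - 1
    return StatResult(
        effect_name=effect_name, statistic=float(u1), estimate=float(z),
        p=p, effect_size=float(rb), note=note,
        extra={"z": float(z), "n1": n1, "n2": n2},
    )


def self_payoff_comparison(
    trials: pd.DataFrame,
    chosen_type: str,
    cond_hi: EfficiencyCondition,
    cond_ref: EfficiencyCondition,
    endowment: float = 25,
) -> StatResult:
    """Compare relative self-payoff between two conditions.

    Restricted to trials where ``chosen_type`` was chosen and an allocation
    was made; per participant, the mean relative self-payoff is computed
    within each condition and the two participant-level samples are compared
    with :func:`mann_whitney` (unpaired: participants enter each condition's
    sample only if they have qualifying trials there).
    """
    q = trials[
        (trials["choice"] == chosen_type) & trials["allocation"].notna()
    ].copy()
    samples = {}
    for cond in (cond_hi, cond_ref):
        sub = q[q["condition"] == cond.value]
        if len(sub) == 0:
            counts = q.groupby("condition").size().to_dict()
            raise ValueError(
                f"no trials where {chosen_type!r} was chosen in "
                f"{cond.value}; qualifying counts per condition: {counts}"
            )
        eff = cond.efficiency_of(chosen_type)
        rsp = sub["allocation"].map(
            lambda a: relative_self_payoff(a, eff, endowment)
        )
        samples[cond.value] = (
            rsp.groupby(sub["participant_id"]).mean().to_numpy()
        )
    return mann_whitney(
        samples[cond_hi.value],
        samples[cond_ref.value],
        effect_name=(
            f"relative self-payoff ({chosen_type} chosen): "
            f"{cond_hi.value} vs {cond_ref.value}"
        ),
    )
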