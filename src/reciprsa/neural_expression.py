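"""Cross-study pattern-expression stage.

Scores each participant's condition contrast map against two whole-brain
weight maps (communal concern and obligation) by dot product, min-max
normalizes the expression values, forms the neural relative weight of
communal concern, and tests its condition structure with a
within-participant label-permutation test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LINEAR_CONTRAST, StatResult, rm_anova_gg
from .design import CONDITION_ORDER

__all__ = [
    "PatternMap",
    "pattern_expression",
    "expression_table",
    "minmax_normalize",
    "neural_relative_weight",
    "relative_weight_table",
    "permutation_test",
    "PermutationResult",
]

MAX_NONFINITE_FRACTION = 0.05


@dataclass
class PatternMap:
    """A named whole-brain weight map on the condition maps' voxel grid."""

    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"pattern map {self.name!r} has non-finite weights")


def pattern_expression(condition_map: np.ndarray, pattern: PatternMap) -> float:
    """Dot product of a condition map with a pattern map.

    Non-finite voxels are excluded pairwise; if they exceed 5% of the grid a
    data-quality error is raised.  Grids must match exactly.
    """
    cmap = np.asarray(condition_map, dtype=float).ravel()
    w = pattern.weights.ravel()
    if cmap.shape != w.shape:
        raise ValueError(
            f"grid mismatch: condition map {cmap.shape} vs "
            f"pattern map {w.shape}"
        )
    valid = np.isfinite(cmap)
    bad = 1.0 - valid.mean()
    if bad >= MAX_NONFINITE_FRACTION and bad > 0:
        raise ValueError(
            f"{bad:.1%} of voxels non-finite (limit "
            f"{MAX_NONFINITE_FRACTION:.0%})"
        )
    return float(cmap[valid] @ w[valid])


def expression_table(
    maps: np.ndarray,
    communal: PatternMap,
    obligation: PatternMap,
    participant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Raw expression values for every (participant, condition, map).

    ``maps`` has shape (participants, 27, voxels) in canonical grid order or
    (participants, 3, voxels) with one map per efficiency condition; with 27
    cells the nine cost cells of each condition are averaged into the
    condition's contrast map first.

    Returns a tidy frame: participant_id, condition, map_name, raw_value.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[1] not in (3, 27):
        raise ValueError(
            "maps must be (participants, 3 or 27, voxels); got "
            f"{maps.shape}"
        )
    if maps.shape[1] == 27:
        maps = maps.reshape(maps.shape[0], 3, 9, maps.shape[2]).mean(axis=2)
    n_part = maps.shape[0]
    if participant_ids is None:
        participant_ids = [f"sub-{i + 1:03d}" for i in range(n_part)]
    rows = []
    for p, pid in enumerate(participant_ids):
        for c, cond in enumerate(CONDITION_ORDER):
            for pm in (communal, obligation):
                rows.append(
                    (pid, cond.value, pm.name,
                     pattern_expression(maps[p, c], pm))
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "map_name", "raw_value"]
    )


def minmax_normalize(
    table: pd.DataFrame, group: str = "global"
) -> pd.DataFrame:
    """Min-max normalize ``raw_value`` into ``norm_value`` per group.

    ``group='global'`` (default) normalizes each map's values jointly across
    all participants and conditions; ``group='participant'`` normalizes each
    map within participant.  Constant groups raise a degenerate-normalization
    error naming the group.
    """
    if group == "global":
        keys = ["map_name"]
    elif group == "participant":
        keys = ["map_name", "participant_id"]
    else:
        raise ValueError(f"unknown normalization group {group!r}")
    out = table.copy()
    norm = np.empty(len(out), dtype=float)
    for name, grp in out.groupby(keys, sort=False):
        lo, hi = grp["raw_value"].min(), grp["raw_value"].max()
        if hi == lo:
            raise ValueError(
                f"degenerate normalization: constant values in group {name}"
            )
        norm[out.index.get_indexer(grp.index)] = (
            (grp["raw_value"] - lo) / (hi - lo)
        )
    out["norm_value"] = norm
    out.attrs["normalization_scope"] = group
    return out


def neural_relative_weight(
    table: pd.DataFrame, value_col: str = "norm_value"
) -> pd.DataFrame:
    """``|NV_communal| / (|NV_communal| + |NV_obligation|)`` per key.

    ``table`` is the (normalized) expression table.  Rows where both values
    are exactly zero yield NaN (no meaningful weight) and are expected to be
    excluded listwise downstream.
    """
    wide = table.pivot_table(
        index=["participant_id", "condition"],
        columns="map_name",
        values=value_col,
    )
    for name in ("communal", "obligation"):
        if name not in wide.columns:
            raise KeyError(f"expression table missing map {name!r}")
    if wide.isna().any().any():
        raise KeyError("missing (participant, condition, map) entries")
    nc = wide["communal"].abs()
    no = wide["obligation"].abs()
    denom = nc + no
    nrw = np.where(denom > 0, nc / denom, np.nan)
    out = wide.reset_index()[["participant_id", "condition"]]
    out["neural_relative_weight"] = nrw
    return out


def relative_weight_table(nrw: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy neural-relative-weight frame to participant x condition."""
    table = nrw.pivot_table(
        index="participant_id", columns="condition",
        values="neural_relative_weight",
    )
    return table[[c.value for c in CONDITION_ORDER]]


def _anova_f_many(Y: np.ndarray) -> np.ndarray:
    """Repeated-measures F for stacked tables, shape (..., n, k)."""
    n, k = Y.shape[-2], Y.shape[-1]
    grand = Y.mean(axis=(-2, -1), keepdims=True)
    col = Y.mean(axis=-2, keepdims=True)
    row = Y.mean(axis=-1, keepdims=True)
    ss_cond = n * ((col - grand) ** 2).sum(axis=(-2, -1))
    resid = Y - row - col + grand
    ss_err = (resid**2).sum(axis=(-2, -1))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    return np.where(ss_err == 0, np.where(ss_cond == 0, 0.0, np.inf), f)


def _linear_beta_many(Y: np.ndarray) -> np.ndarray:
    """Least-squares slope of condition means on position (1, 2, 3)."""
    scores = Y @ LINEAR_CONTRAST  # x3 - x1 per participant
    return scores.mean(axis=-1) / 2.0


@dataclass
class PermutationResult:
    """Empirical p-values and null distributions for F and linear slope."""

    observed_f: float
    observed_beta: float
    p_f: float
    p_beta: float
    null_f: np.ndarray
    null_beta: np.ndarray
    n_perm: int
    exhaustive: bool

    @property
    def resolution(self) -> float:
        """Smallest nonzero p representable (1 / number of permutations)."""
        return 1.0 / self.n_perm


def permutation_test(
    values,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermutationResult:
    """Within-participant condition-label permutation test.

    For each iteration the three condition labels are permuted independently
    within every participant and the repeated-measures ANOVA F and the
    linear-contrast slope are recomputed.  Empirical p is the proportion of
    permuted statistics >= the observed one (ties count, so p is never an
    artifact zero; an exact 0 can only occur in exhaustive mode when the
    observed value is strictly unattainable).  With <= 6 participants all
    ``6^n`` label assignments are enumerated instead of sampled (also
    selectable via ``exhaustive``).
    """
    Y = np.asarray(
        values.to_numpy() if isinstance(values, pd.DataFrame) else values,
        dtype=float,
    )
    if Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError("values must be a participants x 3 table")
    if np.isnan(Y).any():
        raise ValueError("missing cells in permutation-test table")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = Y.shape[0]
    if exhaustive is None:
        exhaustive = n <= 6

    obs_f = float(_anova_f_many(Y))
    obs_beta = float(_linear_beta_many(Y))

    perms3 = np.array(list(itertools.permutations(range(3))))
    if exhaustive:
        idx = np.array(
            list(itertools.product(range(6), repeat=n)), dtype=np.int64
        )  # (6^n, n)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, 6, size=(n_perm, n))
    null_f = np.empty(len(idx))
    null_beta = np.empty(len(idx))
    chunk = 4096
    rows = np.arange(n)
    for start in range(0, len(idx), chunk):
        sel = perms3[idx[start:start + chunk]]  # (m, n, 3)
        Yp = Y[rows[None, :, None], sel]
        null_f[start:start + chunk] = _anova_f_many(Yp)
        null_beta[start:start + chunk] = _linear_beta_many(Yp)

    m = len(idx)
    p_f = float((null_f >= obs_f).sum() / m)
    p_beta = float((null_beta >= obs_beta).sum() / m)
    return PermutationResult(
        observed_f=obs_f, observed_beta=obs_beta,
        p_f=p_f, p_beta=p_beta,
        null_f=null_f, null_beta=null_beta,
        n_perm=m, exhaustive=exhaustive,
    )


def expression_anova(nrw_table: pd.DataFrame) -> StatResult:
    """Convenience: GG-corrected RM-ANOVA on the neural relative weight."""
    clean = nrw_table.dropna()
    return rm_anova_gg(clean, effect_name="neural relative weight ~ condition")
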