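"""Representational similarity stage.

Builds the four hand-coded cognitive dissimilarity matrices, computes
per-parcel neural RDMs from the 27 condition maps via correlation
dissimilarity, regresses neural on cognitive dissimilarity with a
participant-level random intercept, and controls the false discovery rate
across parcels (Benjamini-Hochberg).  An ROI-restricted mode treats each
named mask as a parcel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITION_ORDER, COSTS, EfficiencyCondition

__all__ = [
    "CONDITION_GRID",
    "N_CELLS",
    "COGNITIVE_MODELS",
    "cognitive_codes",
    "cognitive_rdm",
    "parcel_rdm",
    "vectorize_lower",
    "rdm_from_vector",
    "mixed_rsa",
    "fdr_correct",
    "rsa_parcels",
    "roi_rsa",
    "ParcelResult",
    "DegenerateParcelError",
]

log = logging.getLogger(__name__)

#: Canonical 27-cell condition grid: conditions in canonical order, costs
#: ascending within condition.  Identical across participants and modules.
CONDITION_GRID: tuple[tuple[EfficiencyCondition, int], ...] = tuple(
    (cond, cost) for cond in CONDITION_ORDER for cost in COSTS
)
N_CELLS = len(CONDITION_GRID)

#: Condition codings of the four cognitive models, in canonical condition
#: order (A1S3, A1S1, A3S1).  Only the similarity pattern the codes induce
#: matters, not their absolute values.
COGNITIVE_MODELS: dict[str, tuple[int, int, int]] = {
    "general": (3, 1, 3),
    "altruistic": (1, 1, 3),
    "strategic": (3, 1, 1),
    "linear": (1, 2, 3),
}


class DegenerateParcelError(ValueError):
    """Raised when a parcel's voxel patterns cannot support an RDM."""


@dataclass
class ParcelResult:
    """Mixed-model RSA result for one parcel (or ROI) under one model."""

    parcel_id: int | str
    model: str
    coefficient: float
    se: float
    z: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float | None = None
    significant: bool | None = None


def cognitive_codes(model: str) -> dict[EfficiencyCondition, int]:
    if model not in COGNITIVE_MODELS:
        raise ValueError(
            f"unknown cognitive model {model!r}; "
            f"choose from {sorted(COGNITIVE_MODELS)}"
        )
    return dict(zip(CONDITION_ORDER, COGNITIVE_MODELS[model]))


def cognitive_rdm(model: str, binary: bool = False) -> np.ndarray:
    """27 x 27 cognitive dissimilarity matrix for one model.

    Entry (i, j) is the absolute difference between the condition codes of
    cells i and j; cost levels inherit their condition's code, so cells
    sharing a condition are maximally similar (dissimilarity 0).  With
    ``binary=True`` entries are 0/1 same/different-code indicators (for the
    three two-level codings this differs from the default only by a scale
    factor; only the linear model genuinely changes).
    """
    codes = cognitive_codes(model)
    cell_codes = np.array([codes[cond] for cond, _ in CONDITION_GRID], float)
    rdm = np.abs(cell_codes[:, None] - cell_codes[None, :])
    if binary:
        rdm = (rdm > 0).astype(float)
    return rdm


def parcel_rdm(patterns: np.ndarray) -> np.ndarray:
    """Correlation-dissimilarity RDM from one parcel's condition patterns.

    ``patterns`` has shape (27, n_voxels): one voxel vector per condition
    cell in canonical grid order.  Entry (i, j) is 1 minus the Pearson
    correlation of the two cells' voxel vectors; bounded in [0, 2].

    Raises
    ------
    DegenerateParcelError
        If the parcel has < 3 finite voxels or any condition's voxel vector
        has zero variance.
    """
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] != N_CELLS:
        raise ValueError(
            f"patterns must be ({N_CELLS}, n_voxels); got {X.shape}"
        )
    if X.shape[1] < 3 or not np.all(np.isfinite(X)):
        raise DegenerateParcelError(
            "parcel needs >= 3 voxels with finite values in every condition"
        )
    if np.any(X.std(axis=1) == 0):
        raise DegenerateParcelError(
            "zero-variance voxel vector in at least one condition"
        )
    r = np.corrcoef(X)
    rdm = 1.0 - r
    np.fill_diagonal(rdm, 0.0)
    return rdm


_TRIL = np.tril_indices(N_CELLS, k=-1)


def vectorize_lower(rdm: np.ndarray) -> np.ndarray:
    """Below-diagonal entries of an RDM in canonical row-major (i > j) order.

    The same fixed order is used for neural and cognitive vectors, so entry
    (2, 1) precedes (3, 1).  For the 27-cell grid the vector has length 351.
    """
    M = np.asarray(rdm, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"RDM must be square; got {M.shape}")
    if not np.allclose(M, M.T, equal_nan=False):
        raise ValueError("RDM is not symmetric")
    if M.shape[0] == N_CELLS:
        return M[_TRIL]
    return M[np.tril_indices(M.shape[0], k=-1)]


def rdm_from_vector(vec: np.ndarray, n: int = N_CELLS) -> np.ndarray:
    """Inverse of :func:`vectorize_lower` (zero diagonal)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1) // 2,):
        raise ValueError(f"expected vector of length {n * (n - 1) // 2}")
    M = np.zeros((n, n))
    idx = np.tril_indices(n, k=-1)
    M[idx] = vec
    return M + M.T


def mixed_rsa(
    neural_vectors: np.ndarray,
    model_vector: np.ndarray,
    parcel_id: int | str = 0,
    model: str = "",
    engine: str = "closed_form",
) -> ParcelResult:
    """Regress neural dissimilarity on a cognitive model vector.

    Fits ``y_pi = a + b * x_i + u_p + e_pi`` with a random intercept per
    participant and one shared slope.  Because the model vector is identical
    across participants and the data are balanced, the GLS slope equals the
    OLS slope on the participant-mean vector and the REML residual variance
    has a closed form; ``engine='closed_form'`` exploits this (it matches
    ``engine='reml'``, which fits ``statsmodels`` MixedLM, to numerical
    precision) and is the default for speed.  Z = estimate / SE with a
    normal reference, two-tailed.
    """
    Y = np.atleast_2d(np.asarray(neural_vectors, dtype=float))
    x = np.asarray(model_vector, dtype=float)
    if Y.shape[1] != x.shape[0]:
        raise ValueError(
            f"vector length mismatch: neural {Y.shape[1]} vs model {x.shape[0]}"
        )
    n_part, n_obs = Y.shape
    if n_part < 3:
        raise ValueError("mixed_rsa needs >= 3 participants")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant model vector: slope not identifiable")

    if engine == "closed_form":
        ybar = Y.mean(axis=0)
        b = float(xc @ (ybar - ybar.mean()) / sxx)
        resid = Y - Y.mean(axis=1, keepdims=True) - b * xc
        dof = n_part * n_obs - n_part - 1
        sigma2 = float((resid**2).sum() / dof)
        se = float(np.sqrt(sigma2 / (n_part * sxx)))
    elif engine == "reml":
        from statsmodels.regression.mixed_linear_model import MixedLM

        exog = np.column_stack([np.ones(n_part * n_obs), np.tile(x, n_part)])
        groups = np.repeat(np.arange(n_part), n_obs)
        try:
            fit = MixedLM(Y.ravel(), exog, groups).fit(reml=True)
            b, se = float(fit.params[1]), float(fit.bse[1])
        except Exception as exc:  # singular fit -> fixed-effects fallback
            log.warning(
                "MixedLM failed for parcel %s (%s); using participant "
                "fixed-effects OLS fallback", parcel_id, exc,
            )
            return _fixed_effects_rsa(Y, x, parcel_id, model)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if se == 0:
        z = 0.0 if b == 0 else np.inf * np.sign(b)
        p = 1.0 if b == 0 else 0.0
    else:
        z = b / se
        p = float(2 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return ParcelResult(
        parcel_id=parcel_id, model=model, coefficient=b, se=se,
        z=float(z), ci_low=b - half, ci_high=b + half, p_raw=p,
    )


def _fixed_effects_rsa(
    Y: np.ndarray, x: np.ndarray, parcel_id, model
) -> ParcelResult:
    """Pooled OLS with participant fixed effects (demeaned regression)."""
    n_part, n_obs = Y.shape
    xc = x - x.mean()
    sxx = float(xc @ xc)
    Yd = Y - Y.mean(axis=1, keepdims=True)
    b = float((Yd @ xc).sum() / (n_part * sxx))
    resid = Yd - b * xc
    dof = n_part * n_obs - n_part - 1
    sigma2 = float((resid**2).sum() / dof)
    se = float(np.sqrt(sigma2 / (n_part * sxx)))
    z = b / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    half = 1.959963984540054 * se
    return ParcelResult(
        parcel_id=parcel_id, model=model, coefficient=b, se=se,
        z=z, ci_low=b - half, ci_high=b + half, p_raw=p,
    )


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fdr_correct(
    results: list[ParcelResult], alpha: float = 0.05
) -> list[ParcelResult]:
    """Attach BH-adjusted p-values and significance flags (p_fdr < alpha)."""
    if not results:
        return results
    adj = bh_adjust(np.array([r.p_raw for r in results]))
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
        r.significant = bool(a < alpha)
    return results


def _parcel_vectors(
    maps: np.ndarray, voxel_idx: np.ndarray
) -> np.ndarray | None:
    """Stack per-participant lower-triangle RDM vectors for one parcel.

    Returns None (caller logs and skips) if the parcel is degenerate for
    any participant.
    """
    vecs = []
    for p in range(maps.shape[0]):
        try:
            rdm = parcel_rdm(maps[p][:, voxel_idx])
        except DegenerateParcelError:
            return None
        vecs.append(vectorize_lower(rdm))
    return np.vstack(vecs)


def rsa_parcels(
    maps: np.ndarray,
    parcellation: np.ndarray,
    models: list[str] | None = None,
    alpha: float = 0.05,
    binary_rdm: bool = False,
) -> pd.DataFrame:
    """Parcel-wise mixed-model RSA with per-model FDR correction.

    Parameters
    ----------
    maps
        (participants, 27, voxels) condition maps in canonical grid order.
    parcellation
        Integer label per voxel; label 0 is background and ignored.
    models
        Cognitive models to regress on (default: all four), each fit
        separately; BH-FDR is applied per model across parcels.

    Returns
    -------
    DataFrame with one row per (parcel, model): coefficient, se, z, CI,
    p_raw, p_fdr, significant.
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(parcellation).ravel()
    if maps.ndim != 3 or maps.shape[1] != N_CELLS:
        raise ValueError(
            f"maps must be (participants, {N_CELLS}, voxels); got {maps.shape}"
        )
    if labels.shape[0] != maps.shape[2]:
        raise ValueError("parcellation length does not match voxel count")
    if models is None:
        models = list(COGNITIVE_MODELS)

    parcel_ids = [int(l) for l in np.unique(labels) if l != 0]
    neural = {}
    skipped = []
    for pid in parcel_ids:
        vecs = _parcel_vectors(maps, np.flatnonzero(labels == pid))
        if vecs is None:
            skipped.append(pid)
        else:
            neural[pid] = vecs
    if skipped:
        log.warning("skipped %d degenerate parcels: %s", len(skipped), skipped)

    rows = []
    for model in models:
        x = vectorize_lower(cognitive_rdm(model, binary=binary_rdm))
        results = [
            mixed_rsa(neural[pid], x, parcel_id=pid, model=model)
            for pid in neural
        ]
        fdr_correct(results, alpha=alpha)
        rows.extend(results)
    return pd.DataFrame([vars(r) for r in rows])


def roi_rsa(
    maps: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    model: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ROI-restricted RSA: each named mask is treated as one parcel.

    FDR correction is applied across the ROI set for the given model.
    """
    maps = np.asarray(maps, dtype=float)
    x = vectorize_lower(cognitive_rdm(model))
    results = []
    for name, mask in roi_masks.items():
        idx = np.flatnonzero(np.asarray(mask).ravel())
        if idx.size == 0:
            raise ValueError(f"ROI {name!r} has an empty mask")
        if idx.size < 3:
            raise ValueError(f"ROI {name!r} has < 3 voxels")
        if idx.max() >= maps.shape[2]:
            raise ValueError(f"ROI {name!r} mask exceeds the map grid")
        vecs = _parcel_vectors(maps, idx)
        if vecs is None:
            log.warning("ROI %s degenerate; skipped", name)
            continue
        results.append(mixed_rsa(vecs, x, parcel_id=name, model=model))
    fdr_correct(results, alpha=alpha)
    return pd.DataFrame([vars(r) for r in results])
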