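"""Synthetic-data generator with known planted structure.

Produces behavioral choices/allocations, rating profiles, voxel-level
condition maps, motive pattern maps, and a parcellation, all with planted
parameters recorded in a manifest so downstream stages can be verified by
parameter recovery.  The behavioral choice model is a logistic stand-in
(the generator's own construct, not an empirical claim); the neural
generator uses a synthetic block voxel layout because the dissimilarity and
expression math is geometry-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import behavior
from .design import (
    CHOICE_ALTRUISTIC,
    CHOICE_STRATEGIC,
    CONDITION_ORDER,
    COSTS,
    ENDOWMENT,
    build_design,
)
from .rsa import CONDITION_GRID, COGNITIVE_MODELS, cognitive_codes

__all__ = [
    "AgentParams",
    "NeuralGenSpec",
    "SimulatedNeuralData",
    "child_seeds",
    "simulate_ratings",
    "simulate_choices",
    "simulate_behavioral_dataset",
    "simulate_condition_maps",
]

_BENEFACTOR_TYPES = (CHOICE_ALTRUISTIC, CHOICE_STRATEGIC)

#: Baseline rating means (0-100 scale) shared by both benefactor types.
_RATING_BASE = {
    "care": 50.0,
    "second_order_belief": 50.0,
    "gratitude": 55.0,
    "guilt": 45.0,
    "obligation": 50.0,
}


@dataclass
class AgentParams:
    """Generative behavioral parameters.

    ``w_communal_by_condition`` / ``w_obligation_by_condition`` are the
    decision weights on the two factor-score differences in each efficiency
    condition (canonical order A1S3, A1S1, A3S1); the defaults plant a
    strictly increasing communal:obligation ratio across conditions so the
    behavioral recovery check has an unambiguous target ordering.
    """

    w_communal_by_condition: tuple[float, float, float] = (0.6, 1.2, 1.8)
    w_obligation_by_condition: tuple[float, float, float] = (1.8, 1.2, 0.6)
    choice_noise_sd: float = 1.0
    allocation_generosity: float = 0.5
    rating_effect_care: float = 20.0
    rating_effect_belief: float = 45.0
    rating_effect_emotions: float = 15.0
    rating_cost_slope: float = 0.5
    rating_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.choice_noise_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.allocation_generosity <= 1:
            raise ValueError("allocation_generosity must lie in [0, 1]")
        if any(w < 0 for w in self.w_communal_by_condition):
            raise ValueError("communal weights must be non-negative")
        if any(w < 0 for w in self.w_obligation_by_condition):
            raise ValueError("obligation weights must be non-negative")


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child seed sequences from one global seed."""
    return np.random.SeedSequence(seed).spawn(n)


def rating_means(
    agent: AgentParams, benefactor_type: str, cost: float,
    ref_cost: float,
) -> dict[str, float]:
    """Noiseless generative rating means for one benefactor type x cost.

    Care, gratitude and guilt are higher for the altruistic benefactor;
    second-order belief and obligation are higher for the strategic one.
    Every gap grows linearly with cost at ``rating_cost_slope`` per yuan and
    equals its nominal effect size at the reference cost.
    """
    sign = 1.0 if benefactor_type == CHOICE_ALTRUISTIC else -1.0
    growth = agent.rating_cost_slope * (cost - ref_cost)
    gap_care = agent.rating_effect_care + growth
    gap_belief = agent.rating_effect_belief + growth
    gap_emotion = agent.rating_effect_emotions + growth
    means = {
        "care": _RATING_BASE["care"] + sign * gap_care / 2,
        "second_order_belief":
            _RATING_BASE["second_order_belief"] - sign * gap_belief / 2,
        "gratitude": _RATING_BASE["gratitude"] + sign * gap_emotion / 2,
        "guilt": _RATING_BASE["guilt"] + sign * gap_emotion / 2,
        "obligation": _RATING_BASE["obligation"] - sign * gap_emotion / 2,
    }
    return means


def simulate_ratings(
    agent: AgentParams,
    n_participants: int,
    costs: tuple[int, ...] = COSTS,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Rating profiles for every participant x benefactor type x cost.

    Six ratings in [0, 100] per cell; indebtedness is a noisy equal blend of
    guilt and obligation (and is excluded from factoring downstream).
    """
    if len(costs) < 2:
        raise ValueError("need at least 2 cost levels")
    rng = np.random.default_rng(seed)
    ref_cost = float(np.mean(costs))
    rows = []
    for p in range(n_participants):
        pid = f"sub-{p + 1:03d}"
        for bt in _BENEFACTOR_TYPES:
            for cost in costs:
                mu = rating_means(agent, bt, cost, ref_cost)
                noisy = {
                    k: float(np.clip(
                        v + rng.normal(0, agent.rating_noise_sd), 0, 100
                    ))
                    for k, v in mu.items()
                }
                noisy["indebtedness"] = float(np.clip(
                    0.5 * (noisy["guilt"] + noisy["obligation"])
                    + rng.normal(0, agent.rating_noise_sd),
                    0, 100,
                ))
                rows.append({"participant_id": pid, "benefactor_type": bt,
                             "cost": cost, **noisy})
    cols = ["participant_id", "benefactor_type", "cost",
            "care", "second_order_belief", "gratitude", "guilt",
            "obligation", "indebtedness"]
    return pd.DataFrame(rows)[cols]


def simulate_choices(
    agent: AgentParams,
    trials: pd.DataFrame,
    deltas: pd.DataFrame,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Fill a design's choice and allocation columns.

    Per trial, P(altruistic) = logistic(w_c[cond] * dc + w_o[cond] * do +
    eps) with eps ~ Normal(0, choice_noise_sd), where (dc, do) are the
    altruistic-minus-strategic factor-score differences for that
    participant's cost cell.  Communal concern attracts toward the
    altruistic benefactor (dc > 0 under the planted rating structure) while
    obligation attracts toward the strategic one (do < 0 enters with its
    natural sign), so planting w_c increasing and w_o decreasing across the
    canonical condition order yields an increasing probability of choosing
    the altruistic benefactor.  Allocation is
    round(allocation_generosity * 25) plus bounded integer noise, clipped to
    [0, 25].
    """
    need = {"participant_id", "cost", "dc", "do"}
    if not need <= set(deltas.columns):
        raise ValueError(f"deltas table must have columns {sorted(need)}")
    rng = np.random.default_rng(seed)
    merged = trials.merge(
        deltas[["participant_id", "cost", "dc", "do"]],
        on=["participant_id", "cost"], how="left",
    )
    if merged[["dc", "do"]].isna().any().any():
        raise ValueError("missing factor scores for some trial cells")
    wc = {c.value: w for c, w in
          zip(CONDITION_ORDER, agent.w_communal_by_condition)}
    wo = {c.value: w for c, w in
          zip(CONDITION_ORDER, agent.w_obligation_by_condition)}
    eta = (
        merged["condition"].map(wc).to_numpy() * merged["dc"].to_numpy()
        + merged["condition"].map(wo).to_numpy() * merged["do"].to_numpy()
        + rng.normal(0, agent.choice_noise_sd, len(merged))
    )
    p_alt = 1.0 / (1.0 + np.exp(-eta))
    altruistic = rng.random(len(merged)) < p_alt
    base_alloc = round(agent.allocation_generosity * ENDOWMENT)
    alloc = np.clip(
        base_alloc + rng.integers(-3, 4, len(merged)), 0, ENDOWMENT
    )
    out = trials.copy()
    out["choice"] = np.where(altruistic, CHOICE_ALTRUISTIC, CHOICE_STRATEGIC)
    out["allocation"] = alloc
    return out


def design_table(n_participants: int, n_runs: int, seed) -> pd.DataFrame:
    """Trial skeleton table for ``n_participants`` independent designs."""
    seqs = np.random.SeedSequence(seed).spawn(n_participants) \
        if not isinstance(seed, np.random.SeedSequence) \
        else seed.spawn(n_participants)
    frames = []
    for p, ss in enumerate(seqs):
        pid = f"sub-{p + 1:03d}"
        d = build_design(
            n_runs, np.random.default_rng(ss).integers(2**31),
            participant_id=pid,
        )
        frames.append(pd.DataFrame(
            [(t.participant_id, t.run, t.condition.value, t.cost)
             for t in d.trials],
            columns=["participant_id", "run", "condition", "cost"],
        ))
    return pd.concat(frames, ignore_index=True)


def simulate_behavioral_dataset(
    agent: AgentParams,
    n_participants: int = 50,
    n_runs: int = 3,
    costs: tuple[int, ...] = COSTS,
    seed: int = 0,
) -> dict:
    """Full behavioral bundle: designs, ratings, factor scores, choices.

    The factor-score differences fed to the choice model are the generated
    ratings projected through the behavior stage's own factor scoring, so
    recovery tests exercise the complete ratings -> factors -> choice path.
    One global seed fans out to per-component child streams.
    """
    ss_design, ss_ratings, ss_choices = child_seeds(seed, 3)
    trials = design_table(n_participants, n_runs, ss_design)
    ratings = simulate_ratings(agent, n_participants, costs, ss_ratings)
    fs = behavior.factor_scores(ratings)
    deltas = behavior.delta_factor_table(fs.scores)
    filled = simulate_choices(agent, trials, deltas, ss_choices)
    return {
        "trials": filled,
        "ratings": ratings,
        "factor_scores": fs,
        "deltas": deltas,
        "agent": agent,
    }


# ---------------------------------------------------------------------------
# Neural generator
# ---------------------------------------------------------------------------

@dataclass
class NeuralGenSpec:
    """Planted structure for the synthetic condition maps.

    Voxel geometry is a block layout: parcel ``p`` owns the contiguous run
    of ``voxels_per_parcel`` voxels starting at ``p * voxels_per_parcel``.
    ``signal_parcels`` maps a cognitive model name to the parcel indices
    (0-based) carrying that model's representational geometry;
    ``a_by_condition`` / ``b_by_condition`` are the planted loadings of the
    communal / obligation motive maps per efficiency condition.  The motive
    maps are constructed orthonormal so the planted loadings are exactly
    identifiable by dot products (a fixture convenience; empirical pattern
    maps need not be orthogonal).
    """

    n_parcels: int = 200
    voxels_per_parcel: int = 50
    signal_parcels: dict[str, tuple[int, ...]] = field(default_factory=dict)
    signal_amplitude: float = 1.0
    neural_noise_sd: float = 0.3
    a_by_condition: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b_by_condition: tuple[float, float, float] = (0.0, 0.0, 0.0)
    angle_per_code: float = 0.5  # radians of pattern rotation per code unit

    def __post_init__(self) -> None:
        if self.neural_noise_sd < 0:
            raise ValueError("neural_noise_sd must be >= 0")
        if self.voxels_per_parcel < 6:
            raise ValueError("voxels_per_parcel must be >= 6")
        for model, parcels in self.signal_parcels.items():
            if model not in COGNITIVE_MODELS:
                raise ValueError(f"unknown cognitive model {model!r}")
            bad = [p for p in parcels if not 0 <= p < self.n_parcels]
            if bad:
                raise ValueError(
                    f"signal parcels {bad} outside [0, {self.n_parcels})"
                )

    @property
    def n_voxels(self) -> int:
        return self.n_parcels * self.voxels_per_parcel

    @classmethod
    def for_expression(
        cls,
        a_by_condition: tuple[float, float, float] = (0.2, 0.5, 0.8),
        b_by_condition: tuple[float, float, float] = (0.8, 0.5, 0.2),
        neural_noise_sd: float = 0.3,
        **kw,
    ) -> "NeuralGenSpec":
        """Preset for pattern-expression recovery: planted monotone motive
        loadings (communal increasing, obligation decreasing across the
        canonical condition order), no parcel-level signal."""
        return cls(
            a_by_condition=a_by_condition, b_by_condition=b_by_condition,
            neural_noise_sd=neural_noise_sd, **kw,
        )

    @classmethod
    def for_rsa(
        cls,
        n_signal_per_model: int = 3,
        signal_amplitude: float = 1.0,
        neural_noise_sd: float = 0.3,
        **kw,
    ) -> "NeuralGenSpec":
        """Preset for RSA recovery: disjoint signal-parcel sets per model,
        zero motive-map loadings (a global motive loading would make every
        parcel weakly signal-bearing and blur the planted ground truth)."""
        spec = cls(
            signal_amplitude=signal_amplitude,
            neural_noise_sd=neural_noise_sd, **kw,
        )
        models = list(COGNITIVE_MODELS)
        spec.signal_parcels = {
            m: tuple(range(i * n_signal_per_model,
                           (i + 1) * n_signal_per_model))
            for i, m in enumerate(models)
        }
        spec.__post_init__()
        return spec


@dataclass
class SimulatedNeuralData:
    """In-memory neural bundle plus the manifest of planted parameters."""

    maps: np.ndarray          # (participants, 27, voxels)
    parcellation: np.ndarray  # (voxels,) integer labels, 1-based
    communal_map: np.ndarray  # (voxels,) unit norm
    obligation_map: np.ndarray
    participant_ids: list[str]
    manifest: dict


def _orthonormal_pair(rng: np.random.Generator, n: int) -> np.ndarray:
    """Two random orthonormal n-vectors (rows)."""
    M = rng.normal(size=(2, n))
    q, _ = np.linalg.qr(M.T)
    return q.T[:2]


def _parcel_basis(
    rng: np.random.Generator, nuisance: np.ndarray
) -> np.ndarray:
    """Two orthonormal parcel-local vectors orthogonal to ``nuisance`` rows.

    Projecting out the constant vector makes the planted geometry exact
    under Pearson correlation; projecting out the motive-map restrictions
    keeps parcel signal from leaking into the expression scores.
    """
    n = nuisance.shape[1]
    U = rng.normal(size=(2, n))
    qn, _ = np.linalg.qr(nuisance.T)
    U = U - (U @ qn) @ qn.T
    q, _ = np.linalg.qr(U.T)
    return q.T[:2]


def simulate_condition_maps(
    spec: NeuralGenSpec,
    n_participants: int,
    seed: int | np.random.SeedSequence = 0,
) -> SimulatedNeuralData:
    """Generate participant x 27-cell voxel maps with planted structure.

    Each cell's voxel vector is the sum of (i) the condition's planted
    motive-map loadings ``a * communal_map + b * obligation_map``, (ii) for
    signal parcels, an amplitude-scaled pattern whose direction rotates with
    the parcel's cognitive-model condition code (so the noiseless parcel RDM
    is a strictly monotone transform of the model's cognitive RDM), and
    (iii) iid Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    V, vpp = spec.n_voxels, spec.voxels_per_parcel
    communal, obligation = _orthonormal_pair(rng, V)
    parcellation = np.repeat(np.arange(1, spec.n_parcels + 1), vpp)

    a = {c.value: v for c, v in zip(CONDITION_ORDER, spec.a_by_condition)}
    b = {c.value: v for c, v in zip(CONDITION_ORDER, spec.b_by_condition)}
    cell_conditions = [cond.value for cond, _ in CONDITION_GRID]

    # per-cell global motive component, shared by all participants
    base = np.array(
        [a[c] * communal + b[c] * obligation for c in cell_conditions]
    )  # (27, V)

    parcel_models = {}  # parcel index -> model name
    for model, parcels in spec.signal_parcels.items():
        for p in parcels:
            if p in parcel_models:
                raise ValueError(f"parcel {p} assigned to multiple models")
            parcel_models[p] = model

    maps = np.empty((n_participants, len(CONDITION_GRID), V))
    for part in range(n_participants):
        data = base + rng.normal(
            0, spec.neural_noise_sd, size=(len(CONDITION_GRID), V)
        ) if spec.neural_noise_sd > 0 else base.copy()
        for p, model in parcel_models.items():
            sl = slice(p * vpp, (p + 1) * vpp)
            nuisance = np.vstack(
                [np.ones(vpp), communal[sl], obligation[sl]]
            )
            U = _parcel_basis(rng, nuisance)  # (2, vpp)
            codes = cognitive_codes(model)
            for i, (cond, _) in enumerate(CONDITION_GRID):
                theta = codes[cond] * spec.angle_per_code
                direction = np.cos(theta) * U[0] + np.sin(theta) * U[1]
                data[i, sl] += (
                    spec.signal_amplitude * np.sqrt(vpp) * direction
                )
        maps[part] = data

    pids = [f"sub-{i + 1:03d}" for i in range(n_participants)]
    manifest = {
        "n_participants": n_participants,
        "n_parcels": spec.n_parcels,
        "voxels_per_parcel": vpp,
        "signal_parcels": {m: list(p) for m, p in
                           spec.signal_parcels.items()},
        "signal_amplitude": spec.signal_amplitude,
        "neural_noise_sd": spec.neural_noise_sd,
        "a_by_condition": list(spec.a_by_condition),
        "b_by_condition": list(spec.b_by_condition),
        "angle_per_code": spec.angle_per_code,
    }
    return SimulatedNeuralData(
        maps=maps, parcellation=parcellation,
        communal_map=communal, obligation_map=obligation,
        participant_ids=pids, manifest=manifest,
    )


def agent_manifest(agent: AgentParams) -> dict:
    """Planted behavioral parameters in a serializable form."""
    d = asdict(agent)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
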