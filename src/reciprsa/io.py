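"""Reading and writing of trial/rating tables (CSV) and NIfTI volumes.

Voxel grids are serialized as (n_voxels, 1, 1) NIfTI volumes: the analysis
is geometry-agnostic, so a flat layout keeps the synthetic bundle simple
while remaining a valid volume for any NIfTI-aware tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import COSTS, CONDITION_ORDER, EfficiencyCondition
from .neural_expression import PatternMap
from .simulate import SimulatedNeuralData

__all__ = [
    "write_trials",
    "read_trials",
    "write_ratings",
    "read_ratings",
    "write_neural_bundle",
    "read_neural_bundle",
    "vector_to_nifti",
    "nifti_to_vector",
]

TRIAL_COLUMNS = ["participant_id", "run", "condition", "cost",
                 "choice", "allocation"]
_CONDITION_VALUES = {c.value for c in CONDITION_ORDER}


def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.reindex(columns=TRIAL_COLUMNS)
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "choice": "object"})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad_cond = set(df["condition"]) - _CONDITION_VALUES
    if bad_cond:
        raise ValueError(f"unknown conditions in trial table: {bad_cond}")
    bad_cost = set(df["cost"]) - set(COSTS)
    if bad_cost:
        raise ValueError(
            f"unknown cost levels in trial table: {sorted(bad_cost)}"
        )
    return df


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def vector_to_nifti(vec: np.ndarray, dtype=np.float32) -> nib.Nifti1Image:
    data = np.asarray(vec).reshape(-1, 1, 1).astype(dtype)
    return nib.Nifti1Image(data, affine=np.eye(4))


def nifti_to_vector(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).ravel()


def _condition_map_name(pid: str, cond: EfficiencyCondition, cost: int) -> str:
    return f"participant-{pid}_cond-{cond.value}_cost-{cost}.nii.gz"


def write_neural_bundle(data: SimulatedNeuralData, outdir) -> Path:
    """Write condition maps, parcellation, motive maps, and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapdir = outdir / "condition_maps"
    mapdir.mkdir(exist_ok=True)
    from .rsa import CONDITION_GRID

    for p, pid in enumerate(data.participant_ids):
        for i, (cond, cost) in enumerate(CONDITION_GRID):
            nib.save(
                vector_to_nifti(data.maps[p, i]),
                mapdir / _condition_map_name(pid, cond, cost),
            )
    nib.save(
        vector_to_nifti(data.parcellation, dtype=np.int32),
        outdir / "parcellation.nii.gz",
    )
    nib.save(vector_to_nifti(data.communal_map),
             outdir / "pattern_communal.nii.gz")
    nib.save(vector_to_nifti(data.obligation_map),
             outdir / "pattern_obligation.nii.gz")
    (outdir / "manifest.json").write_text(
        json.dumps(data.manifest, indent=2, sort_keys=True)
    )
    return outdir


def read_neural_bundle(outdir) -> SimulatedNeuralData:
    """Load a bundle written by :func:`write_neural_bundle`."""
    outdir = Path(outdir)
    from .rsa import CONDITION_GRID

    manifest = json.loads((outdir / "manifest.json").read_text())
    parcellation = nifti_to_vector(outdir / "parcellation.nii.gz").astype(int)
    communal = nifti_to_vector(outdir / "pattern_communal.nii.gz")
    obligation = nifti_to_vector(outdir / "pattern_obligation.nii.gz")

    mapdir = outdir / "condition_maps"
    pids = sorted(
        {f.name.split("_")[0].removeprefix("participant-")
         for f in mapdir.glob("participant-*.nii.gz")}
    )
    maps = np.empty((len(pids), len(CONDITION_GRID), communal.size))
    for p, pid in enumerate(pids):
        for i, (cond, cost) in enumerate(CONDITION_GRID):
            maps[p, i] = nifti_to_vector(
                mapdir / _condition_map_name(pid, cond, cost)
            )
    return SimulatedNeuralData(
        maps=maps, parcellation=parcellation,
        communal_map=communal, obligation_map=obligation,
        participant_ids=pids, manifest=manifest,
    )


def read_pattern_map(path, name: str) -> PatternMap:
    return PatternMap(name=name, weights=nifti_to_vector(path))
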