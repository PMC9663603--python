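"""Artifact serialization: CSV for tables and RDMs, NPZ + JSON sidecar for
dense arrays (epochs, volumes).  Every writer/reader pair round-trips
exactly for identifiers and integers and within representation precision for
reals."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rdm import RDM
from .synth import EpochSet, RatingCatalog, SubjectRDMStack, VolumeResponses

__all__ = [
    "catalog_to_csv",
    "catalog_from_csv",
    "rdm_to_csv",
    "rdm_from_csv",
    "stack_to_dir",
    "stack_from_dir",
    "epochs_to_npz",
    "epochs_from_npz",
    "volume_to_npz",
    "volume_from_npz",
]


def catalog_to_csv(catalog: RatingCatalog, path: str | Path) -> None:
    """Long format: participant, stimulus, category, dimension, rating.

    Repeated presentations are stored with a ``presentation`` column (1 or 2).
    """
    rows = []
    for p in range(catalog.n_participants):
        for s, (stim, cat) in enumerate(zip(catalog.stimulus_ids, catalog.category_labels)):
            for d, dim in enumerate(catalog.dimension_names):
                rows.append((f"p{p:02d}", stim, cat, dim, 1, catalog.ratings[p, s, d]))
        if catalog.repeat_ratings is not None:
            cat_of = dict(zip(catalog.stimulus_ids, catalog.category_labels))
            for s, stim in enumerate(catalog.repeat_ids):
                for d, dim in enumerate(catalog.dimension_names):
                    rows.append((f"p{p:02d}", stim, cat_of[stim], dim, 2,
                                 catalog.repeat_ratings[p, s, d]))
    df = pd.DataFrame(
        rows, columns=["participant", "stimulus", "category", "dimension", "presentation", "rating"]
    )
    df.to_csv(path, index=False)


def catalog_from_csv(path: str | Path) -> RatingCatalog:
    try:
        df = pd.read_csv(path)
    except Exception as err:  # noqa: BLE001 - surface parse context
        raise ValueError(f"cannot parse catalog CSV {path}: {err}") from err
    required = {"participant", "stimulus", "category", "dimension", "presentation", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog CSV {path} missing columns: {sorted(missing)}")
    first = df[df.presentation == 1]
    participants = sorted(first.participant.unique())
    stimuli = list(dict.fromkeys(first.stimulus))
    dims = list(dict.fromkeys(first.dimension))
    cat_of = dict(zip(first.stimulus, first.category))
    pivot = first.pivot_table(
        index=["participant", "stimulus"], columns="dimension", values="rating", sort=False
    )
    ratings = np.empty((len(participants), len(stimuli), len(dims)))
    for pi, p in enumerate(participants):
        block = pivot.loc[p].reindex(stimuli)[dims]
        ratings[pi] = block.to_numpy()
    repeats = df[df.presentation == 2]
    repeat_ids: list[str] = []
    repeat_ratings = None
    if not repeats.empty:
        repeat_ids = list(dict.fromkeys(repeats.stimulus))
        rpivot = repeats.pivot_table(
            index=["participant", "stimulus"], columns="dimension", values="rating", sort=False
        )
        repeat_ratings = np.empty((len(participants), len(repeat_ids), len(dims)))
        for pi, p in enumerate(participants):
            repeat_ratings[pi] = rpivot.loc[p].reindex(repeat_ids)[dims].to_numpy()
    return RatingCatalog(
        stimulus_ids=stimuli,
        category_labels=[cat_of[s] for s in stimuli],
        dimension_names=dims,
        ratings=ratings,
        repeat_ids=repeat_ids,
        repeat_ratings=repeat_ratings,
    )


def rdm_to_csv(rdm: RDM, path: str | Path) -> None:
    """Square CSV with stimulus ids as header row and index column."""
    pd.DataFrame(rdm.values, index=rdm.stimulus_ids, columns=rdm.stimulus_ids).to_csv(path)


def rdm_from_csv(path: str | Path) -> RDM:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as err:  # noqa: BLE001
        raise ValueError(f"cannot parse RDM CSV {path}: {err}") from err
    if list(df.index) != list(df.columns):
        raise ValueError(f"RDM CSV {path}: header row and index column disagree")
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2  # absorb CSV rounding asymmetry
    return RDM(stimulus_ids=[str(s) for s in df.index], values=values)


def stack_to_dir(stack: SubjectRDMStack, outdir: str | Path) -> None:
    """One CSV per subject plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s, sid in enumerate(stack.subject_ids):
        rdm_to_csv(RDM(stimulus_ids=list(stack.stimulus_ids), values=stack.rdms[s]),
                   outdir / f"{sid}.csv")
    manifest = {"subject_ids": list(stack.subject_ids), "stimulus_ids": list(stack.stimulus_ids)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def stack_from_dir(indir: str | Path) -> SubjectRDMStack:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    rdms = []
    for sid in manifest["subject_ids"]:
        rdm = rdm_from_csv(indir / f"{sid}.csv")
        if rdm.stimulus_ids != manifest["stimulus_ids"]:
            raise ValueError(f"subject {sid} stimulus ordering disagrees with manifest")
        rdms.append(rdm.values)
    return SubjectRDMStack(
        subject_ids=manifest["subject_ids"],
        stimulus_ids=manifest["stimulus_ids"],
        rdms=np.stack(rdms),
    )


def _sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def epochs_to_npz(epochs: EpochSet, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, data=epochs.data, timepoints=epochs.timepoints,
             conditions=np.array(epochs.conditions))
    _sidecar(path, {"kind": "EpochSet", "units": "signal (a.u.), time in ms",
                    "dims": ["condition", "trial", "channel", "time"], **(meta or {})})


def epochs_from_npz(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return EpochSet(conditions=[str(c) for c in z["conditions"]],
                        timepoints=z["timepoints"], data=z["data"])


def volume_to_npz(vol: VolumeResponses, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, grid_shape=np.array(vol.grid_shape), mask=vol.mask,
             responses=vol.responses, activation_map=vol.activation_map)
    _sidecar(path, {"kind": "VolumeResponses", "units": "t-value-like",
                    "dims": ["voxel", "condition"], **(meta or {})})


def volume_from_npz(path: str | Path) -> VolumeResponses:
    with np.load(path, allow_pickle=False) as z:
        return VolumeResponses(grid_shape=tuple(int(g) for g in z["grid_shape"]),
                               mask=z["mask"], responses=z["responses"],
                               activation_map=z["activation_map"])
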