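"""Readers and writers for motion collections and artificial-database archives.

Motion CSV schema: columns ``participant,session,repetition,label,
point_index,x,y`` with 32 rows per motion.  Artificial-dataset CSVs add the
columns ``schedule_index,noise_index,ph,pv,theta``.  A database archive is a
directory with ``dataset_00.csv .. dataset_19.csv`` plus ``manifest.json``
recording the configuration, seed and (once assigned) the split.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from motiondda.augment import (
    AnnotatedMotion,
    ArtificialDatabase,
    ArtificialDataset,
    AugmentationConfig,
    DatabaseSplit,
)
from motiondda.shapes import N_POINTS, MotionMatrix

_META_KEYS = ("participant", "session", "repetition")


def motions_to_frame(motions: Sequence[MotionMatrix]) -> pd.DataFrame:
    rows = []
    for m in motions:
        meta = {k: m.meta.get(k, -1) for k in _META_KEYS}
        for i, (x, y) in enumerate(m.points):
            rows.append({**meta, "label": m.label, "point_index": i, "x": x, "y": y})
    return pd.DataFrame(rows)


def save_motions_csv(motions: Sequence[MotionMatrix], path: str | Path) -> None:
    motions_to_frame(motions).to_csv(path, index=False)


def load_motions_csv(path: str | Path) -> list[MotionMatrix]:
    df = pd.read_csv(path)
    motions = []
    for key, grp in df.groupby([*_META_KEYS, "label"], sort=False):
        grp = grp.sort_values("point_index")
        meta = {k: int(v) for k, v in zip(_META_KEYS, key) if v >= 0}
        motions.append(MotionMatrix(grp[["x", "y"]].to_numpy(), key[-1], meta))
    return motions


def save_motions_json(motions: Sequence[MotionMatrix], path: str | Path) -> None:
    records = [
        {"label": m.label, "points": m.points.tolist(), "meta": m.meta} for m in motions
    ]
    Path(path).write_text(json.dumps(records))


def load_motions_json(path: str | Path) -> list[MotionMatrix]:
    records = json.loads(Path(path).read_text())
    return [MotionMatrix(np.array(r["points"]), r["label"], r.get("meta", {})) for r in records]


def load_mendeley_deposit(path: str | Path) -> list[MotionMatrix]:
    """Adapter stub for the deposited VR capture data (Mendeley accession
    10.17632/kbbprxr4nw.1); the deposit's on-disk layout is not standardised,
    so reading it is left to a site-specific implementation."""
    raise NotImplementedError(
        "reading the deposited capture data requires a site-specific adapter; "
        "convert the deposit to the motion CSV/JSON schema and use "
        "load_motions_csv/load_motions_json instead"
    )


def _dataset_to_frame(dataset: ArtificialDataset) -> pd.DataFrame:
    rows = []
    for item in dataset.items:
        m = item.motion
        meta = {k: m.meta.get(k, -1) for k in _META_KEYS}
        for i, (x, y) in enumerate(m.points):
            rows.append({
                **meta, "label": m.label, "point_index": i, "x": x, "y": y,
                "schedule_index": item.schedule_index, "noise_index": item.noise_index,
                "ph": item.ph, "pv": item.pv, "theta": item.theta,
            })
    return pd.DataFrame(rows)


def _dataset_from_frame(df: pd.DataFrame, dataset_index: int) -> ArtificialDataset:
    items = []
    keys = ["label", "schedule_index", "noise_index"]
    for key, grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("point_index")
        first = grp.iloc[0]
        meta = {k: int(first[k]) for k in _META_KEYS if first[k] >= 0}
        items.append(AnnotatedMotion(
            MotionMatrix(grp[["x", "y"]].to_numpy(), key[0], meta),
            schedule_index=int(key[1]), noise_index=int(key[2]),
            ph=float(first["ph"]), pv=float(first["pv"]), theta=float(first["theta"]),
        ))
    return ArtificialDataset(items, dataset_index=dataset_index)


def save_database(database: ArtificialDatabase, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, ds in enumerate(database.datasets):
        _dataset_to_frame(ds).to_csv(directory / f"dataset_{i:02d}.csv", index=False,
                                     float_format="%.12g")
    manifest = {"config": asdict(database.config)}
    if database.split is not None:
        manifest["split"] = {
            "test": list(database.split.test),
            "folds": [[list(tr), list(va)] for tr, va in database.split.folds],
            "unused": list(database.split.unused),
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_database(directory: str | Path) -> ArtificialDatabase:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    raw = manifest["config"]
    for k in ("range_ph", "range_pv", "range_theta"):
        if raw.get(k) is not None:
            raw[k] = tuple(raw[k])
    config = AugmentationConfig(**raw)
    datasets = []
    for i in range(config.n_datasets):
        df = pd.read_csv(directory / f"dataset_{i:02d}.csv")
        datasets.append(_dataset_from_frame(df, i))
    db = ArtificialDatabase(datasets, config)
    if "split" in manifest:
        s = manifest["split"]
        db.split = DatabaseSplit(
            test=tuple(s["test"]),
            folds=[(tuple(tr), tuple(va)) for tr, va in s["folds"]],
            unused=tuple(s["unused"]),
        )
    return db
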