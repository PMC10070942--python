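"""Reading and writing the pipeline's on-disk formats.

Label movies are multi-page TIFF (one 3D stack per frame, or a 4D stack);
lineage trees are JSON; feature and contact tracks are tidy CSV (one row per
cell x frame / pair x frame); nucleus sets are CSV (frame, x, y, z, name).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from morphodyn.lineage import Cell, LineageTree
from morphodyn.match import NucleusSet
from morphodyn.morphometry import ContactTrack, FeatureTrack, LabeledVolume


@dataclass
class EmbryoRecord:
    """Loaded per-embryo data in the shape the analyses expect."""

    embryo_id: str
    tree: LineageTree
    tracks: dict[str, FeatureTrack]
    contacts: dict[tuple[str, str], ContactTrack]


def write_lineage(tree: LineageTree, path: str | Path) -> None:
    data = {
        "n_frames": tree.n_frames,
        "frame_interval_s": tree.frame_interval_s,
        "cells": [
            {
                "name": c.name,
                "parent": c.parent,
                "birth_frame": c.birth_frame,
                "anaphase_frame": c.anaphase_frame,
                "division_frame": c.division_frame,
            }
            for c in sorted(tree, key=lambda c: c.name)
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_lineage(path: str | Path) -> LineageTree:
    data = json.loads(Path(path).read_text())
    cells = {
        d["name"]: Cell(
            name=d["name"],
            parent=d["parent"],
            birth_frame=d["birth_frame"],
            anaphase_frame=d.get("anaphase_frame"),
            division_frame=d.get("division_frame"),
        )
        for d in data["cells"]
    }
    return LineageTree(cells, n_frames=data["n_frames"], frame_interval_s=data["frame_interval_s"])


def write_labels(frames: list[LabeledVolume], path: str | Path) -> None:
    """Write a label movie as a 4D TIFF plus a JSON sidecar with metadata."""
    stack = np.stack([f.grid for f in frames]).astype(np.int32)
    tifffile.imwrite(path, stack)
    meta = {
        "spacing": list(frames[0].spacing),
        "frames": [f.frame for f in frames],
        "times_min": [f.time_min for f in frames],
        "names": {str(k): v for k, v in (frames[0].names or {}).items()},
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_labels(path: str | Path) -> list[LabeledVolume]:
    stack = tifffile.imread(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    names = {int(k): v for k, v in meta["names"].items()} or None
    return [
        LabeledVolume(
            grid=stack[i],
            spacing=tuple(meta["spacing"]),
            frame=meta["frames"][i],
            time_min=meta["times_min"][i],
            names=names,
        )
        for i in range(stack.shape[0])
    ]


def features_to_frame(tracks: dict[str, FeatureTrack], embryo_id: str = "") -> pd.DataFrame:
    rows = []
    for name, tr in sorted(tracks.items()):
        for i, f in enumerate(tr.frames):
            row = {"embryo": embryo_id, "cell": name, "frame": int(f),
                   "time_min": float(tr.times_min[i]), "normalized": tr.normalized}
            for k, v in tr.features.items():
                if k == "centroid":
                    row["cx"], row["cy"], row["cz"] = map(float, v[i])
                elif np.ndim(v[i]) == 0:
                    row[k] = float(v[i])
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(df: pd.DataFrame) -> dict[str, FeatureTrack]:
    skip = {"embryo", "cell", "frame", "time_min", "normalized", "cx", "cy", "cz"}
    out = {}
    for name, g in df.groupby("cell"):
        g = g.sort_values("frame")
        feats = {c: g[c].to_numpy(float) for c in g.columns if c not in skip}
        if {"cx", "cy", "cz"} <= set(g.columns):
            feats["centroid"] = g[["cx", "cy", "cz"]].to_numpy(float)
        out[str(name)] = FeatureTrack(
            cell=str(name),
            frames=g["frame"].to_numpy(int),
            times_min=g["time_min"].to_numpy(float),
            features=feats,
            normalized=bool(g["normalized"].iloc[0]) if "normalized" in g else False,
        )
    return out


def contacts_to_frame(
    contacts: dict[tuple[str, str], ContactTrack], embryo_id: str = ""
) -> pd.DataFrame:
    rows = []
    for (a, b), ct in sorted(contacts.items()):
        for f, area in zip(ct.frames, ct.areas):
            rows.append(
                {"embryo": embryo_id, "cell_a": a, "cell_b": b,
                 "frame": int(f), "area": float(area)}
            )
    return pd.DataFrame(rows)


def frame_to_contacts(df: pd.DataFrame) -> dict[tuple[str, str], ContactTrack]:
    out = {}
    for (a, b), g in df.groupby(["cell_a", "cell_b"]):
        g = g.sort_values("frame")
        pair = (min(a, b), max(a, b))
        out[pair] = ContactTrack(
            pair=pair, frames=g["frame"].to_numpy(int), areas=g["area"].to_numpy(float)
        )
    return out


def write_nuclei(nsets: list[NucleusSet], path: str | Path) -> None:
    rows = []
    for ns in nsets:
        for i, p in enumerate(ns.points):
            rows.append(
                {"frame": ns.frame, "x": p[0], "y": p[1], "z": p[2],
                 "name": ns.names[i] if ns.names else ""}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nuclei(path: str | Path) -> list[NucleusSet]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for f, g in df.groupby("frame"):
        names = [str(n) for n in g["name"]] if (g["name"].astype(str) != "").all() else None
        out.append(NucleusSet(points=g[["x", "y", "z"]].to_numpy(float), frame=int(f), names=names))
    return out


def load_embryo_dir(path: str | Path) -> EmbryoRecord:
    """Load one embryo's directory (lineage.json, features.csv, contacts.csv)."""
    path = Path(path)
    tree = read_lineage(path / "lineage.json")
    tracks = frame_to_features(pd.read_csv(path / "features.csv"))
    cfile = path / "contacts.csv"
    contacts = {}
    if cfile.exists():
        df = pd.read_csv(cfile)
        if len(df):
            contacts = frame_to_contacts(df)
    return EmbryoRecord(embryo_id=path.name, tree=tree, tracks=tracks, contacts=contacts)
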