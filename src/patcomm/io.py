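"""Readers and writers for the dataset file formats.

Patterns are stored as long CSV (pattern_id, index, x, y) with a JSON
sidecar carrying each pattern's generator spec, seed and source class;
drawings as dot-level CSV; descriptions as JSON lines; ratings as CSV.
Grammar fits export both a JSON document and a flat CSV fit table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import KernelSpec
from .reconstruction import Drawing
from .simulate import GameDataset
from .text import Description
from .patterns import Pattern

__all__ = [
    "write_patterns", "read_patterns",
    "write_drawings", "read_drawings",
    "write_descriptions", "read_descriptions",
    "write_ratings", "read_ratings",
    "write_game_dataset", "read_game_dataset",
    "write_matched_set", "grammar_fit_frame",
]


def write_patterns(patterns: list[Pattern], csv_path, sidecar_path=None) -> None:
    rows = []
    meta = {}
    for p in patterns:
        for i, (x, y) in enumerate(zip(p.x, p.y)):
            rows.append({"pattern_id": p.pattern_id, "index": i, "x": x, "y": y})
        meta[p.pattern_id] = {
            "generator": json.loads(p.generator.to_json()),
            "seed": p.seed,
            "source_class": p.source_class,
        }
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_patterns(csv_path, sidecar_path=None) -> list[Pattern]:
    df = pd.read_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    out = []
    for pid, grp in df.groupby("pattern_id", sort=False):
        grp = grp.sort_values("index")
        m = meta[str(pid)]
        out.append(
            Pattern(
                pattern_id=str(pid),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                source_class=m["source_class"],
                generator=KernelSpec.from_json(json.dumps(m["generator"])),
                seed=m.get("seed"),
            )
        )
    return out


def write_drawings(drawings: list[Drawing], csv_path) -> None:
    rows = [
        {"drawer_id": d.drawer_id, "pattern_id": d.pattern_id,
         "dot_index": i, "x": x, "y": y}
        for d in drawings
        for i, (x, y) in enumerate(d.dots)
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_drawings(csv_path) -> list[Drawing]:
    df = pd.read_csv(csv_path)
    out = []
    for (wid, pid), grp in df.groupby(["drawer_id", "pattern_id"], sort=False):
        grp = grp.sort_values("dot_index")
        out.append(Drawing(grp[["x", "y"]].to_numpy(), drawer_id=str(wid), pattern_id=str(pid)))
    return out


def write_descriptions(descriptions: list[Description], path) -> None:
    with open(path, "w") as fh:
        for d in descriptions:
            fh.write(json.dumps({
                "describer_id": d.describer_id, "pattern_id": d.pattern_id,
                "text": d.text, "judge_rating": d.judge_rating,
            }) + "\n")


def read_descriptions(path) -> list[Description]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            obj = json.loads(line)
            out.append(Description(obj["describer_id"], obj["pattern_id"],
                                   obj["text"], obj.get("judge_rating")))
    return out


def write_ratings(ratings: pd.DataFrame, csv_path) -> None:
    ratings.to_csv(csv_path, index=False)


def read_ratings(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_game_dataset(dataset: GameDataset, out_dir) -> None:
    """Write the four dataset files plus the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_patterns(dataset.patterns, out / "patterns.csv", out / "patterns.json")
    write_descriptions(dataset.descriptions, out / "descriptions.jsonl")
    write_drawings(dataset.drawings, out / "drawings.csv")
    write_ratings(dataset.ratings, out / "ratings.csv")
    (out / "ground_truth.json").write_text(json.dumps(dataset.ground_truth, indent=1))


def read_game_dataset(out_dir) -> GameDataset:
    out = Path(out_dir)
    from .reconstruction import spline_resample

    patterns = read_patterns(out / "patterns.csv", out / "patterns.json")
    drawings = read_drawings(out / "drawings.csv")
    grid = patterns[0].x
    for d in drawings:
        spline_resample(d, grid)
    return GameDataset(
        patterns=patterns,
        descriptions=read_descriptions(out / "descriptions.jsonl"),
        drawings=drawings,
        ratings=read_ratings(out / "ratings.csv"),
        ground_truth=json.loads((out / "ground_truth.json").read_text()),
    )


def write_matched_set(matched, out_dir) -> None:
    """Write a matched stimulus set: pattern files plus a JSON manifest of
    pairings and matching statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_patterns(matched.patterns, out / "patterns.csv", out / "patterns.json")
    manifest = {
        "compositional": [p.pattern_id for p in matched.compositional],
        "noncompositional": [p.pattern_id for p in matched.noncompositional],
        "pairs": matched.match_stats.to_dict(orient="records"),
    }
    (out / "matched_set.json").write_text(json.dumps(manifest, indent=1))


def grammar_fit_frame(pattern_id: str, gf) -> pd.DataFrame:
    """Flat per-structure fit table (pattern_id, structure, log_ml, converged)."""
    df = gf.to_frame()
    df.insert(0, "pattern_id", pattern_id)
    return df[["pattern_id", "structure", "log_ml", "converged"]]
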