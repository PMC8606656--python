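"""Reading and writing the delimited-text formats of the pipeline.

The fixation table dialect: UTF-8 delimited text (comma or tab,
auto-detected) with header columns ``subject_id, image_id, x, y,
label``. Coordinates are 0-based pixel floats, origin top-left; the
label is +1/-1 and must be constant within a subject. Rows falling
outside the canvas are dropped and counted in an audit record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .density import FixationDataset
from .dictionary import BowFeature, Dictionary

__all__ = [
    "read_fixations",
    "write_fixations",
    "read_dictionary",
    "write_dictionary",
    "write_bow_features",
    "read_bow_features",
    "write_eval_report",
    "write_provenance",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "image_id", "x", "y", "label")


def read_fixations(path, canvas: tuple = (700.0, 500.0)):
    """Read a fixation table; returns ``(FixationDataset, audit_dict)``.

    Enforces per-subject label consistency (hard error naming the
    offending subject) and drops out-of-canvas rows with an audit count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no fixation rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["image_id"] = df["image_id"].astype(str)
    bad = df.groupby("subject_id")["label"].nunique()
    bad = bad[bad > 1]
    if len(bad):
        raise ValueError(
            f"{path}: inconsistent labels for subject(s) {', '.join(bad.index)}"
        )
    in_canvas = (
        (df["x"] >= 0) & (df["x"] <= canvas[0]) & (df["y"] >= 0) & (df["y"] <= canvas[1])
    )
    n_dropped = int((~in_canvas).sum())
    if n_dropped:
        logger.warning("%s: dropped %d out-of-canvas rows", path, n_dropped)
    df = df[in_canvas]
    if df.empty:
        raise ValueError(f"{path}: all rows fell outside the canvas")
    data = FixationDataset(
        points=df[["x", "y"]].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        subject_ids=df["subject_id"].to_numpy(),
        image_ids=df["image_id"].to_numpy(),
    )
    return data, {"n_rows": len(df), "n_dropped": n_dropped}


def write_fixations(data: FixationDataset, path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": data.subject_ids.astype(str),
            "image_id": data.image_ids.astype(str),
            "x": data.points[:, 0],
            "y": data.points[:, 1],
            "label": data.labels,
        }
    )
    df.to_csv(path, index=False)


def write_dictionary(dictionary: Dictionary, path) -> None:
    """One row per word (index, x, y, method_tag) plus a metadata header."""
    path = Path(path)
    meta = {
        "method": dictionary.method_tag,
        "K": dictionary.K,
        "h": dictionary.h,
        "seed": dictionary.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# gazedict dictionary {json.dumps(meta)}\n")
        fh.write("word,x,y,method_tag\n")
        for k, (x, y) in enumerate(dictionary.centroids):
            fh.write(f"{k},{float(x)!r},{float(y)!r},{dictionary.method_tag}\n")


def read_dictionary(path) -> Dictionary:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("# gazedict dictionary"):
        meta = json.loads(first.split("dictionary", 1)[1])
    df = pd.read_csv(path, comment="#")
    return Dictionary(
        centroids=df[["x", "y"]].to_numpy(dtype=float),
        method_tag=str(df["method_tag"].iloc[0]),
        h=meta.get("h"),
        seed=meta.get("seed"),
        provenance=meta,
    )


def write_bow_features(features: list[BowFeature], path) -> None:
    K = len(features[0].histogram)
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "image_id": f.image_id, "label": f.label}
        row.update({f"w{k}": f.histogram[k] for k in range(K)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bow_features(path) -> list[BowFeature]:
    df = pd.read_csv(path)
    wcols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
    wcols.sort(key=lambda c: int(c[1:]))
    feats = []
    for _, row in df.iterrows():
        hist = row[wcols].to_numpy(dtype=float)
        feats.append(
            BowFeature(
                histogram=hist / hist.sum(),
                n_fixations=max(int(round(1.0 / hist[hist > 0].min())), 1),
                subject_id=str(row["subject_id"]),
                image_id=str(row["image_id"]),
                label=int(row["label"]),
            )
        )
    return feats


def write_trajectories(trajectories, path) -> None:
    """Dump seeking trajectories as long-format delimited text.

    Columns: kernel index, iteration, x, y, objective value, initial
    sign — enough to redraw per-iteration shift visualizations.
    """
    rows = []
    for i, t in enumerate(trajectories):
        for step, (pos, q) in enumerate(zip(t.positions, t.q_values)):
            rows.append(
                {"kernel": i, "iteration": step, "x": pos[0], "y": pos[1],
                 "q": q, "initial_sign": t.initial_sign}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_eval_report(result, out_prefix) -> dict:
    """Write the metric summary (JSON), per-subject scores and ROC (CSV)."""
    out_prefix = Path(out_prefix)
    summary = {
        "method": result.method_tag,
        "params": result.params,
        "threshold": result.threshold,
        "accuracy": result.accuracy,
        "auc": result.auc,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "confusion": {"tp": result.tp, "fp": result.fp, "tn": result.tn, "fn": result.fn},
        "notes": result.notes,
    }
    with open(out_prefix.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    pd.DataFrame(
        {
            "subject_id": result.subject_ids,
            "score": result.subject_scores,
            "label": result.subject_labels,
        }
    ).to_csv(out_prefix.parent / (out_prefix.name + "_subjects.csv"), index=False)
    pd.DataFrame(result.roc_points, columns=["fpr", "tpr"]).to_csv(
        out_prefix.parent / (out_prefix.name + "_roc.csv"), index=False
    )
    return summary


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_provenance(artifact_path, config: dict, seed: int) -> Path:
    """Sidecar JSON naming the seed and config hash that produced a file."""
    from . import __version__

    artifact_path = Path(artifact_path)
    record = {
        "artifact": artifact_path.name,
        "seed": seed,
        "config": config,
        "config_sha256": config_hash(config),
        "gazedict_version": __version__,
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    out = artifact_path.parent / (artifact_path.name + ".provenance.json")
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, default=str)
    return out
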