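"""Readers and writers for the pipeline's on-disk formats.

Recordings are multipage TIFF (8-bit grayscale) or directories of
numbered PNGs; detections, tracks, population scores and plates are
CSV (comma-separated, UTF-8, header row, '.' decimal, times in hours at
2 decimals); corpora are JSON-lines; validation results and run
manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .imaging import Detection, FrameStack
from .ranking import Corpus, LooValidation, RankedList
from .rtquic import RtQuicPlate, frame_to_plate, plate_to_frame
from .simulate.worms import GroundTruth
from .tracking import PopulationResult, Track

# ---------------------------------------------------------------- recordings


def write_recording(stack: FrameStack, path: "str | Path") -> None:
    """Write a frame stack as an 8-bit grayscale multipage TIFF."""
    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = (np.clip(frames, 0.0, 1.0) * 255).astype(np.uint8)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def read_recording(path: "str | Path", fps: float) -> FrameStack:
    """Read a multipage TIFF or a directory of numbered PNGs."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
    if frames.dtype == np.uint8:
        frames = frames.astype(np.float32) / 255.0
    return FrameStack(frames=frames, fps=fps)


def write_ground_truth(truth: GroundTruth, path: "str | Path") -> None:
    """Ground-truth CSV: frame, worm_id, posture, x, y."""
    n_worms, n_frames = truth.posture.shape
    rows = {
        "frame": np.repeat(np.arange(n_frames), n_worms),
        "worm_id": np.tile(np.arange(n_worms), n_frames),
        "posture": truth.posture.T.ravel(),
        "x": truth.centroids[:, :, 0].T.ravel(),
        "y": truth.centroids[:, :, 1].T.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- detections


def detections_to_frame(detections_per_frame: "list[list[Detection]]") -> pd.DataFrame:
    rows = [
        {
            "frame": d.frame_index,
            "object_id": d.object_id,
            "area_px2": d.area,
            "perimeter_px": d.perimeter,
            "circularity": d.circularity,
            "x": d.centroid[0],
            "y": d.centroid[1],
            "posture": d.posture,
        }
        for frame in detections_per_frame
        for d in frame
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "object_id", "area_px2", "perimeter_px",
            "circularity", "x", "y", "posture",
        ],
    )


def write_detections(detections_per_frame, path: "str | Path") -> None:
    detections_to_frame(detections_per_frame).to_csv(path, index=False)


def read_detections(path: "str | Path") -> "list[list[Detection]]":
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    per_frame: list[list[Detection]] = [[] for _ in range(n_frames)]
    for r in df.itertuples():
        per_frame[int(r.frame)].append(
            Detection(
                frame_index=int(r.frame),
                object_id=int(r.object_id),
                area=float(r.area_px2),
                perimeter=float(r.perimeter_px),
                circularity=float(r.circularity),
                centroid=(float(r.x), float(r.y)),
                posture=None if pd.isna(r.posture) else str(r.posture),
            )
        )
    return per_frame


# ------------------------------------------------------------------- tracks


def write_tracks(tracks: "list[Track]", path: "str | Path") -> None:
    rows = [
        {
            "track_id": t.track_id,
            "frame": d.frame_index,
            "circularity": d.circularity,
            "x": d.centroid[0],
            "y": d.centroid[1],
        }
        for t in tracks
        for d in t.detections
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "circularity", "x", "y"]).to_csv(
        path, index=False
    )


def write_population_results(
    results: "dict[str, PopulationResult]", path: "str | Path"
) -> None:
    rows = [
        {
            "population_id": pid,
            "n_tracks": r.n_tracks,
            "coiler_score_pct": r.coiler_score,
            "mean_speed_px_s": r.mean_speed,
            "frames_used": r.frames_used,
            "frames_dropped": r.frames_dropped,
        }
        for pid, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------- corpus


def write_corpus(corpus: Corpus, path: "str | Path") -> None:
    """JSON-lines: one record per document (doc_id, entity, role, text)."""
    with open(path, "w", encoding="utf-8") as fh:
        for entity in sorted(corpus.entity_map):
            for doc_id in sorted(corpus.entity_map[entity]):
                rec = {
                    "doc_id": doc_id,
                    "entity": entity,
                    "role": corpus.roles[entity],
                    "text": " ".join(corpus.documents[doc_id]),
                }
                fh.write(json.dumps(rec) + "\n")


def read_corpus(path: "str | Path") -> Corpus:
    documents: dict[str, list[str]] = {}
    entity_map: dict[str, set[str]] = {}
    roles: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            documents[rec["doc_id"]] = rec["text"].lower().split()
            entity_map.setdefault(rec["entity"], set()).add(rec["doc_id"])
            roles[rec["entity"]] = rec["role"]
    return Corpus(documents=documents, entity_map=entity_map, roles=roles)


# ------------------------------------------------------------------ ranking


def write_ranking(ranked: RankedList, path: "str | Path") -> None:
    pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked.candidates) + 1),
            "entity": ranked.candidates,
            "score": [ranked.scores[c] for c in ranked.candidates],
        }
    ).to_csv(path, index=False)


def write_validation(loo: LooValidation, path: "str | Path") -> None:
    payload = {
        "auc": loo.auc,
        "average_precision": loo.average_precision,
        "ranksum_p": loo.ranksum_p,
        "holdout_ranks": loo.holdout_ranks,
        "holdout_scores": loo.holdout_scores,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_curve(points: np.ndarray, columns: "tuple[str, str]", path) -> None:
    pd.DataFrame(points, columns=list(columns)).to_csv(path, index=False)


# -------------------------------------------------------------------- plates


def write_plate(plate: RtQuicPlate, path: "str | Path") -> None:
    plate_to_frame(plate).to_csv(path, index=False)


def read_plate(path: "str | Path") -> RtQuicPlate:
    return frame_to_plate(pd.read_csv(path))


# ----------------------------------------------------------------- manifests


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    path: "str | Path", *, stage: str, config: dict, inputs: "list[str]",
    outputs: "list[str]", seed: "int | None" = None,
) -> None:
    """Run manifest: everything needed to reproduce the outputs."""
    manifest = {
        "stage": stage,
        "config": config,
        "config_hash": config_hash(config),
        "inputs": inputs,
        "outputs": outputs,
        "seed": seed,
        "python": sys.version.split()[0],
        "package_version": _package_version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def _package_version() -> str:
    from . import __version__

    return __version__
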