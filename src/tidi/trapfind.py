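"""Trap detection, grid indexing, cross-frame linking, and ROI cropping.

The detector contract: anything that maps a brightfield frame to a list of
:class:`TrapDetection` is acceptable.  The default backend is normalized
cross-correlation (NCC) against a trap template with greedy non-maximum
suppression — a classical stand-in for a learned detector, adequate because
trap structures are rigid and near-identical.

Traps are indexed row-major on the grid (cluster y-centers into rows, sort
by x within a row), linked frame-to-frame by nearest centroid, and only
traps trackable through the entire series are retained; crops of fixed size
(default 56x72 W x H) around each tracked trap form the per-trap image
dataset, whose size is exactly (number of complete tracks) x (timepoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template, peak_local_max


@dataclass(frozen=True)
class TrapDetection:
    frame_index: int
    bbox: tuple[float, float, float, float]   # (x, y, w, h), half-open
    score: float

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2, y + h / 2)


def _iou(a, b):
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    return inter / (aw * ah + bw * bh - inter) if inter else 0.0


def detect_traps(frame: np.ndarray, template: np.ndarray,
                 score_threshold: float = 0.8, nms_iou: float = 0.3,
                 frame_index: int = 0) -> list[TrapDetection]:
    """NCC template matching + greedy NMS on a single brightfield frame.

    Scores are the correlation coefficient clipped to [0, 1].  NMS keeps the
    higher score; exact ties break toward smaller (y, x).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty image")
    if template.shape[0] > frame.shape[0] or template.shape[1] > frame.shape[1]:
        raise ValueError("template larger than frame")
    corr = match_template(frame, template, pad_input=True)
    th, tw = template.shape
    peaks = peak_local_max(corr, min_distance=max(2, min(th, tw) // 3),
                           threshold_abs=score_threshold, exclude_border=False)
    cand = []
    for (py, px) in peaks:
        score = float(np.clip(corr[py, px], 0.0, 1.0))
        cand.append(TrapDetection(frame_index,
                                  (px - tw / 2, py - th / 2, tw, th), score))
    # greedy NMS: best score first, ties by (y, x)
    cand.sort(key=lambda d: (-d.score, d.bbox[1], d.bbox[0]))
    kept: list[TrapDetection] = []
    for det in cand:
        if all(_iou(det.bbox, k.bbox) <= nms_iou for k in kept):
            kept.append(det)
    return kept


def index_grid(detections: list[TrapDetection],
               layout_hint: tuple[int, int] | None = None) -> dict[int, int]:
    """Row-major grid ids for a set of detections.

    Rows come from 1-D gap clustering of y-centers (boundary where the gap
    exceeds half the estimated row pitch); within a row, ids increase with
    x.  Returns ``{index_into_detections: trap_id}``; deterministic and
    invariant to the input ordering of equal detections.
    """
    if not detections:
        raise ValueError("need at least one detection")
    centers = np.array([d.center for d in detections])
    heights = np.array([d.bbox[3] for d in detections])
    order = np.argsort(centers[:, 1], kind="stable")
    ys = centers[order, 1]
    gaps = np.diff(ys)
    min_row_gap = 0.6 * float(np.median(heights))
    if layout_hint is not None and layout_hint[0] > 1:
        # take the (rows-1) largest gaps as boundaries
        k = layout_hint[0] - 1
        idx = np.argsort(gaps)[::-1][:k]
        boundaries = np.zeros(len(gaps), dtype=bool)
        boundaries[idx] = gaps[idx] > 1e-9
    else:
        big = gaps[gaps > min_row_gap]
        if len(big) == 0:
            boundaries = np.zeros(len(gaps), dtype=bool)
        else:
            pitch = float(np.median(big))
            tol = pitch / 2
            boundaries = gaps > tol
            if not boundaries.all() and (gaps[~boundaries] > tol).any():
                warnings.warn("ambiguous row clustering; best-effort ids")
    row_of = np.zeros(len(ys), dtype=int)
    row_of[1:] = np.cumsum(boundaries)
    mapping: dict[int, int] = {}
    tid = 0
    for r in range(row_of.max() + 1):
        members = order[row_of == r]
        for i in members[np.argsort(centers[members, 0], kind="stable")]:
            mapping[int(i)] = tid
            tid += 1
    return mapping


@dataclass
class TrackSet:
    """Per-trap tracks: boxes (n_tracks, n_frames, 4) with NaN where a trap
    was not found in a frame."""

    trap_ids: np.ndarray           # (n_tracks,)
    boxes: np.ndarray              # (n_tracks, n_frames, 4) float
    present: np.ndarray            # (n_tracks, n_frames) bool
    scores: np.ndarray | None = None

    @property
    def n_tracks(self) -> int:
        return len(self.trap_ids)

    @property
    def n_frames(self) -> int:
        return self.boxes.shape[1]

    @property
    def complete(self) -> np.ndarray:
        return self.present.all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        comp = self.complete
        for i, tid in enumerate(self.trap_ids):
            for f in range(self.n_frames):
                x, y, w, h = self.boxes[i, f]
                s = self.scores[i, f] if self.scores is not None else np.nan
                rows.append((int(tid), f, x, y, w, h, s, bool(comp[i])))
        return pd.DataFrame(rows, columns=["trap_id", "frame", "x", "y",
                                           "w", "h", "score", "complete"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrackSet":
        tids = np.array(sorted(df["trap_id"].unique()))
        n_frames = int(df["frame"].max()) + 1
        boxes = np.full((len(tids), n_frames, 4), np.nan)
        present = np.zeros((len(tids), n_frames), dtype=bool)
        scores = np.full((len(tids), n_frames), np.nan)
        pos = {t: i for i, t in enumerate(tids)}
        for rec in df.itertuples(index=False):
            i = pos[rec.trap_id]
            boxes[i, rec.frame] = (rec.x, rec.y, rec.w, rec.h)
            present[i, rec.frame] = np.isfinite(rec.x)
            scores[i, rec.frame] = rec.score
        return cls(tids, boxes, present, scores)


def link_tracks(per_frame_detections: list[list[TrapDetection]],
                max_shift_px: float = 5.0,
                layout_hint: tuple[int, int] | None = None) -> TrackSet:
    """Nearest-centroid frame-to-frame association.

    Frame-0 detections seed the tracks (ids from :func:`index_grid`); no new
    tracks start later.  In each subsequent frame, tracks claim their
    nearest detection within ``max_shift_px`` of the last known position,
    closest pairs first, each detection used at most once.  A frame with no
    match leaves a gap, which marks the track incomplete.
    """
    if not per_frame_detections:
        raise ValueError("need at least one frame")
    first = per_frame_detections[0]
    if not first:
        raise ValueError("no detections in frame 0")
    ids = index_grid(first, layout_hint)
    n_frames = len(per_frame_detections)
    n_tracks = len(first)
    boxes = np.full((n_tracks, n_frames, 4), np.nan)
    present = np.zeros((n_tracks, n_frames), dtype=bool)
    scores = np.full((n_tracks, n_frames), np.nan)
    trap_ids = np.empty(n_tracks, dtype=int)
    last_center = np.empty((n_tracks, 2))
    for det_idx, tid in ids.items():
        d = first[det_idx]
        boxes[tid, 0] = d.bbox
        present[tid, 0] = True
        scores[tid, 0] = d.score
        trap_ids[tid] = tid
        last_center[tid] = d.center

    for f in range(1, n_frames):
        dets = per_frame_detections[f]
        if not dets:
            continue
        centers = np.array([d.center for d in dets])
        # all candidate (track, detection) pairs within gate, closest first
        diff = last_center[:, None, :] - centers[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        ti, di = np.nonzero(dist <= max_shift_px)
        order = np.argsort(dist[ti, di], kind="stable")
        used_t, used_d = set(), set()
        for k in order:
            t, dj = int(ti[k]), int(di[k])
            if t in used_t or dj in used_d:
                continue
            used_t.add(t)
            used_d.add(dj)
            boxes[t, f] = dets[dj].bbox
            present[t, f] = True
            scores[t, f] = dets[dj].score
            last_center[t] = dets[dj].center
    order = np.argsort(trap_ids)
    return TrackSet(trap_ids[order], boxes[order], present[order],
                    scores[order])


def filter_complete(tracks: TrackSet, n_frames: int | None = None) -> TrackSet:
    """Keep only traps identified in every frame of the series."""
    if n_frames is not None and n_frames != tracks.n_frames:
        keep = tracks.present[:, :n_frames].all(axis=1)
    else:
        keep = tracks.complete
    if not keep.any():
        warnings.warn("no complete tracks retained")
    return TrackSet(tracks.trap_ids[keep], tracks.boxes[keep],
                    tracks.present[keep],
                    None if tracks.scores is None else tracks.scores[keep])


class CropDataset:
    """Lazy per-trap, per-frame crop accessor over an image stack.

    ``len(ds)`` is exactly (number of complete tracks) x (timepoints); crops
    are materialized on demand, centered on the tracked box center, clipped
    and zero-padded at canvas edges.  ``stack`` may be an ndarray
    (frames, C, H, W) or any object supporting ``stack[frame] -> (C, H, W)``.
    """

    def __init__(self, stack, tracks: TrackSet, crop_w: int = 56,
                 crop_h: int = 72):
        if not tracks.complete.all():
            raise ValueError("crop_rois requires complete tracks only")
        self.stack = stack
        self.tracks = tracks
        self.crop_w, self.crop_h = crop_w, crop_h

    @property
    def n_traps(self) -> int:
        return self.tracks.n_tracks

    @property
    def n_frames(self) -> int:
        return self.tracks.n_frames

    def __len__(self) -> int:
        return self.n_traps * self.n_frames

    def get(self, track_index: int, frame: int) -> np.ndarray:
        frm = self.stack[frame]
        x, y, w, h = self.tracks.boxes[track_index, frame]
        cx, cy = x + w / 2, y + h / 2
        x0 = int(round(cx - self.crop_w / 2))
        y0 = int(round(cy - self.crop_h / 2))
        C, H, W = frm.shape
        if x0 >= W or y0 >= H or x0 + self.crop_w <= 0 or y0 + self.crop_h <= 0:
            raise ValueError(
                f"bbox fully outside canvas: trap "
                f"{self.tracks.trap_ids[track_index]} frame {frame}")
        out = np.zeros((C, self.crop_h, self.crop_w), dtype=frm.dtype)
        xa, xb = max(0, x0), min(W, x0 + self.crop_w)
        ya, yb = max(0, y0), min(H, y0 + self.crop_h)
        out[:, ya - y0:yb - y0, xa - x0:xb - x0] = frm[:, ya:yb, xa:xb]
        return out

    def trap_series(self, track_index: int) -> list[np.ndarray]:
        return [self.get(track_index, f) for f in range(self.n_frames)]


def crop_rois(stack, tracks: TrackSet, crop_w: int = 56,
              crop_h: int = 72) -> CropDataset:
    """Build the per-trap image dataset from complete tracks.

    The dataset size obeys the accounting identity
    |dataset| = (#complete traps) x (#timepoints).
    """
    return CropDataset(stack, tracks, crop_w, crop_h)
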