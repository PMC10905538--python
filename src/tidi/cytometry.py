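"""Per-trap cell counting, E:T population assignment, and death-event calling.

At t=0 each trap's tumor and NK fluorescent channels are counted
independently with circular blob detection, the (n_nk, n_tumor) pair maps to
one of the tracked effector:target populations (1:0, 0:1, 1:1, 2:1, 3:1, or
other/empty), and the population is assumed constant for the rest of the
series.  A death event is the first frame at which caspase-reporter signal
covers a sufficient fraction of the tumor mask and persists for k
consecutive frames; its time is frame_index x frame interval.  The output
is a per-trap event table: trap_id, event time (h), status code (1 = death
event occurred, 2 = no mediated cell death event), population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.feature import blob_log
from skimage.transform import hough_circle, hough_circle_peaks
from skimage import feature as _skfeature

POPULATIONS = ("1:0", "0:1", "1:1", "2:1", "3:1", "other/empty")

# channel indices within a 4-channel crop (brightfield, tumor, NK, caspase)
CH_TUMOR, CH_NK, CH_CASPASE = 1, 2, 3


def assign_population(n_nk: int, n_tumor: int) -> str:
    """Map per-trap cell counts to the tracked E:T population label.

    (E, T) = (1..3, 1) are the coculture ratios; (>=1, 0) is the NK-only
    control, (0, >=1) the tumor-only control; everything else (including
    empty traps) is "other/empty".
    """
    if n_nk < 0 or n_tumor < 0:
        raise ValueError("counts must be >= 0")
    if n_tumor == 1 and n_nk in (1, 2, 3):
        return f"{n_nk}:1"
    if n_tumor == 0 and n_nk >= 1:
        return "1:0"
    if n_nk == 0 and n_tumor >= 1:
        return "0:1"
    return "other/empty"


# fluorescence below this many counts over background is treated as empty;
# well under one cell's peak brightness but far above sensor noise
MIN_SIGNAL = 1000.0
INTENSITY_SCALE = 5000.0


def _count_channel_log(chan: np.ndarray, radius_range, sensitivity) -> int:
    lo, hi = radius_range
    img = chan.astype(float)
    bg = np.median(img)
    if img.max() - bg < MIN_SIGNAL:
        return 0
    norm = np.clip((img - bg) / INTENSITY_SCALE, 0, 2)
    threshold = max(0.05, 0.5 * (1.0 - sensitivity))
    blobs = blob_log(norm, min_sigma=lo / np.sqrt(2), max_sigma=hi / np.sqrt(2),
                     num_sigma=6, threshold=threshold)
    return len(blobs)


def _count_channel_hough(chan: np.ndarray, radius_range, sensitivity) -> int:
    lo, hi = radius_range
    img = chan.astype(float)
    if img.max() - np.median(img) < MIN_SIGNAL:
        return 0
    img = (img - img.min()) / max(np.ptp(img), 1.0)
    edges = _skfeature.canny(img, sigma=1.5)
    radii = np.arange(max(1, int(lo)), int(hi) + 1)
    h = hough_circle(edges, radii)
    accum, *_ = hough_circle_peaks(h, radii, threshold=1.0 - sensitivity,
                                   min_xdistance=int(lo), min_ydistance=int(lo))
    return len(accum)


def _central_roi(chan: np.ndarray, roi: tuple[int, int] | None) -> np.ndarray:
    """Central (w, h) window of a crop channel; crops are wider than the
    trap pitch, so counting on the full crop would pick up neighbors."""
    if roi is None:
        return chan
    H, W = chan.shape
    w, h = min(roi[0], W), min(roi[1], H)
    x0, y0 = (W - w) // 2, (H - h) // 2
    return chan[y0:y0 + h, x0:x0 + w]


def count_cells_t0(crop_t0: np.ndarray,
                   radius_range_px: tuple[float, float] = (2.5, 7.0),
                   sensitivity: float = 0.85,
                   method: str = "log",
                   roi: tuple[int, int] | None = (36, 46),
                   ) -> tuple[int, int]:
    """Count tumor and NK cells in a 4-channel t=0 crop.

    Each fluorescent channel is counted independently inside the central
    ``roi`` window (the trap interior; None = whole crop); ``method``
    selects Laplacian-of-Gaussian blob detection (default, robust on
    diffraction-limited spots) or a circular Hough transform.  Returns
    (n_tumor, n_nk).
    """
    if radius_range_px[0] > radius_range_px[1]:
        raise ValueError("radius range inverted")
    counter = {"log": _count_channel_log, "hough": _count_channel_hough}[method]
    n_tumor = counter(_central_roi(crop_t0[CH_TUMOR], roi),
                      radius_range_px, sensitivity)
    n_nk = counter(_central_roi(crop_t0[CH_NK], roi),
                   radius_range_px, sensitivity)
    return n_tumor, n_nk


def census_trap(crop_t0, **kwargs) -> dict:
    """Count + label a single trap at t=0."""
    n_tumor, n_nk = count_cells_t0(crop_t0, **kwargs)
    return {"n_tumor": n_tumor, "n_nk": n_nk,
            "population": assign_population(n_nk, n_tumor)}


def call_death(crops_over_time: list[np.ndarray],
               caspase_threshold: float = 1500.0,
               overlap_rule: float = 0.3,
               persistence_k: int = 2,
               frame_interval_h: float = 1 / 3,
               tumor_threshold: float | None = None,
               roi: tuple[int, int] | None = (36, 46)) -> float | None:
    """First persistent caspase-positive frame over the tumor mask.

    The tumor mask comes from the t=0 tumor channel (thresholded, central
    ``roi`` window only so neighboring traps cannot trigger calls); a frame
    is caspase-positive when at least ``overlap_rule`` of that mask exceeds
    ``caspase_threshold`` in the reporter channel.  The event is the first
    frame beginning a run of ``persistence_k`` consecutive positives; at
    most one event per trap.  Returns the event time in hours, or None.
    """
    if tumor_threshold is None:
        tumor_threshold = caspase_threshold
    tumor_mask = _central_roi(crops_over_time[0][CH_TUMOR],
                              roi).astype(float) > tumor_threshold
    area = int(tumor_mask.sum())
    if area == 0:
        return None
    positive = np.array([
        (_central_roi(crop[CH_CASPASE], roi).astype(float)
         > caspase_threshold)[tumor_mask].mean() >= overlap_rule
        for crop in crops_over_time])
    run = 0
    for f, pos in enumerate(positive):
        run = run + 1 if pos else 0
        if run >= persistence_k:
            first = f - persistence_k + 1
            return first * frame_interval_h
    # a positive run truncated by the end of the series still counts: there
    # are no later frames in which persistence could have been observed
    if run > 0:
        return (len(positive) - run) * frame_interval_h
    return None


def build_event_table(census: pd.DataFrame, calls: dict[int, float | None],
                      run_id: str = "run1", line_id: str = "synthetic",
                      ) -> pd.DataFrame:
    """Assemble the per-trap event table schema.

    ``census`` needs columns trap_id, population (or n_tumor/n_nk to derive
    it); ``calls`` maps trap_id -> event time in hours or None.  Death calls
    for traps without tumor content are ignored.  Columns: trap_id,
    event_time_h (NaN if none), status_code, population, run_id, line_id.
    """
    census = census.copy()
    if census["trap_id"].duplicated().any():
        raise ValueError("duplicate trap_id in census")
    if "population" not in census:
        census["population"] = [assign_population(r.n_nk, r.n_tumor)
                                for r in census.itertuples(index=False)]
    rows = []
    for rec in census.itertuples(index=False):
        t = calls.get(int(rec.trap_id))
        if t is not None and rec.population not in ("0:1", "1:1", "2:1", "3:1"):
            t = None            # no tumor to die
        rows.append((int(rec.trap_id),
                     np.nan if t is None else float(t),
                     2 if t is None else 1,
                     rec.population, run_id, line_id))
    return pd.DataFrame(rows, columns=["trap_id", "event_time_h",
                                       "status_code", "population",
                                       "run_id", "line_id"])


def population_counts(table: pd.DataFrame) -> pd.Series:
    """Marginal trap counts per population (partition of all traps)."""
    return table["population"].value_counts().reindex(
        POPULATIONS, fill_value=0)
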