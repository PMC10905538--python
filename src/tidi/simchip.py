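"""Synthetic trap-array time-lapse generator with exact ground truth.

Emulates a microfluidic hydrodynamic cell-trapping device imaged in four
confocal channels (brightfield, tumor tracker, NK tracker, caspase-3/7
reporter) over a 24-h time course at 20-min intervals.  Every downstream
stage of the pipeline (trap detection, tracking, cell counting, death-event
calling, survival estimation) can be validated against the ground truth this
module writes.

The death model is exponential per effector:target (E:T) population: a trap
of population p with at least one tumor cell draws a death time
``t ~ Exp(hazard[p])``; times are snapped UP to the next imaging frame
because events are only observable at frame times, and times past the
imaging horizon are censored there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile

from .cytometry import assign_population

# default render geometry (pixels); a reduced-magnification view of the
# device so that a full 30x29 grid renders on a ~1350x1700 canvas
DEFAULT_TRAP_SIZE = (28, 36)   # (w, h)
DEFAULT_PITCH = (42, 56)       # (x, y)
DEFAULT_MARGIN = 40

# channel order, fixed across the package
CH_BRIGHTFIELD, CH_TUMOR, CH_NK, CH_CASPASE = 0, 1, 2, 3
N_CHANNELS = 4

# intensity model (uint16 counts)
_BG_BF = 500.0
_TRAP_EDGE = 3000.0
_BG_FLUO = 150.0
_CELL_AMP = 8000.0
_CASP_AMP = 6000.0


def full_scale_geometry() -> dict:
    """Trap/pitch sizes at the native stitched-image scale (a 30x29 grid
    fills a ~3796x4641 px canvas)."""
    return {"trap_size": (56, 72), "pitch": (126, 160), "margin": 80}


@dataclass
class ChipLayout:
    """Trap-grid geometry: per-trap centers (row-major) and broken flags."""

    rows: int
    cols: int
    trap_w_px: int
    trap_h_px: int
    pitch_x_px: float
    pitch_y_px: float
    centers: np.ndarray          # (N, 2) float, (x, y)
    broken: np.ndarray           # (N,) bool
    jitter_px: float = 0.0

    @property
    def n_traps(self) -> int:
        return len(self.centers)

    @property
    def intact_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.broken)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["centers"] = self.centers.tolist()
        d["broken"] = self.broken.astype(int).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "ChipLayout":
        with open(path) as fh:
            d = json.load(fh)
        d["centers"] = np.asarray(d["centers"], dtype=float)
        d["broken"] = np.asarray(d["broken"], dtype=bool)
        return cls(**d)


def generate_layout(
    rows: int,
    cols: int,
    trap_size: tuple[int, int] = DEFAULT_TRAP_SIZE,
    pitch: tuple[float, float] = DEFAULT_PITCH,
    broken_fraction: float = 0.0,
    jitter_px: float = 0.0,
    seed: int = 0,
    margin: float = DEFAULT_MARGIN,
) -> ChipLayout:
    """Lay out a rows x cols trap grid with optional positional jitter and a
    fixed fraction of broken (undetectable) traps.

    The number of broken traps is exactly ``round(broken_fraction * rows *
    cols)``, drawn uniformly without replacement.  Deterministic per seed.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not 0 <= broken_fraction < 1:
        raise ValueError("broken_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    xs = margin + pitch[0] * np.arange(cols)
    ys = margin + pitch[1] * np.arange(rows)
    gx, gy = np.meshgrid(xs, ys)              # row-major: y outer, x inner
    centers = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    if jitter_px > 0:
        centers = centers + rng.uniform(-jitter_px, jitter_px, centers.shape)
    n = rows * cols
    broken = np.zeros(n, dtype=bool)
    n_broken = int(round(broken_fraction * n))
    if n_broken:
        broken[rng.choice(n, size=n_broken, replace=False)] = True
    return ChipLayout(rows, cols, trap_size[0], trap_size[1],
                      pitch[0], pitch[1], centers, broken, jitter_px)


def generate_composite_layout(blocks, **kwargs) -> ChipLayout:
    """Stack several (rows, cols) blocks vertically into one device.

    Mirrors split-architecture devices such as "15 x 30 + 15 x 31"
    (915 traps): blocks share pitch and are separated by one extra pitch.
    """
    seed = kwargs.pop("seed", 0)
    layouts = [generate_layout(r, c, seed=seed + i, **kwargs)
               for i, (r, c) in enumerate(blocks)]
    pitch_y = layouts[0].pitch_y_px
    centers, broken = [], []
    y_off = 0.0
    for lay in layouts:
        c = lay.centers.copy()
        c[:, 1] += y_off
        centers.append(c)
        broken.append(lay.broken)
        y_off += lay.rows * pitch_y + pitch_y
    first = layouts[0]
    return ChipLayout(
        rows=sum(l.rows for l in layouts), cols=max(l.cols for l in layouts),
        trap_w_px=first.trap_w_px, trap_h_px=first.trap_h_px,
        pitch_x_px=first.pitch_x_px, pitch_y_px=pitch_y,
        centers=np.concatenate(centers), broken=np.concatenate(broken),
        jitter_px=first.jitter_px)


def sample_occupancy(
    layout: ChipLayout,
    p_tumor: float = 0.75,
    nk_count_probs: dict[int, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw stochastic trap occupancy: one Bernoulli tumor cell and a
    categorical 0-3 NK count per intact trap.

    Defaults emulate seeding in which most traps receive a tumor cell and
    NK counts concentrate on 0-1 with a tail to 2-3.  Returns a DataFrame
    with columns trap_id, n_tumor, n_nk (one row per non-broken trap).
    """
    if nk_count_probs is None:
        nk_count_probs = {0: 0.25, 1: 0.45, 2: 0.2, 3: 0.1}
    if not 0 <= p_tumor <= 1:
        raise ValueError("p_tumor must be in [0, 1]")
    counts = np.array(sorted(nk_count_probs))
    probs = np.array([nk_count_probs[k] for k in counts], dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("nk_count_probs values must be in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("nk_count_probs must sum to 1")
    rng = np.random.default_rng(seed)
    ids = layout.intact_ids
    n_tumor = (rng.random(len(ids)) < p_tumor).astype(int)
    n_nk = rng.choice(counts, size=len(ids), p=probs)
    return pd.DataFrame({"trap_id": ids, "n_tumor": n_tumor, "n_nk": n_nk})


# per-population default hazards (events per hour); tumor-only control has a
# small background death rate, NK-containing populations kill faster with E
DEFAULT_HAZARDS = {"0:1": 0.002, "1:1": 0.02, "2:1": 0.03, "3:1": 0.04,
                   "1:0": 0.0, "other/empty": 0.002}


def sample_events(
    occupancy: pd.DataFrame,
    hazards: dict[str, float] | None = None,
    horizon_h: float = 24.0,
    frame_interval_h: float = 1 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw exponential death times per trap and snap them to the frame grid.

    Only traps containing at least one tumor cell can register a death.
    Raw (unsnapped) times are kept in ``raw_time_h`` for distributional
    checks; the observable ``event_time_h`` is the raw time rounded UP to
    the next frame.  Times past the horizon are censored (status 2).
    """
    hazards = dict(DEFAULT_HAZARDS if hazards is None else hazards)
    if any(v < 0 for v in hazards.values()):
        raise ValueError("hazards must be >= 0")
    n_steps = horizon_h / frame_interval_h
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("horizon must be a multiple of the frame interval")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in occupancy.itertuples(index=False):
        pop = assign_population(rec.n_nk, rec.n_tumor)
        lam = hazards.get(pop, 0.0)
        raw = np.inf
        if rec.n_tumor >= 1 and lam > 0:
            raw = rng.exponential(1.0 / lam)
        if np.isfinite(raw) and raw <= horizon_h:
            snapped = np.ceil(raw / frame_interval_h - 1e-12) * frame_interval_h
            snapped = max(snapped, frame_interval_h)
            if snapped <= horizon_h:
                rows.append((rec.trap_id, pop, snapped, 1, raw))
                continue
        rows.append((rec.trap_id, pop, np.nan, 2,
                     raw if np.isfinite(raw) else np.nan))
    return pd.DataFrame(rows, columns=["trap_id", "population",
                                       "event_time_h", "status_code",
                                       "raw_time_h"])


@dataclass
class RenderConfig:
    """Rendering parameters for the synthetic time-lapse."""

    n_frames: int = 73                      # t=0 plus 72 20-min intervals
    frame_interval_h: float = 1 / 3
    cell_radius_px: float = 4.0
    noise_sigma: float = 80.0               # gaussian, uint16 counts
    drift_px_per_frame: tuple[float, float] = (0.25, 0.1)
    seed: int = 0
    channels: tuple[str, ...] = ("brightfield", "tumor", "nk", "caspase")

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def horizon_h(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_h


def canvas_shape(layout: ChipLayout, cfg: RenderConfig,
                 margin: float = DEFAULT_MARGIN) -> tuple[int, int]:
    """(H, W) canvas that contains the grid plus full accumulated drift."""
    dx, dy = cfg.drift_px_per_frame
    w = layout.centers[:, 0].max() + margin + abs(dx) * (cfg.n_frames - 1)
    h = layout.centers[:, 1].max() + margin + abs(dy) * (cfg.n_frames - 1)
    return int(np.ceil(h)), int(np.ceil(w))


def _cell_positions(layout, occupancy, seed):
    """Static within-trap cell positions: one draw per trap, reused across
    frames (trapped cells do not migrate in v1)."""
    out = {}
    for rec in occupancy.itertuples(index=False):
        rng = np.random.default_rng((seed, int(rec.trap_id)))
        cx, cy = layout.centers[rec.trap_id]
        w, h = layout.trap_w_px, layout.trap_h_px
        tumor = []
        if rec.n_tumor:
            tumor = [(cx + rng.uniform(-w / 8, w / 8),
                      cy + rng.uniform(-h / 8, h / 8))
                     for _ in range(rec.n_tumor)]
        nk = []
        angles = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi,
                                                         rec.n_nk,
                                                         endpoint=False)
        for a in angles:
            nk.append((cx + 0.28 * w * np.cos(a), cy + 0.30 * h * np.sin(a)))
        out[int(rec.trap_id)] = (tumor, nk)
    return out


def _stamp(img, x, y, radius, amp):
    """Add a gaussian disk at (x, y), clipped to the canvas."""
    sigma = radius / 1.6
    r = int(np.ceil(3 * sigma))
    x0, y0 = int(round(x)), int(round(y))
    h, w = img.shape
    xa, xb = max(0, x0 - r), min(w, x0 + r + 1)
    ya, yb = max(0, y0 - r), min(h, y0 + r + 1)
    if xa >= xb or ya >= yb:
        return
    xs = np.arange(xa, xb) - x
    ys = np.arange(ya, yb) - y
    g = np.exp(-(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * sigma ** 2))
    img[ya:yb, xa:xb] += amp * g


def trap_template(trap_w: int = DEFAULT_TRAP_SIZE[0],
                  trap_h: int = DEFAULT_TRAP_SIZE[1],
                  edge: int = 2, pad: int = 3) -> np.ndarray:
    """Noise-free brightfield appearance of one trap (U-shaped weir walls),
    usable as the NCC template for detection."""
    h, w = trap_h + 2 * pad, trap_w + 2 * pad
    img = np.full((h, w), _BG_BF, dtype=float)
    _draw_trap(img, w / 2, h / 2, trap_w, trap_h, edge)
    return img


def _draw_trap(img, cx, cy, tw, th, edge=2):
    """U-shaped trap wall: two side walls and a bottom weir, open at top."""
    h, w = img.shape
    x0, x1 = int(round(cx - tw / 2)), int(round(cx + tw / 2))
    y0, y1 = int(round(cy - th / 2)), int(round(cy + th / 2))
    x0c, x1c = max(0, x0), min(w, x1)
    y0c, y1c = max(0, y0), min(h, y1)
    if x0c >= x1c or y0c >= y1c:
        return
    # side walls
    img[y0c:y1c, max(0, x0):min(w, x0 + edge)] = _TRAP_EDGE
    img[y0c:y1c, max(0, x1 - edge):min(w, x1)] = _TRAP_EDGE
    # bottom weir
    img[max(0, y1 - edge):min(h, y1), x0c:x1c] = _TRAP_EDGE


def truth_boxes(layout: ChipLayout, cfg: RenderConfig,
                frame_idx: int) -> np.ndarray:
    """Ground-truth (x, y, w, h) boxes (0-based, half-open) for every trap at
    a given frame, including the accumulated global drift."""
    dx, dy = cfg.drift_px_per_frame
    c = layout.centers + np.array([dx, dy]) * frame_idx
    w, h = layout.trap_w_px, layout.trap_h_px
    return np.column_stack([c[:, 0] - w / 2, c[:, 1] - h / 2,
                            np.full(len(c), w), np.full(len(c), h)])


def render_frame(layout, occupancy, truth, cfg: RenderConfig,
                 frame_idx: int, shape=None) -> np.ndarray:
    """Render one 4-channel frame (C, H, W) uint16."""
    if shape is None:
        shape = canvas_shape(layout, cfg)
    H, W = shape
    if (layout.centers[:, 0].max() + layout.trap_w_px / 2 > W
            or layout.centers[:, 1].max() + layout.trap_h_px / 2 > H):
        raise ValueError("canvas too small for layout")
    rng = np.random.default_rng((cfg.seed, frame_idx))
    dx, dy = cfg.drift_px_per_frame
    ox, oy = dx * frame_idx, dy * frame_idx
    t_h = frame_idx * cfg.frame_interval_h

    bf = np.full((H, W), _BG_BF, dtype=float)
    tu = np.full((H, W), _BG_FLUO, dtype=float)
    nk = np.full((H, W), _BG_FLUO, dtype=float)
    cp = np.full((H, W), _BG_FLUO, dtype=float)

    for tid in range(layout.n_traps):
        if layout.broken[tid]:
            continue
        cx, cy = layout.centers[tid]
        _draw_trap(bf, cx + ox, cy + oy, layout.trap_w_px, layout.trap_h_px)

    positions = _cell_positions(layout, occupancy, cfg.seed)
    events = truth.set_index("trap_id") if truth is not None else None
    for tid, (tumor, nks) in positions.items():
        for (x, y) in tumor:
            _stamp(tu, x + ox, y + oy, cfg.cell_radius_px, _CELL_AMP)
        for (x, y) in nks:
            _stamp(nk, x + ox, y + oy, cfg.cell_radius_px, _CELL_AMP)
        if events is not None and tid in events.index:
            ev = events.loc[tid]
            et = ev["event_time_h"]
            if ev["status_code"] == 1 and t_h >= et - 1e-9 and tumor:
                for (x, y) in tumor:
                    _stamp(cp, x + ox, y + oy, cfg.cell_radius_px, _CASP_AMP)

    out = np.stack([bf, tu, nk, cp])
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0, cfg.noise_sigma, out.shape)
    return np.clip(out, 0, 65535).astype(np.uint16)


class LazyStack:
    """Frame-on-demand view of a synthetic stack: ``stack[i] -> (C, H, W)``.

    Avoids materializing all frames for large devices; frames are
    deterministic functions of (config seed, frame index).
    """

    def __init__(self, layout, occupancy, truth, cfg):
        self.layout, self.occupancy, self.truth, self.cfg = (
            layout, occupancy, truth, cfg)
        self.shape_hw = canvas_shape(layout, cfg)

    def __len__(self):
        return self.cfg.n_frames

    def __getitem__(self, i):
        if not 0 <= i < len(self):
            raise IndexError(i)
        return render_frame(self.layout, self.occupancy, self.truth,
                            self.cfg, i, self.shape_hw)

    @property
    def n_channels(self):
        return N_CHANNELS


def render_stack(layout, occupancy, truth, cfg: RenderConfig,
                 out_dir=None, materialize: bool = True):
    """Render the full 4-channel stack; optionally write TIFF + ground truth.

    Returns the stack as (n_frames, 4, H, W) uint16 when ``materialize``,
    else a :class:`LazyStack`.  When ``out_dir`` is given, writes
    ``stack.tif`` (frame-major multi-page), ``ground_truth_traps.csv``,
    ``ground_truth_events.csv`` and ``layout.json``.
    """
    lazy = LazyStack(layout, occupancy, truth, cfg)
    stack = (np.stack([lazy[i] for i in range(cfg.n_frames)])
             if materialize else lazy)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if materialize:
            tifffile.imwrite(out / "stack.tif", stack,
                             photometric="minisblack")
        else:
            with tifffile.TiffWriter(out / "stack.tif") as tw:
                for i in range(cfg.n_frames):
                    tw.write(lazy[i][None], contiguous=True,
                             photometric="minisblack")
        write_ground_truth(layout, occupancy, truth, cfg, out)
    return stack


def write_ground_truth(layout, occupancy, truth, cfg, out_dir) -> None:
    """Write trap geometry and event truth CSVs (byte-stable per seed)."""
    import pathlib

    out = pathlib.Path(out_dir)
    boxes = truth_boxes(layout, cfg, 0)
    traps = pd.DataFrame({
        "trap_id": np.arange(layout.n_traps),
        "row": np.arange(layout.n_traps) // layout.cols,
        "col": np.arange(layout.n_traps) % layout.cols,
        "x": boxes[:, 0], "y": boxes[:, 1],
        "w": boxes[:, 2], "h": boxes[:, 3],
        "broken": layout.broken.astype(int),
    })
    occ = occupancy.set_index("trap_id")
    traps["n_tumor"] = traps["trap_id"].map(occ["n_tumor"]).fillna(0).astype(int)
    traps["n_nk"] = traps["trap_id"].map(occ["n_nk"]).fillna(0).astype(int)
    traps.to_csv(out / "ground_truth_traps.csv", index=False,
                 float_format="%.4f")
    ev = truth.copy()
    ev["censor_time_h"] = cfg.horizon_h
    ev.to_csv(out / "ground_truth_events.csv", index=False,
              float_format="%.6f")
    layout.to_json(out / "layout.json")
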