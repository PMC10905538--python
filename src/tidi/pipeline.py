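"""Orchestration and format plumbing: simulate -> detect -> cytometry ->
survive -> panel as one reproducible run driven by a single YAML config.

Each stage consumes the previous stage's declared outputs from the run
directory; a manifest (parameters, output hashes, versions) is written at
the end so any output can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import simchip, trapfind, cytometry, survival

log = logging.getLogger("tidi")

VALID_STATUS = {1, 2}
EVENT_COLUMNS = ["trap_id", "event_time_h", "status_code", "population",
                 "run_id", "line_id"]


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """All stage parameters for one end-to-end run."""

    out_dir: str = "tidi_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "detect", "cytometry", "survive"])
    # simulate
    rows: int = 10
    cols: int = 10
    broken_fraction: float = 0.02
    jitter_px: float = 1.0
    p_tumor: float = 0.75
    nk_count_probs: dict = field(default_factory=lambda: {
        0: 0.25, 1: 0.45, 2: 0.2, 3: 0.1})
    hazards: dict = field(default_factory=lambda: dict(simchip.DEFAULT_HAZARDS))
    n_frames: int = 73
    frame_interval_h: float = 1 / 3
    noise_sigma: float = 80.0
    drift_px_per_frame: tuple = (0.25, 0.1)
    # detect
    score_threshold: float = 0.8
    nms_iou: float = 0.3
    max_shift_px: float = 5.0
    crop_w: int = 56
    crop_h: int = 72
    # cytometry
    caspase_threshold: float = 1500.0
    overlap_rule: float = 0.3
    persistence_k: int = 2
    radius_range_px: tuple = (2.5, 7.0)
    sensitivity: float = 0.85
    # survive
    response_threshold: float = 0.75
    normalize: bool = True
    line_id: str = "synthetic"
    run_id: str = "run1"
    # panel (optional stage)
    expression_path: str | None = None
    panel_path: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_px_per_frame"] = list(d["drift_px_per_frame"])
        d["radius_range_px"] = list(d["radius_range_px"])
        d["nk_count_probs"] = {int(k): float(v)
                               for k, v in d["nk_count_probs"].items()}
        return d

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("drift_px_per_frame", "radius_range_px"):
            if key in d:
                d[key] = tuple(d[key])
        if "nk_count_probs" in d:
            d["nk_count_probs"] = {int(k): float(v)
                                   for k, v in d["nk_count_probs"].items()}
        return cls(**d)


# ---------------------------------------------------------------- IO

def write_event_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_event_table(path) -> pd.DataFrame:
    """Read and validate an event-table CSV schema."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad = df[~df["status_code"].isin(VALID_STATUS)]
    if len(bad):
        raise ValueError(
            f"invalid status codes at rows {bad.index.tolist()[:10]}: "
            f"{sorted(bad['status_code'].unique())}")
    inconsistent = df[(df["status_code"] == 1) & df["event_time_h"].isna()
                      | (df["status_code"] == 2) & df["event_time_h"].notna()]
    if len(inconsistent):
        raise ValueError(
            f"status/event-time mismatch at rows "
            f"{inconsistent.index.tolist()[:10]}")
    return df


def write_tracks(tracks: trapfind.TrackSet, path) -> None:
    tracks.to_frame().to_csv(path, index=False, float_format="%.3f")


def read_tracks(path) -> trapfind.TrackSet:
    return trapfind.TrackSet.from_frame(pd.read_csv(path))


def read_expression(path):
    """Load a processed gene-by-cell matrix as AnnData (h5ad/MTX dir/CSV).

    CSV input is genes x cells with gene symbols in the first column; MTX
    input is a directory with matrix.mtx, genes.tsv (or features.tsv) and
    barcodes.tsv.  Values are assumed already normalized and logarithmized.
    """
    import anndata

    p = pathlib.Path(path)
    if p.suffix == ".h5ad":
        return anndata.read_h5ad(p)
    if p.is_dir():
        import scipy.io as sio

        X = sio.mmread(p / "matrix.mtx").tocsr().T  # cells x genes
        genes_file = (p / "genes.tsv" if (p / "genes.tsv").exists()
                      else p / "features.tsv")
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0]
        ad = anndata.AnnData(X=X.astype(np.float32))
        ad.var_names = genes
        ad.obs_names = cells.tolist()
        return ad
    df = pd.read_csv(p, index_col=0)          # genes x cells
    ad = anndata.AnnData(X=df.to_numpy(dtype=np.float32).T)
    ad.var_names = df.index.tolist()
    ad.obs_names = df.columns.tolist()
    return ad


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, out: pathlib.Path) -> dict:
    layout = simchip.generate_layout(
        cfg.rows, cfg.cols, broken_fraction=cfg.broken_fraction,
        jitter_px=cfg.jitter_px, seed=cfg.seed)
    occupancy = simchip.sample_occupancy(
        layout, cfg.p_tumor, cfg.nk_count_probs, seed=cfg.seed + 1)
    rcfg = simchip.RenderConfig(
        n_frames=cfg.n_frames, frame_interval_h=cfg.frame_interval_h,
        noise_sigma=cfg.noise_sigma,
        drift_px_per_frame=cfg.drift_px_per_frame, seed=cfg.seed + 2)
    truth = simchip.sample_events(
        occupancy, cfg.hazards, rcfg.horizon_h, cfg.frame_interval_h,
        seed=cfg.seed + 3)
    simchip.render_stack(layout, occupancy, truth, rcfg, out_dir=out,
                         materialize=False)
    return {"n_traps": layout.n_traps,
            "n_intact": int((~layout.broken).sum())}


def _load_sim(out: pathlib.Path, cfg: RunConfig):
    stack = tifffile.imread(out / "stack.tif")
    # normalize to (frames, channels, H, W) regardless of page layout
    h, w = stack.shape[-2:]
    return stack.reshape(-1, simchip.N_CHANNELS, h, w)


def _stage_detect(cfg: RunConfig, out: pathlib.Path) -> dict:
    if not (out / "stack.tif").exists():
        raise FileNotFoundError("missing stack.tif: run the simulate stage "
                                "or point the config at an input stack")
    stack = _load_sim(out, cfg)
    template = simchip.trap_template()
    dets = [trapfind.detect_traps(stack[f, simchip.CH_BRIGHTFIELD],
                                  template, cfg.score_threshold,
                                  cfg.nms_iou, frame_index=f)
            for f in range(stack.shape[0])]
    tracks = trapfind.link_tracks(dets, cfg.max_shift_px)
    complete = trapfind.filter_complete(tracks)
    write_tracks(complete, out / "tracks.csv")
    log.info("detect: %d/%d tracks complete", complete.n_tracks,
             tracks.n_tracks)
    return {"n_tracks": tracks.n_tracks,
            "n_complete": complete.n_tracks}


def _stage_cytometry(cfg: RunConfig, out: pathlib.Path) -> dict:
    if not (out / "tracks.csv").exists():
        raise FileNotFoundError("missing tracks.csv: run the detect stage")
    stack = _load_sim(out, cfg)
    tracks = read_tracks(out / "tracks.csv")
    crops = trapfind.crop_rois(stack, tracks, cfg.crop_w, cfg.crop_h)
    census_rows, calls = [], {}
    for i in range(crops.n_traps):
        series = crops.trap_series(i)
        n_tumor, n_nk = cytometry.count_cells_t0(
            series[0], cfg.radius_range_px, cfg.sensitivity)
        tid = int(tracks.trap_ids[i])
        census_rows.append({"trap_id": tid, "n_tumor": n_tumor,
                            "n_nk": n_nk})
        calls[tid] = cytometry.call_death(
            series, cfg.caspase_threshold, cfg.overlap_rule,
            cfg.persistence_k, cfg.frame_interval_h)
    census = pd.DataFrame(census_rows)
    table = cytometry.build_event_table(census, calls, cfg.run_id,
                                        cfg.line_id)
    write_event_table(table, out / "events.csv")
    return {"n_traps": len(table),
            "population_counts":
                cytometry.population_counts(table).to_dict()}


def _stage_survive(cfg: RunConfig, out: pathlib.Path) -> dict:
    if not (out / "events.csv").exists():
        raise FileNotFoundError("missing events.csv: run the cytometry stage")
    table = read_event_table(out / "events.csv")
    horizon = (cfg.n_frames - 1) * cfg.frame_interval_h
    curves = survival.survival_curves_table(table, horizon)
    curves.to_csv(out / "survival_curves.csv", index=False,
                  float_format="%.6f")
    info: dict = {}
    pops = set(table["population"])
    if cfg.normalize and "0:1" in pops:
        cont = survival.km_estimate(
            table[table["population"] == "0:1"], horizon)
        norm = {}
        for pop in ("1:1", "2:1", "3:1"):
            if pop in pops:
                exp = survival.km_estimate(
                    table[table["population"] == pop], horizon)
                norm[pop] = survival.normalize_survival(exp, cont).S_norm[-1]
        info["normalized_s24"] = {k: float(v) for k, v in norm.items()}
    if "1:1" in pops:
        call = survival.classify_response(
            table, cfg.line_id, cfg.response_threshold, horizon_h=horizon)
        pd.DataFrame([dataclasses.asdict(call)]).to_csv(
            out / "response_calls.csv", index=False)
        info["response"] = call.label
        info["s24_1to1"] = call.S_at_24h
    if {"1:1", "0:1"} <= pops:
        lr = survival.logrank_test(table[table["population"] == "1:1"],
                                   table[table["population"] == "0:1"],
                                   horizon, groups=("1:1", "0:1"))
        with open(out / "logrank.json", "w") as fh:
            json.dump(dataclasses.asdict(lr), fh, indent=1)
        info["logrank_1to1_vs_control_p"] = lr.p_value
    return info


def _stage_panel(cfg: RunConfig, out: pathlib.Path) -> dict:
    from . import ligandpanel

    if cfg.expression_path is None:
        raise FileNotFoundError("panel stage needs expression_path")
    expr = read_expression(cfg.expression_path)
    panel = ligandpanel.load_panel(cfg.panel_path)
    res = ligandpanel.summarize_by_group(expr, panel)
    res["summary"].to_csv(out / "panel_summary.csv", index=False)
    ranked = ligandpanel.rank_group_differences(expr, panel)
    ranked.to_csv(out / "panel_ranked.csv", index=False)
    return {"n_panel_genes": len(ligandpanel.panel_genes(panel)),
            "missing_genes": res["missing_genes"]}


STAGES = {"simulate": _stage_simulate, "detect": _stage_detect,
          "cytometry": _stage_cytometry, "survive": _stage_survive,
          "panel": _stage_panel}


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest: dict = {"config": config.to_dict(), "stages": {},
                      "versions": _versions()}
    for name in config.stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage: {name}")
        t0 = time.perf_counter()
        info = STAGES[name](config, out)
        info["elapsed_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = info
        log.info("stage %s done in %.1fs", name, info["elapsed_s"])
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in {".csv", ".json", ".yaml"}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _versions() -> dict:
    import numpy, scipy, pandas, skimage
    from . import __version__

    return {"tidi": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "scikit-image": skimage.__version__}
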