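import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from tidi import simchip, trapfind


@pytest.fixture(scope="session")
def small_device():
    """A fully rendered 10x10 device, 73 frames, default noise/drift, with
    hazards high enough that a good share of tumor-bearing traps die."""
    lay = simchip.generate_layout(10, 10, jitter_px=1.0, seed=101)
    occ = simchip.sample_occupancy(lay, seed=102)
    cfg = simchip.RenderConfig(n_frames=73, seed=103)
    hazards = {"0:1": 0.01, "1:1": 0.05, "2:1": 0.07, "3:1": 0.09,
               "1:0": 0.0, "other/empty": 0.01}
    truth = simchip.sample_events(occ, hazards, cfg.horizon_h,
                                  cfg.frame_interval_h, seed=104)
    stack = simchip.render_stack(lay, occ, truth, cfg)
    return {"layout": lay, "occupancy": occ, "truth": truth, "cfg": cfg,
            "stack": stack}


@pytest.fixture(scope="session")
def small_device_tracks(small_device):
    tpl = simchip.trap_template()
    dets = [trapfind.detect_traps(small_device["stack"][f, 0], tpl,
                                  frame_index=f)
            for f in range(small_device["cfg"].n_frames)]
    tracks = trapfind.filter_complete(trapfind.link_tracks(dets))
    return tracks


def truth_id_for_track(small_device, tracks, i):
    """Map a track index to the ground-truth trap id by nearest center."""
    tb = simchip.truth_boxes(small_device["layout"], small_device["cfg"], 0)
    centers = tb[:, :2] + tb[:, 2:] / 2
    x, y, w, h = tracks.boxes[i, 0]
    c = np.array([x + w / 2, y + h / 2])
    return int(np.argmin(np.hypot(centers[:, 0] - c[0],
                                  centers[:, 1] - c[1])))
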