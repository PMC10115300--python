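from types import SimpleNamespace

import pytest

from harborsound import acoustics as ac
from harborsound import scene_sim as ss


@pytest.fixture(scope="session")
def cal():
    return ac.CalibrationSpec()


@pytest.fixture(scope="session")
def small_scene():
    """Three days, one station, 8 kHz test profile."""
    cfg = ss.default_scene_config(days=3, n_stations=1, rng_seed=11)
    schedule = ss.build_schedule(cfg)
    env = ss.simulate_environment(cfg)
    truth = ss.simulate_events(schedule, env, cfg)
    return SimpleNamespace(cfg=cfg, schedule=schedule, env=env, truth=truth)


_EVENT_COLS = ("vessel_present", "rain_present", "right_whale_present",
               "dolphin_echolocation", "dolphin_whistles", "dolphin_burst")


def _zeroed(truth_files):
    files = truth_files.copy()
    for col in files.columns:
        if col.startswith("count_") or col in _EVENT_COLS:
            files[col] = 0
    return files


@pytest.fixture()
def quiet_truth(small_scene):
    """A copy of the small scene's truth with every event/flag zeroed."""
    return ss.GroundTruth(small_scene.cfg, _zeroed(small_scene.truth.files))


def single_producer_truth(scene, producer: str, count: int,
                          file_index: int = 0):
    """Ground truth with only `count` events of one producer in one file."""
    truth = ss.GroundTruth(scene.cfg, _zeroed(scene.truth.files))
    fid = scene.schedule[file_index].file_id
    truth.files.loc[truth.files["file_id"] == fid, f"count_{producer}"] = count
    return truth, scene.schedule[file_index]
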