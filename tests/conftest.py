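import datetime

import numpy as np
import pytest

import frostmap as fm
from frostmap.pipeline import config_for_scene, run_pipeline
from frostmap.synthetic import write_scene

SEASON_START = datetime.date(2018, 3, 1)


@pytest.fixture(scope="session")
def season_curve() -> fm.DailyCurve:
    """The default double-logistic winter-wheat reference curve."""
    return fm.make_reference_curve()


@pytest.fixture(scope="session")
def noise_free_scene() -> fm.Scene:
    return fm.simulate_scene(seed=11, noise_sd=0.0, gap_rate=0.0)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_scene, tmp_path_factory):
    """Full pipeline run on the noise-free scene; returns (scene, result)."""
    base = tmp_path_factory.mktemp("noise_free")
    write_scene(noise_free_scene, base / "scene")
    cfg = config_for_scene(base / "scene", base / "run")
    result = run_pipeline(cfg)
    return noise_free_scene, result


def curve(values, start=SEASON_START, mask=None) -> fm.DailyCurve:
    return fm.DailyCurve(start, np.asarray(values, dtype=float), mask)
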