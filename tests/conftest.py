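import numpy as np
import pytest

from preclin.io import GrowthCurve, Measurement
from preclin.simulate import CohortSpec, simulate_cohort


def make_curve(days, volumes, mouse_id="m1", group="g", v_start="auto", **kw):
    """GrowthCurve helper; v_start defaults to the day-0 volume."""
    days = np.asarray(days)
    volumes = np.asarray(volumes, dtype=float)
    if v_start == "auto":
        at0 = np.nonzero(days == 0)[0]
        v_start = float(volumes[at0[0]]) if at0.size else None
    return GrowthCurve(
        mouse_id=mouse_id, group=group, days=days, volumes=volumes, v_start=v_start, **kw
    )


@pytest.fixture
def simple_measurements():
    return [
        Measurement("m1", "ctrl", 0, 80.0),
        Measurement("m1", "ctrl", 3, 160.0),
        Measurement("m1", "ctrl", 7, 400.0),
        Measurement("m2", "ctrl", 0, 100.0),
        Measurement("m2", "ctrl", 3, 50.0),
        Measurement("m2", "ctrl", 7, 4.0),
    ]


@pytest.fixture
def mixed_cohort():
    spec = CohortSpec(
        n_mice=40, class_mixture=(0.4, 0.3, 0.3), noise_cv=0.15, seed=11, group="mix"
    )
    curves, labels = simulate_cohort(spec)
    return spec, curves, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
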