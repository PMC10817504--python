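import datetime as dt

import numpy as np
import pytest

from forestmon.collection import Scene, SceneCollection
from forestmon.grid import GridSpec


@pytest.fixture
def grid4() -> GridSpec:
    return GridSpec(width=4, height=4)


def make_scene(
    grid: GridSpec,
    date: dt.date,
    band_values: dict[str, float | np.ndarray],
    qa: np.ndarray | None = None,
    cloud_pct: float = 0.0,
) -> Scene:
    """Hand-build a scene from per-band constants or arrays."""
    bands = {}
    for name, v in band_values.items():
        arr = np.asarray(v, dtype=float)
        bands[name] = np.broadcast_to(arr, grid.shape).copy() if arr.ndim == 0 else arr.copy()
    if qa is None:
        qa = np.zeros(grid.shape, dtype=np.uint16)
    return Scene(bands=bands, qa=qa, date=date, cloudy_pixel_percentage=cloud_pct, grid=grid)


def make_collection_of(grid: GridSpec, *scenes: Scene) -> SceneCollection:
    return SceneCollection(sorted(scenes, key=lambda s: s.date), grid=grid)


@pytest.fixture
def tiny_sim_config():
    """A small, fast, noise-free synthetic configuration with one severe
    damage year."""
    import dataclasses

    from forestmon.simulate import DEFAULT_PHENOLOGY, DamageEvent, SimConfig

    return SimConfig(
        phenology={c: dataclasses.replace(m, noise_sd=0.0) for c, m in DEFAULT_PHENOLOGY.items()},
        grid=GridSpec(width=20, height=20),
        years=(2017, 2018, 2019, 2020),
        dates_doy=(120, 152, 184, 216, 248),
        n_compartments=4,
        species_mixture={0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25},
        events=(DamageEvent("C001", 2019, "drought", 0.8, 1.0),),
        cloud_frac_range=(0.0, 0.0),
        seed=11,
    )
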