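#!/usr/bin/env python
"""Filter the archive and build cloud-free annual median composites.

For each year: keep scenes inside the vegetation window [14 April,
15 October), drop scenes with more than 5% cloud metadata, mask the
remaining cloudy pixels via QA bits 10/11, restrict to the compartment
ROI, and reduce per pixel with the median.  Also writes a stretched
true-colour (B4/B3/B2) rendering of each composite.

Inputs:  results/sim/            Outputs: results/composites/
"""

import datetime as dt
from pathlib import Path

import numpy as np
import shapely

from forestmon import io as fio
from forestmon.collection import (
    SceneCollection,
    filter_bounds,
    filter_cloud_metadata,
    filter_date,
    make_rgb,
    mask_collection,
    reduce,
)

SIM = Path("results/sim")
OUT = Path("results/composites")
SEASON = ((4, 14), (10, 15))
MAX_CLOUD_PCT = 5.0


def load_yearly_collections() -> dict[int, SceneCollection]:
    scenes = [fio.read_scene(p) for p in (SIM / "scenes").glob("*.tif")]
    by_year: dict[int, list] = {}
    for s in sorted(scenes, key=lambda s: s.date):
        by_year.setdefault(s.date.year, []).append(s)
    return {y: SceneCollection(ss) for y, ss in sorted(by_year.items())}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    comps = fio.read_compartments(SIM / "compartments.geojson")
    roi = shapely.union_all([c.polygon for c in comps])
    for year, coll in load_yearly_collections().items():
        n0 = len(coll)
        coll = filter_date(coll, dt.date(year, *SEASON[0]), dt.date(year, *SEASON[1]))
        coll = filter_cloud_metadata(coll, MAX_CLOUD_PCT)
        kept = len(coll)
        coll = mask_collection(filter_bounds(coll, roi))
        comp = reduce(coll, "median")
        stack = np.stack([comp.bands[b] for b in comp.band_names])
        fio.write_raster(OUT / f"composite_{year}.tif", stack, comp.grid, comp.band_names,
                         nodata=float("nan"))
        fio.write_raster(OUT / f"rgb_{year}.tif", make_rgb(comp), comp.grid, ["R", "G", "B", "A"])
        gap_pct = 100 * float((comp.n_scenes_used == 0).mean())
        print(
            f"{year}: {kept}/{n0} scenes pass the cloud filter; "
            f"median composite has {gap_pct:.1f}% unfilled pixels"
        )


if __name__ == "__main__":
    main()
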