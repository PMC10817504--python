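#!/usr/bin/env python
"""Generate the synthetic study archive.

Writes a four-year (2017-2020) Sentinel-2-style scene archive on a
60x60 grid at 10 m — twelve acquisitions per growing season with random
cloud fields — plus the forest-compartment map (36 compartments, five
species classes) and the compartment-level damage reports.  2019 is the
severe damage year: drought/frost events depress NIR over ~80% of the
compartment area.  Everything is deterministic in the seed.

Outputs: results/sim/{scenes/*.tif, compartments.geojson, reports.csv}
"""

from pathlib import Path

from forestmon import io as fio
from forestmon.simulate import demo_config, make_collection, make_compartments, make_reports

SEED = 42
OUT = Path("results/sim")


def main() -> None:
    (OUT / "scenes").mkdir(parents=True, exist_ok=True)
    cfg = demo_config(seed=SEED)
    comps = make_compartments(cfg)
    reports = make_reports(cfg)
    fio.write_compartments(OUT / "compartments.geojson", comps, cfg.grid.crs_label)
    fio.write_reports(OUT / "reports.csv", reports)
    n = 0
    for year in cfg.years:
        for scene in make_collection(cfg, year):
            fio.write_scene(OUT / "scenes" / f"scene_{scene.date.isoformat()}.tif", scene)
            n += 1
    by_species: dict[int, int] = {}
    for c in comps:
        by_species[c.species_code] = by_species.get(c.species_code, 0) + 1
    print(f"wrote {n} scenes over {len(cfg.years)} years -> {OUT / 'scenes'}")
    print(f"{len(comps)} compartments ({comps.total_area_ha:.0f} ha), species counts {by_species}")
    print(f"{len(reports)} damage-report rows ({sorted({r.year for r in reports})})")


if __name__ == "__main__":
    main()
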