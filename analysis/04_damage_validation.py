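#!/usr/bin/env python
"""Classify damage from the anomaly maps and validate against reports.

Each year's Z-NDVI map is thresholded at -0.5 (strictly below = damage)
and compared pixel-wise with the rasterized damage reports (compartment
damage ratio >= 30% = reference damage) in a confusion matrix, from
which producer's, user's, and total accuracies are derived per year and
on average.

Inputs:  results/sim/, results/indices/
Outputs: results/damage/ (binary maps), results/confusion.csv,
         results/damage_accuracy.csv
"""

from pathlib import Path

import pandas as pd

from forestmon import io as fio
from forestmon.damage import (
    accuracies,
    classify_damage,
    confusion,
    mean_accuracies,
    reference_damage_map,
    round_pct,
)
from forestmon.indices import IndexRaster

SIM = Path("results/sim")
INDICES = Path("results/indices")
OUT = Path("results/damage")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    comps = fio.read_compartments(SIM / "compartments.geojson")
    reports = fio.read_reports(SIM / "reports.csv")

    conf_rows, entries = [], []
    for path in sorted(INDICES.glob("zndvi_*.tif")):
        year = int(path.stem.split("_")[1])
        arr, meta = fio.read_raster(path)
        z = IndexRaster(arr[0].astype(float), "zndvi", str(year), meta.grid)
        classified = classify_damage(z)
        reference = reference_damage_map(comps, reports, year, meta.grid)
        fio.write_raster(OUT / f"classified_{year}.tif", classified.values, meta.grid,
                         ["damage"], nodata=-1)
        fio.write_raster(OUT / f"reference_{year}.tif", reference.values, meta.grid,
                         ["damage"], nodata=-1)
        m = confusion(classified, reference)
        conf_rows.append({"year": year, "n11": m.n11, "n10": m.n10, "n01": m.n01,
                          "n00": m.n00, "total": m.total})
        e = accuracies(m)
        entries.append(e)
        print(f"{year}: PA={round_pct(e.producer_pct)} UA={round_pct(e.user_pct)} "
              f"TA={round_pct(e.total_pct)} (n={m.total} px)")

    mean = mean_accuracies(entries)
    print(f"mean over years: PA={round_pct(mean.producer_pct)} "
          f"UA={round_pct(mean.user_pct)} TA={round_pct(mean.total_pct)}")

    fio.write_table(Path("results/confusion.csv"), pd.DataFrame(conf_rows))
    rows = [
        {"year": e.year, "producer_pct": round_pct(e.producer_pct),
         "user_pct": round_pct(e.user_pct), "total_pct": round_pct(e.total_pct)}
        for e in entries
    ]
    rows.append({"year": "mean", "producer_pct": round_pct(mean.producer_pct),
                 "user_pct": round_pct(mean.user_pct), "total_pct": round_pct(mean.total_pct)})
    fio.write_table(Path("results/damage_accuracy.csv"), pd.DataFrame(rows))


if __name__ == "__main__":
    main()
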