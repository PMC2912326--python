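#!/usr/bin/env python
"""Build the call-rate experiment grid: data0 (as genotyped, marker
call-rate cutoff 95%) and data1/data2/data3 degraded to 95/90/85% GCR
(marker cutoff 80%), reporting the achieved rates and marker counts.

Reads results/hotspots/rh_free.*, writes results/callrate_grid/.
"""

import sys
from pathlib import Path

from popflow import callrate, genotype_io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> int:
    src = BASE / "hotspots"
    if not (src / "rh_free.ped").exists():
        print("run analysis/02_flag_hotspots.py first", file=sys.stderr)
        return 1
    out = BASE / "callrate_grid"
    out.mkdir(parents=True, exist_ok=True)
    mat = genotype_io.read_ped_map(src / "rh_free.ped", src / "rh_free.map")

    data0, dropped0 = callrate.filter_markers_by_call_rate(mat, 0.95)
    print(f"data0: GCR {callrate.call_rate(data0).overall:.4f}, "
          f"{data0.n_markers} markers (dropped {len(dropped0)} below 95%)")
    genotype_io.write_ped_map(data0, out / "data0")

    for k, target in enumerate(callrate.CANONICAL_TARGETS, start=1):
        degraded = callrate.degrade_call_rate(data0, target, seed=SEED + k)
        filtered, dropped = callrate.filter_markers_by_call_rate(degraded, 0.80)
        rates = callrate.call_rate(filtered)
        genotype_io.write_ped_map(filtered, out / f"data{k}")
        print(f"data{k}: target GCR {target:.2f}, achieved "
              f"{rates.overall:.4f} after the 80% marker cutoff "
              f"({filtered.n_markers} markers, dropped {len(dropped)})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
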