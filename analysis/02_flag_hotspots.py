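#!/usr/bin/env python
"""Flag recombination-hotspot surrogate positions on a dense reference
panel and remove them from the cohort.

A block-structured reference panel (four populations, 50 diploids each,
50-marker haplotype blocks copied from 4 founders) is simulated on the
cohort's marker grid, standing in for an external dense haplotype
resource.  A marker is flagged when its windowed mean EM R-squared drops
below 0.7 in at least one reference population; block boundaries are the
planted ground truth.  Reads results/cohort/, writes results/hotspots/.
"""

import sys
from pathlib import Path

import numpy as np

from popflow import genotype_io, ld_hotspots
from popflow.synthetic_data import SimulationConfig, simulate

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> int:
    if not (BASE / "cohort" / "cohort.ped").exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    out = BASE / "hotspots"
    out.mkdir(parents=True, exist_ok=True)
    cohort = genotype_io.read_ped_map(BASE / "cohort" / "cohort.ped",
                                      BASE / "cohort" / "cohort.map")

    panel_cfg = SimulationConfig(
        n_pops=4, n_per_pop=50, n_markers=cohort.n_markers,
        fst_per_pop=(0.15, 0.1, 0.1, 0.2),
        pop_names=["REF1", "REF2", "REF3", "REF4"],
        block_length=50, founder_haplotypes_per_block=4,
        missing_rate=0.0, marker_spacing_bp=55_000, seed=SEED + 100,
    )
    panel = simulate(panel_cfg)
    genotype_io.write_ped_map(panel.matrix, out / "reference_panel")

    flank = 25
    scan = ld_hotspots.flag_hotspots(panel.matrix, flank=flank, threshold=0.7)
    table = ld_hotspots.hotspot_table(scan, panel.matrix)
    table.to_csv(out / "hotspots.tsv", sep="\t", index=False)
    flagged = table["is_hotspot"].to_numpy()
    hits = np.flatnonzero(flagged)
    bounds = panel.pools.boundary_markers
    detected = [(np.abs(hits - b) <= flank).any() for b in bounds]

    keep = np.flatnonzero(~flagged)  # panel and cohort share the marker grid
    rh_free = cohort.subset_markers(keep)
    genotype_io.write_ped_map(rh_free, out / "rh_free")
    print(f"flagged {int(flagged.sum())} of {cohort.n_markers} panel positions "
          f"as possible hotspots")
    print(f"planted block boundaries detected: {int(np.sum(detected))}/{len(bounds)}")
    print(f"RH-free cohort: {rh_free.n_markers} markers -> {out / 'rh_free.ped'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
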