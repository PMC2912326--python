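"""Multi-population genotype simulator with known drift, LD blocks,
planted regional markers, admixture and missingness.

The generative model is deliberately the simplest one under which every
downstream statistic has a known expectation:

* **Drift** — population allele frequencies follow the Balding–Nichols
  model: an ancestral frequency ``p`` is drawn uniformly on [0.05, 0.95]
  and each population ``i`` draws its frequency from
  ``Beta(p (1 - F_i) / F_i, (1 - p)(1 - F_i) / F_i)``, so that
  ``Var(p_i) = F_i p (1 - p)`` and Weir–Cockerham theta recovers ``F_i``.
* **LD blocks** — within a block of consecutive markers every haplotype is
  copied from a small founder pool, giving high within-block R-squared;
  blocks are drawn independently, giving near-zero cross-block R-squared.
  Block boundaries are therefore ground-truth recombination-hotspot
  surrogates.
* **Regional markers** — selected markers get one population's frequency
  displaced from the ancestral value, creating the frequency-variance
  outliers the RSM scan looks for.

Founder pools are built as a two-core mixture: two core haplotypes are
drawn from the population frequencies, founders are assigned alternately
to the cores and each founder site is flipped with a small mutation rate.
Independent Bernoulli founders would give mean pairwise R-squared of about
1/(pool size - 1), far below any realistic within-block LD; the two-core
construction keeps within-block R-squared high (near 1) while the mutation
rate controls haplotype diversity inside the pool.

``founder_haplotypes_per_block=None`` switches a simulation to
linkage-equilibrium draws (each haplotype sampled site-wise from the
population frequencies), the appropriate setting for unlinked-marker
calibrations where a finite pool would quantise allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

# stage tags mixed into the seed stream so each operation is an
# independent, reproducible function of config.seed
_STAGE_FREQ = 11
_STAGE_FOUNDERS = 23
_STAGE_DRAW = 37
_STAGE_MISSING = 53

#: simulated allele characters: A1 carries the tracked frequency
SIM_ALLELES = ("A", "G")


class SimulationConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class AdmixtureSpec:
    """A batch of admixed individuals drawing haplotypes from several pools.

    ``ancestry`` maps population label to the probability that any one
    haplotype is drawn from that population's pool.
    """

    label: str
    ancestry: Mapping[str, float]
    n_individuals: int

    def validate(self, pops: Sequence[str]) -> None:
        total = sum(self.ancestry.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"admixture proportions for {self.label!r} sum to {total}, not 1"
            )
        for pop in self.ancestry:
            if pop not in pops:
                raise SimulationConfigError(f"unknown ancestry population {pop!r}")


@dataclass
class PlantedMarker:
    """Frequency displacement planted at one marker in one population."""

    marker_index: int
    target_pop: str
    shift: float


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults emulate, at desk scale, a worldwide SNP-chip cohort: five
    continental-level populations with graded drift (strongest in the
    most-bottlenecked group), 16 diploid samples per group, haplotype
    blocks of 50 markers copied from 4 founders, and a 1.3% no-call rate
    (a 98.7% genotype call rate).
    """

    n_pops: int = 5
    n_per_pop: int = 16
    n_markers: int = 2000
    fst_per_pop: Sequence[float] = (0.30, 0.20, 0.16, 0.12, 0.02)
    pop_names: Sequence[str] | None = None
    block_length: int = 50
    founder_haplotypes_per_block: int | None = 4
    founder_mutation_rate: float = 0.01
    admixture: Sequence[AdmixtureSpec] = field(default_factory=list)
    planted_markers: Sequence[PlantedMarker] = field(default_factory=list)
    missing_rate: float = 0.013
    chrom: Sequence[str] | None = None
    positions_bp: Sequence[int] | None = None
    marker_spacing_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_names is None:
            self.pop_names = [f"POP{i + 1}" for i in range(self.n_pops)]
        self.pop_names = list(self.pop_names)
        if len(self.pop_names) != self.n_pops:
            raise SimulationConfigError("pop_names length must equal n_pops")
        self.fst_per_pop = list(self.fst_per_pop)
        if len(self.fst_per_pop) != self.n_pops:
            raise SimulationConfigError("fst_per_pop length must equal n_pops")
        for f in self.fst_per_pop:
            if not 0.0 < f < 1.0:
                raise SimulationConfigError(f"fst value {f} outside open (0,1)")
        if self.block_length < 1:
            raise SimulationConfigError("block_length must be >= 1")
        if (
            self.founder_haplotypes_per_block is not None
            and self.founder_haplotypes_per_block < 1
        ):
            raise SimulationConfigError("founder pool size must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationConfigError("missing_rate must be in [0, 1)")
        if self.chrom is None:
            self.chrom = ["1"] * self.n_markers
        self.chrom = list(self.chrom)
        if self.positions_bp is None:
            # spacing restarts on each chromosome
            pos, counter, prev = [], 0, None
            for c in self.chrom:
                counter = counter + 1 if c == prev else 1
                pos.append(counter * self.marker_spacing_bp)
                prev = c
            self.positions_bp = pos
        self.positions_bp = list(self.positions_bp)
        if len(self.chrom) != self.n_markers or len(self.positions_bp) != self.n_markers:
            raise SimulationConfigError("chrom/positions length must equal n_markers")
        arr = np.asarray(self.positions_bp)
        chrom = np.asarray(self.chrom, dtype=object)
        for c in dict.fromkeys(self.chrom):
            p = arr[chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise SimulationConfigError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        for spec in self.admixture:
            spec.validate(self.pop_names)

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class FrequencyTable:
    """Per-population allele-frequency table plus the ancestral draw."""

    ancestral: np.ndarray  # (M,)
    freqs: pd.DataFrame  # markers x populations
    planted: pd.DataFrame  # marker_index, target_pop, shift (ground truth)

    def copy(self) -> "FrequencyTable":
        return FrequencyTable(self.ancestral.copy(), self.freqs.copy(), self.planted.copy())


def simulate_frequencies(config: SimulationConfig) -> FrequencyTable:
    """Draw ancestral and Balding–Nichols population allele frequencies.

    Ancestral frequencies are uniform on [0.05, 0.95]; population ``i``
    draws from ``Beta(p(1-F_i)/F_i, (1-p)(1-F_i)/F_i)`` so the expected
    drift variance is ``F_i p(1-p)``.
    """
    rng = config._rng(_STAGE_FREQ)
    m = config.n_markers
    p = rng.uniform(0.05, 0.95, size=m)
    cols = {}
    for name, f in zip(config.pop_names, config.fst_per_pop):
        scale = (1.0 - f) / f
        cols[name] = rng.beta(p * scale, (1.0 - p) * scale)
    freqs = pd.DataFrame(cols, index=pd.RangeIndex(m, name="marker_index"))
    planted = pd.DataFrame(columns=["marker_index", "target_pop", "shift"])
    return FrequencyTable(ancestral=p, freqs=freqs, planted=planted)


def plant_specific_markers(
    table: FrequencyTable, planted_markers: Sequence[PlantedMarker]
) -> FrequencyTable:
    """Displace one population's frequency at each planted marker.

    The target population's frequency becomes ``ancestral + shift``; the
    ground truth is recorded on the returned table.
    """
    out = table.copy()
    rows = []
    for pm in planted_markers:
        if pm.shift == 0:  # no displacement: leave the drawn frequency alone
            continue
        target = out.ancestral[pm.marker_index] + pm.shift
        if not 0.0 <= target <= 1.0:
            raise SimulationConfigError(
                f"planted frequency {target:.3f} at marker {pm.marker_index} "
                "outside [0, 1]"
            )
        out.freqs.loc[pm.marker_index, pm.target_pop] = target
        rows.append(
            {"marker_index": pm.marker_index, "target_pop": pm.target_pop, "shift": pm.shift}
        )
    if rows:
        new = pd.DataFrame(rows)
        out.planted = (
            new if out.planted.empty
            else pd.concat([out.planted, new], ignore_index=True)
        )
    return out


def _block_slices(config: SimulationConfig) -> list[slice]:
    """Maximal runs of <= block_length markers, restarted per chromosome."""
    chrom = np.asarray(config.chrom, dtype=object)
    slices: list[slice] = []
    start = 0
    for c in dict.fromkeys(config.chrom):
        idx = np.flatnonzero(chrom == c)
        lo, hi = idx[0], idx[-1] + 1
        for s in range(lo, hi, config.block_length):
            slices.append(slice(s, min(s + config.block_length, hi)))
    return slices


@dataclass
class HaplotypePools:
    """Founder haplotypes per population plus block ground truth.

    ``founders[pop]`` is an (F, M) 0/1 array (rows are founder haplotypes)
    or ``None`` for linkage-equilibrium populations.  ``block_id`` labels
    each marker with its block; ``boundary_markers`` are the first marker
    indices of every block except the first on each chromosome — the
    ground-truth hotspot surrogate positions.
    """

    founders: dict[str, np.ndarray | None]
    freq_table: FrequencyTable
    block_slices: list[slice]
    block_id: np.ndarray
    boundary_markers: np.ndarray


def simulate_block_haplotypes(
    table: FrequencyTable, config: SimulationConfig
) -> HaplotypePools:
    """Build per-population founder pools with two-core block structure."""
    rng = config._rng(_STAGE_FOUNDERS)
    slices = _block_slices(config)
    m = config.n_markers
    block_id = np.empty(m, dtype=np.int64)
    boundaries = []
    chrom = np.asarray(config.chrom, dtype=object)
    for b, sl in enumerate(slices):
        block_id[sl] = b
        first = sl.start
        if first > 0 and chrom[first] == chrom[first - 1]:
            boundaries.append(first)

    founders: dict[str, np.ndarray | None] = {}
    n_f = config.founder_haplotypes_per_block
    for pop in config.pop_names:
        p = table.freqs[pop].to_numpy()
        if n_f is None:
            founders[pop] = None
            continue
        pool = np.empty((n_f, m), dtype=np.int8)
        for sl in slices:
            p_blk = p[sl]
            core0 = (rng.random(p_blk.shape) < p_blk).astype(np.int8)
            core1 = (rng.random(p_blk.shape) < p_blk).astype(np.int8)
            for j in range(n_f):
                hap = (core0 if j % 2 == 0 else core1).copy()
                if config.founder_mutation_rate > 0:
                    flip = rng.random(hap.shape) < config.founder_mutation_rate
                    hap[flip] = 1 - hap[flip]
                pool[j, sl] = hap
        founders[pop] = pool
    return HaplotypePools(
        founders=founders,
        freq_table=table,
        block_slices=slices,
        block_id=block_id,
        boundary_markers=np.asarray(boundaries, dtype=np.int64),
    )


def _draw_haplotype(
    pools: HaplotypePools, pop: str, rng: np.random.Generator
) -> np.ndarray:
    founders = pools.founders[pop]
    m = len(pools.block_id)
    if founders is None:
        p = pools.freq_table.freqs[pop].to_numpy()
        return (rng.random(m) < p).astype(np.int8)
    hap = np.empty(m, dtype=np.int8)
    for sl in pools.block_slices:
        hap[sl] = founders[rng.integers(founders.shape[0]), sl]
    return hap


def draw_genotypes(pools: HaplotypePools, config: SimulationConfig) -> GenotypeMatrix:
    """Sample diploid individuals: two haplotypes per individual, drawn with
    replacement from the population's pool (block-wise for pooled
    populations, site-wise at linkage equilibrium otherwise).  Admixed
    individuals pick each haplotype's source pool by their ancestry
    proportions."""
    rng = config._rng(_STAGE_DRAW)
    m = config.n_markers
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    for pop in config.pop_names:
        for i in range(config.n_per_pop):
            hap1 = _draw_haplotype(pools, pop, rng)
            hap2 = _draw_haplotype(pools, pop, rng)
            rows.append(hap1 + hap2)
            sample_ids.append(f"{pop}_{i + 1}")
            pop_labels.append(pop)
    for spec in config.admixture:
        anc_pops = list(spec.ancestry)
        anc_probs = np.asarray([spec.ancestry[a] for a in anc_pops])
        for i in range(spec.n_individuals):
            srcs = rng.choice(len(anc_pops), size=2, p=anc_probs)
            hap1 = _draw_haplotype(pools, anc_pops[srcs[0]], rng)
            hap2 = _draw_haplotype(pools, anc_pops[srcs[1]], rng)
            rows.append(hap1 + hap2)
            sample_ids.append(f"{spec.label}_{i + 1}")
            pop_labels.append(spec.label)
    dosage = np.vstack(rows).astype(np.int8)
    alleles = np.tile(np.asarray(SIM_ALLELES, dtype=object), (m, 1))
    return GenotypeMatrix(
        sample_ids=np.asarray(sample_ids, dtype=object),
        pop_labels=np.asarray(pop_labels, dtype=object),
        marker_ids=np.asarray([f"snp{i + 1}" for i in range(m)], dtype=object),
        chrom=np.asarray(config.chrom, dtype=object),
        pos_bp=np.asarray(config.positions_bp, dtype=np.int64),
        alleles=alleles,
        dosage=dosage,
    )


def apply_missingness(
    matrix: GenotypeMatrix, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Set each call to MISSING independently with the given probability."""
    if not 0.0 <= missing_rate < 1.0:
        raise SimulationConfigError("missing_rate must be in [0, 1)")
    out = matrix.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_MISSING]))
    mask = rng.random(out.dosage.shape) < missing_rate
    out.dosage[mask] = MISSING
    return out


@dataclass
class SimulationResult:
    """A simulated cohort plus its ground truth."""

    matrix: GenotypeMatrix
    freq_table: FrequencyTable
    pools: HaplotypePools

    def ground_truth(self) -> pd.DataFrame:
        """Per-marker truth sidecar: planted status, block boundaries and
        true per-population frequencies."""
        mat = self.matrix
        df = pd.DataFrame(
            {
                "marker_id": mat.marker_ids,
                "chrom": mat.chrom,
                "pos_bp": mat.pos_bp,
            }
        )
        planted = self.freq_table.planted
        df["is_planted"] = df.index.isin(planted["marker_index"])
        pop_of = dict(zip(planted["marker_index"], planted["target_pop"]))
        df["planted_pop"] = [pop_of.get(i, "") for i in df.index]
        df["is_block_boundary"] = df.index.isin(self.pools.boundary_markers)
        for pop in self.freq_table.freqs.columns:
            df[f"freq_{pop}"] = self.freq_table.freqs[pop].to_numpy()
        return df


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: frequencies -> planting -> haplotype pools ->
    genotype draws -> missingness."""
    table = simulate_frequencies(config)
    table = plant_specific_markers(table, config.planted_markers)
    pools = simulate_block_haplotypes(table, config)
    matrix = draw_genotypes(pools, config)
    if config.missing_rate > 0:
        matrix = apply_missingness(matrix, config.missing_rate, config.seed)
    return SimulationResult(matrix=matrix, freq_table=table, pools=pools)
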