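"""Pairwise identity-by-state / allele-sharing distances between
individuals.

At each locus where both individuals are called, the number of shared
alleles between the two unordered genotypes is 2 - |dosage difference|
(AA/AA and Aa/Aa share 2, AA/Aa share 1, AA/aa share 0).  The distance is
one minus the proportion of shared alleles over jointly called loci
(pairwise deletion).  For biallelic SNPs under this genotype-identity
convention the allele-sharing distance (ASD) coincides with the IBS
distance; the metric label records intent only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    sample_ids: np.ndarray
    values: np.ndarray  # N x N in [0, 1], symmetric, zero diagonal
    metric_name: str
    n_markers_used: np.ndarray  # N x N joint-call counts

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def ibs_pair(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, int]:
    """IBS distance and joint-call count for two dosage vectors."""
    if calls_a.shape != calls_b.shape:
        raise DistanceError("call vectors differ in length")
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    used = int(ok.sum())
    if used == 0:
        return float("nan"), 0
    shared = 2 - np.abs(
        calls_a[ok].astype(np.int64) - calls_b[ok].astype(np.int64)
    )
    return float(1.0 - shared.sum() / (2.0 * used)), used


def distance_matrix(matrix: GenotypeMatrix, metric: str = "IBS") -> DistanceMatrix:
    """All-pairs IBS/ASD distance matrix with pairwise-complete loci.

    Any pair with zero jointly called loci is an error (the offending
    pairs are listed).
    """
    if metric.upper() not in {"IBS", "ASD"}:
        raise DistanceError(f"unknown metric {metric!r}")
    n = matrix.n_samples
    if n < 2:
        raise DistanceError("need at least two samples")
    dos = matrix.dosage.astype(np.int64)
    called = dos != MISSING
    values = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    undefined = []
    for i in range(n):
        ok = called[i] & called[i + 1 :]
        diff = np.abs(dos[i] - dos[i + 1 :])
        shared = np.where(ok, 2 - diff, 0).sum(axis=1)
        cnt = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - shared / (2.0 * cnt)
        for off, c in enumerate(cnt):
            j = i + 1 + off
            if c == 0:
                undefined.append((str(matrix.sample_ids[i]), str(matrix.sample_ids[j])))
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        used[i, i + 1 :] = cnt
        used[i + 1 :, i] = cnt
        used[i, i] = int(called[i].sum())
    if undefined:
        raise DistanceError(
            f"{len(undefined)} pairs share no called loci: {undefined[:5]}"
        )
    return DistanceMatrix(
        sample_ids=matrix.sample_ids.copy(),
        values=values,
        metric_name=metric.upper(),
        n_markers_used=used,
    )


def population_centroid_distances(
    dist: DistanceMatrix, pop_labels: np.ndarray
) -> DistanceMatrix:
    """Population-level matrix: mean inter-individual distance between the
    samples of each pair of populations (diagonal forced to zero)."""
    pops = list(dict.fromkeys(pop_labels))
    k = len(pops)
    vals = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    idx = {p: np.flatnonzero(np.asarray(pop_labels, dtype=object) == p) for p in pops}
    for a in range(k):
        for b in range(a + 1, k):
            block = dist.values[np.ix_(idx[pops[a]], idx[pops[b]])]
            vals[a, b] = vals[b, a] = float(block.mean())
            counts[a, b] = counts[b, a] = block.size
    return DistanceMatrix(
        sample_ids=np.asarray(pops, dtype=object),
        values=vals,
        metric_name=dist.metric_name + "_POP_MEAN",
        n_markers_used=counts,
    )


def separation_score(dist: DistanceMatrix, pop_labels: np.ndarray) -> float:
    """Mean between-population distance over mean within-population
    distance — a scalar population-separation summary."""
    labels = np.asarray(pop_labels, dtype=object)
    n = dist.n
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    within = dist.values[iu][same]
    between = dist.values[iu][~same]
    if within.size == 0 or between.size == 0:
        raise DistanceError("need both within- and between-population pairs")
    return float(between.mean() / within.mean())
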