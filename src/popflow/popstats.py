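"""Population differentiation and drift statistics: Weir–Cockerham theta
(per-marker and ratio-of-sums mean Fst), grouped mean-Fst tables, and the
per-population monomorphic-marker drift score.

Weir–Cockerham theta is estimated from genotype counts with the full
variance-component decomposition (a: between populations, b: between
individuals within populations, c: within individuals), so observed
heterozygosity enters the estimate.  The mean over markers is the
ratio-of-sums sum(a) / sum(a+b+c), the standard multi-locus combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class PopStatsError(ValueError):
    pass


def _wc_components(
    matrix: GenotypeMatrix, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker Weir–Cockerham variance components (a, b, c) and a mask
    of usable markers (every population called, locus polymorphic)."""
    r = len(pops)
    if r < 2:
        raise PopStatsError("need at least two populations")
    called = matrix.dosage != MISSING
    dos = np.where(called, matrix.dosage, 0).astype(float)

    n_i = np.empty((r, matrix.n_markers))
    p_i = np.empty((r, matrix.n_markers))
    h_i = np.empty((r, matrix.n_markers))
    for k, pop in enumerate(pops):
        rows = matrix.samples_in_pop(pop)
        n_i[k] = called[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = dos[rows].sum(axis=0) / (2.0 * n_i[k])
            h_i[k] = ((matrix.dosage[rows] == 1) & called[rows]).sum(axis=0) / n_i[k]

    usable = (n_i > 0).all(axis=0)
    n_sum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    poly = (pbar > 0) & (pbar < 1)
    usable &= poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, usable


@dataclass
class FstResult:
    per_marker: pd.Series  # theta per usable marker
    mean: float  # ratio-of-sums across markers
    n_markers: int
    populations: list[str]


def wc_fst(matrix: GenotypeMatrix, pops: list[str] | None = None) -> FstResult:
    """Per-marker Weir–Cockerham theta and the ratio-of-sums mean."""
    if pops is None:
        pops = matrix.populations
    a, b, c, usable = _wc_components(matrix, pops)
    skipped = int((~usable).sum())
    if skipped:
        logger.info("wc_fst: skipping %d unusable markers", skipped)
    if usable.sum() == 0:
        raise PopStatsError("no usable markers for Fst")
    tot = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(tot != 0, a / tot, np.nan)
    per_marker = pd.Series(
        theta[usable], index=list(matrix.marker_ids[usable]), name="theta"
    )
    mean = float(a[usable].sum() / tot[usable].sum())
    return FstResult(per_marker=per_marker, mean=mean, n_markers=int(usable.sum()), populations=list(pops))


@dataclass
class FstReport:
    level: str
    group: str
    mean_fst: float
    n_markers: int
    n_samples: int
    estimator: str = "weir_cockerham_theta"


def group_vs_rest_fst(
    matrix: GenotypeMatrix, group_of: dict[str, str], level: str = "all"
) -> list[FstReport]:
    """One mean Fst per group: that group's samples versus the pooled
    complement, within the samples covered by the grouping."""
    groups = list(dict.fromkeys(group_of.values()))
    if len(groups) < 2:
        raise PopStatsError("need at least two groups (one-group Fst has an empty complement)")
    labels = np.asarray(
        [group_of.get(p) for p in matrix.pop_labels], dtype=object
    )
    covered = np.flatnonzero(labels != None)  # noqa: E711
    sub = matrix.subset_samples(covered)
    sub_groups = labels[covered]
    reports = []
    for g in groups:
        two_way = sub.copy()
        two_way.pop_labels = np.where(sub_groups == g, g, "REST").astype(object)
        res = wc_fst(two_way, [g, "REST"])
        reports.append(
            FstReport(
                level=level,
                group=g,
                mean_fst=res.mean,
                n_markers=res.n_markers,
                n_samples=int((sub_groups == g).sum()),
            )
        )
    return reports


def mean_fst_table(
    matrix: GenotypeMatrix, grouping: dict[str, dict[str, str]]
) -> pd.DataFrame:
    """Multi-level mean-Fst table.

    ``grouping`` maps level name -> {population label -> group}; each
    level is analysed on its covered samples only, group versus rest.
    """
    rows = []
    for level, group_of in grouping.items():
        for rep in group_vs_rest_fst(matrix, group_of, level=level):
            rows.append(
                {
                    "level": rep.level,
                    "group": rep.group,
                    "mean_fst": rep.mean_fst,
                    "n_markers": rep.n_markers,
                    "n_samples": rep.n_samples,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DriftReport:
    population: str
    n_monomorphic: int
    fraction_monomorphic: float
    rank: int


def monomorphic_drift(
    matrix: GenotypeMatrix,
    pops: list[str] | None = None,
    rarefy: bool = False,
    seed: int = 0,
) -> list[DriftReport]:
    """Per-population count and fraction of overall-polymorphic markers
    that are monomorphic within the population; rank 1 = most drifted.

    The raw count is sample-size biased (small samples fix more markers
    by chance); a warning is logged when population sizes differ by more
    than 20%, and ``rarefy=True`` subsamples every population to the
    minimum size first.
    """
    if pops is None:
        pops = matrix.populations
    if len(pops) < 2:
        raise PopStatsError("need at least two populations")
    sizes = {p: len(matrix.samples_in_pop(p)) for p in pops}
    if max(sizes.values()) > 1.2 * min(sizes.values()):
        if rarefy:
            logger.info("monomorphic_drift: rarefying to n=%d", min(sizes.values()))
        else:
            logger.warning(
                "monomorphic_drift: population sizes differ by >20%% "
                "(%s); counts are size-biased", sizes,
            )
    work = matrix
    if rarefy:
        n_min = min(sizes.values())
        rng = np.random.default_rng(seed)
        keep = np.concatenate(
            [
                rng.choice(matrix.samples_in_pop(p), size=n_min, replace=False)
                for p in pops
            ]
        )
        work = matrix.subset_samples(np.sort(keep))

    called = work.dosage != MISSING
    rows_all = np.concatenate([work.samples_in_pop(p) for p in pops])
    sub_called = called[rows_all]
    sub_dos = work.dosage[rows_all]
    has_ref = ((sub_dos < 2) & (sub_dos != MISSING) & sub_called).any(axis=0) | (
        (sub_dos == 1) & sub_called
    ).any(axis=0)
    has_alt = ((sub_dos > 0) & sub_called).any(axis=0)
    overall_poly = has_ref & has_alt
    n_poly = int(overall_poly.sum())
    if n_poly == 0:
        raise PopStatsError("no overall-polymorphic markers")

    reports = []
    for p in pops:
        rows = work.samples_in_pop(p)
        if not called[rows].any():
            raise PopStatsError(f"population {p} has no called genotypes")
        d = work.dosage[rows][:, overall_poly]
        c = d != MISSING
        p_has_alt = ((d > 0) & c).any(axis=0)
        p_has_ref = ((d < 2) & c).any(axis=0)
        mono = (~(p_has_alt & p_has_ref)) & c.any(axis=0)
        n_mono = int(mono.sum())
        reports.append(
            DriftReport(
                population=p,
                n_monomorphic=n_mono,
                fraction_monomorphic=n_mono / n_poly,
                rank=0,
            )
        )
    order = np.argsort([-r.fraction_monomorphic for r in reports], kind="stable")
    for rank, idx in enumerate(order, start=1):
        reports[idx].rank = rank
    return reports


def drift_table(reports: list[DriftReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population": [r.population for r in reports],
            "n_monomorphic": [r.n_monomorphic for r in reports],
            "fraction_monomorphic": [r.fraction_monomorphic for r in reports],
            "rank": [r.rank for r in reports],
        }
    )
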