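"""Two-locus EM haplotype-frequency estimation, R-squared, and
recombination-hotspot flagging by windowed per-population mean R-squared.

For two biallelic loci observed as unphased genotypes, only the double
heterozygote is phase-ambiguous: it is either AB/ab or Ab/aB.  The EM
algorithm splits that cell between the two configurations in proportion to
the current haplotype-frequency products and re-normalises, converging to
a local maximum of the multinomial likelihood.  A marker position is
flagged as a possible recombination hotspot when its windowed mean
R-squared drops below a threshold (default 0.7) in at least one reference
population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: sentinel for statistics undefined at monomorphic loci
UNDEFINED = float("nan")

DEFAULT_R2_THRESHOLD = 0.7


class EstimationError(ValueError):
    pass


@dataclass
class HaplotypeFrequencies:
    """Frequencies of the four two-locus haplotypes AB, Ab, aB, ab."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    converged: bool = True
    n_iter: int = 0

    def as_array(self) -> np.ndarray:
        return np.asarray([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])


def genotype_pair_table(dos1: np.ndarray, dos2: np.ndarray) -> np.ndarray:
    """3x3 genotype count table from two dosage vectors (pairwise deletion).

    Row/column index 0, 1, 2 = copies of the A (resp. B) allele: aa/Aa/AA
    ordering is (2-dosage) so index 0 is the A1-homozygote AA when dosage
    counts A1 copies; orientation is irrelevant to R-squared.
    """
    ok = (dos1 != MISSING) & (dos2 != MISSING)
    t = np.zeros((3, 3), dtype=np.int64)
    np.add.at(t, (2 - dos1[ok].astype(np.int64), 2 - dos2[ok].astype(np.int64)), 1)
    return t


def loglik(table: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under random
    haplotype pairing with haplotype frequencies f = (AB, Ab, aB, ab)."""
    fAB, fAb, faB, fab = (max(x, 0.0) for x in f)
    # genotype probabilities; table indexed by (# a alleles at locus1? see
    # genotype_pair_table: index = 2 - dosage, i.e. 0 = AA, 1 = Aa, 2 = aa)
    pA = np.array(
        [
            [fAB**2, 2 * fAB * fAb, fAb**2],
            [2 * fAB * faB, 2 * (fAB * fab + fAb * faB), 2 * fAb * fab],
            [faB**2, 2 * faB * fab, fab**2],
        ]
    )
    with np.errstate(divide="ignore"):
        logp = np.log(pA)
    if np.any((table > 0) & ~np.isfinite(logp)):
        return -np.inf
    return float(np.sum(table[table > 0] * logp[table > 0]))


def _em_run(
    base: np.ndarray,
    n_dh: float,
    n: float,
    f0: np.ndarray,
    tol: float,
    max_iter: int,
    table: np.ndarray,
    record: list[float] | None,
) -> tuple[np.ndarray, bool, int]:
    f = f0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between AB/ab and Ab/aB
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        denom = cis + trans
        w_cis = 0.5 if denom == 0 else cis / denom
        counts = base.copy()
        counts[0] += n_dh * w_cis
        counts[3] += n_dh * w_cis
        counts[1] += n_dh * (1 - w_cis)
        counts[2] += n_dh * (1 - w_cis)
        # M-step
        f_new = counts / (2 * n)
        if record is not None:
            record.append(loglik(table, f_new))
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    return f, converged, it


def em_haplotype_freqs(
    table: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    trajectory: list[float] | None = None,
) -> HaplotypeFrequencies:
    """EM estimate of two-locus haplotype frequencies from a 3x3 genotype
    count table (indexed 0=AA..2=aa by 0=BB..2=bb).

    The primary run starts at linkage equilibrium (products of observed
    allele frequencies).  Because the LE point splits double
    heterozygotes exactly 50/50, it can be a saddle fixed point for
    tables dominated by that cell, so two further runs start with f_AB
    near each end of its Fréchet interval; the highest-likelihood
    solution is returned.  Each run iterates until the largest absolute
    frequency change is below ``tol`` or ``max_iter`` is reached
    (non-convergence is flagged, the last iterate returned).

    If ``trajectory`` is a list, the per-iteration log-likelihoods of the
    winning run are appended to it (non-decreasing by EM theory).
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n <= 0:
        raise EstimationError("empty genotype table")
    if tol <= 0:
        raise EstimationError("tol must be positive")

    # unambiguous haplotype counts contributed by each cell; the double
    # heterozygote cell (1,1) is handled in the E-step
    base = np.zeros(4)  # AB, Ab, aB, ab
    ncontrib = {
        (0, 0): (2, 0, 0, 0),
        (0, 1): (1, 1, 0, 0),
        (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0),
        (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0),
        (2, 1): (0, 0, 1, 1),
        (2, 2): (0, 0, 0, 2),
    }
    for (i, j), w in ncontrib.items():
        base += table[i, j] * np.asarray(w, dtype=float)
    n_dh = table[1, 1]

    # allele frequencies (A at locus 1, B at locus 2) are fixed by the data
    p_a = (2 * table[0, :].sum() + table[1, :].sum()) / (2 * n)
    p_b = (2 * table[:, 0].sum() + table[:, 1].sum()) / (2 * n)

    def freqs_at(f_ab: float) -> np.ndarray:
        return np.asarray(
            [f_ab, p_a - f_ab, p_b - f_ab, 1 - p_a - p_b + f_ab]
        ).clip(min=0.0)

    starts = [freqs_at(p_a * p_b)]
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if n_dh > 0 and hi - lo > 0:
        delta = min(0.01, (hi - lo) / 4)
        starts += [freqs_at(lo + delta), freqs_at(hi - delta)]

    best = None
    for f0 in starts:
        rec: list[float] = []
        f, converged, it = _em_run(
            base, n_dh, n, f0, tol, max_iter, table, rec
        )
        ll = loglik(table, f)
        if best is None or ll > best[0]:
            best = (ll, f, converged, it, rec)
    _, f, converged, it, rec = best
    if trajectory is not None:
        trajectory.extend(rec)
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return HaplotypeFrequencies(*f, converged=converged, n_iter=it)


def r_squared(freqs: HaplotypeFrequencies) -> float:
    """R-squared LD coefficient; ``nan`` when either locus is monomorphic."""
    p_a = freqs.f_AB + freqs.f_Ab
    p_b = freqs.f_AB + freqs.f_aB
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return UNDEFINED
    d = freqs.f_AB - p_a * p_b
    return float(d * d / denom)


def pair_r2(dos1: np.ndarray, dos2: np.ndarray, tol: float = 1e-8) -> float:
    """EM-based R-squared between two dosage vectors (pairwise deletion)."""
    t = genotype_pair_table(dos1, dos2)
    if t.sum() == 0:
        return UNDEFINED
    return r_squared(em_haplotype_freqs(t, tol=tol))


def window_mean_r2(
    matrix: GenotypeMatrix,
    focal_marker: int,
    flank: int,
    population: str,
) -> float:
    """Mean EM R-squared between a focal marker and its flanking markers
    within one population.

    The window spans ``flank`` markers each side on the same chromosome,
    truncated at chromosome ends; monomorphic flank markers and undefined
    pairs are skipped.  Returns ``nan`` when the focal marker is
    monomorphic in the population or no pair is defined.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    rows = matrix.samples_in_pop(population)
    dos = matrix.dosage[rows]
    c = matrix.chrom[focal_marker]
    lo = focal_marker
    while lo > 0 and matrix.chrom[lo - 1] == c and focal_marker - (lo - 1) <= flank:
        lo -= 1
    hi = focal_marker
    while (
        hi + 1 < matrix.n_markers
        and matrix.chrom[hi + 1] == c
        and (hi + 1) - focal_marker <= flank
    ):
        hi += 1
    focal = dos[:, focal_marker]
    vals = []
    for j in range(lo, hi + 1):
        if j == focal_marker:
            continue
        r2 = pair_r2(focal, dos[:, j])
        if not np.isnan(r2):
            vals.append(r2)
    if not vals:
        return UNDEFINED
    return float(np.mean(vals))


@dataclass
class HotspotScanResult:
    marker_id: str
    mean_r2: dict[str, float]  # per population; nan = undefined
    is_hotspot: bool


def flag_hotspots(
    matrix: GenotypeMatrix,
    populations: list[str] | None = None,
    flank: int = 25,
    threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[HotspotScanResult]:
    """Flag markers whose windowed mean R-squared falls below ``threshold``
    in at least one reference population; undefined means never flag."""
    if populations is None:
        populations = matrix.populations
    if not populations:
        raise ValueError("at least one population required")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    results = []
    for m in range(matrix.n_markers):
        means = {
            pop: window_mean_r2(matrix, m, flank, pop) for pop in populations
        }
        flagged = any(
            not np.isnan(v) and v < threshold for v in means.values()
        )
        results.append(
            HotspotScanResult(
                marker_id=str(matrix.marker_ids[m]), mean_r2=means, is_hotspot=flagged
            )
        )
    return results


def hotspot_table(results: list[HotspotScanResult], matrix: GenotypeMatrix) -> pd.DataFrame:
    """Tabulate a hotspot scan (marker, position, per-pop means, flag)."""
    df = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in results],
            "chrom": matrix.chrom,
            "pos_bp": matrix.pos_bp,
        }
    )
    for pop in results[0].mean_r2:
        df[f"mean_r2_{pop}"] = [r.mean_r2[pop] for r in results]
    df["is_hotspot"] = [r.is_hotspot for r in results]
    return df


def remove_hotspots(
    matrix: GenotypeMatrix, results: list[HotspotScanResult]
) -> GenotypeMatrix:
    """Drop flagged markers, yielding the RH-free dataset."""
    flagged = {r.marker_id for r in results if r.is_hotspot}
    keep = np.asarray([mid not in flagged for mid in matrix.marker_ids])
    logger.info("remove_hotspots: dropping %d of %d markers", len(flagged), matrix.n_markers)
    return matrix.subset_markers(np.flatnonzero(keep))
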