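"""Regional-specific-marker (RSM) selection by allele-frequency variance
analysis.

Per marker, each population's deviation variance is
``var_i = (p_i - p_bar)^2`` where ``p_i`` is the population allele
frequency and ``p_bar`` the pooled frequency over all populations; the
z-score of ``var_i`` against the mean and (denominator-K) standard
deviation of the variances across populations flags populations whose
frequency is a strong outlier.  A marker is a regional specific marker
when any population has |z| above a threshold (default 4.0).  Selected
markers closer than a maximum gap (default 500 kb) are thinned to the
first marker of each run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

DEFAULT_Z_THRESHOLD = 4.0
DEFAULT_THIN_BP = 500_000


class RsmError(ValueError):
    pass


def allele_frequency(n11: int, n12: int, n22: int) -> float:
    """Allele-1 frequency from the three genotype-class counts; ``nan``
    when no samples are called."""
    n = n11 + n12 + n22
    if n == 0:
        return float("nan")
    return (2 * n11 + n12) / (2 * n)


@dataclass
class MarkerVarianceRecord:
    marker_id: str
    p_bar: float
    p: dict[str, float]  # per-population frequency (nan if uncalled)
    var: dict[str, float]  # (p_i - p_bar)^2
    mu: float
    sigma: float
    z: dict[str, float]
    usable: bool  # >= 3 populations with defined frequency


def marker_variance_table(
    matrix: GenotypeMatrix, populations: list[str] | None = None
) -> pd.DataFrame:
    """Vectorised per-marker frequencies, variances and z-scores.

    Returns a DataFrame with columns ``marker_id, chrom, pos_bp, p_bar,
    p_<pop>.., var_<pop>.., z_<pop>.., n_pops_defined, usable``.
    Populations with zero called samples at a marker are excluded from
    that marker's mean and standard deviation; when sigma is zero all
    z-scores are zero.
    """
    if populations is None:
        populations = matrix.populations
    if len(populations) < 2:
        raise RsmError("at least two populations required")
    called = matrix.dosage != MISSING
    dos = np.where(called, matrix.dosage, 0).astype(np.int64)

    p_cols, names = [], []
    pooled_alt = np.zeros(matrix.n_markers)
    pooled_n = np.zeros(matrix.n_markers)
    for pop in populations:
        rows = matrix.samples_in_pop(pop)
        n_called = called[rows].sum(axis=0)
        alt = dos[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        p_cols.append(p)
        names.append(pop)
        pooled_alt += alt
        pooled_n += n_called
    p_mat = np.vstack(p_cols)  # K x M
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = np.where(pooled_n > 0, pooled_alt / (2.0 * pooled_n), np.nan)

    var = (p_mat - p_bar) ** 2
    defined = ~np.isnan(var)
    k_def = defined.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.nanmean(np.where(defined, var, np.nan), axis=0)
        # population-count denominator (K), not K-1
        sigma = np.sqrt(
            np.nanmean(np.where(defined, (var - mu) ** 2, np.nan), axis=0)
        )
        z = np.where(sigma > 0, (var - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    z = np.where(defined, z, np.nan)

    df = pd.DataFrame(
        {
            "marker_id": matrix.marker_ids,
            "chrom": matrix.chrom,
            "pos_bp": matrix.pos_bp,
            "p_bar": p_bar,
        }
    )
    for i, pop in enumerate(names):
        df[f"p_{pop}"] = p_mat[i]
    for i, pop in enumerate(names):
        df[f"var_{pop}"] = var[i]
    for i, pop in enumerate(names):
        df[f"z_{pop}"] = z[i]
    df["n_pops_defined"] = k_def
    df["usable"] = k_def >= 3
    return df


def marker_variances(
    matrix: GenotypeMatrix, populations: list[str] | None = None
) -> list[MarkerVarianceRecord]:
    """Record view of :func:`marker_variance_table`."""
    if populations is None:
        populations = matrix.populations
    df = marker_variance_table(matrix, populations)
    out = []
    for _, row in df.iterrows():
        p = {pop: row[f"p_{pop}"] for pop in populations}
        var = {pop: row[f"var_{pop}"] for pop in populations}
        z = {pop: row[f"z_{pop}"] for pop in populations}
        vals = [v for v in var.values() if not np.isnan(v)]
        mu = float(np.mean(vals)) if vals else float("nan")
        sigma = float(np.sqrt(np.mean((np.asarray(vals) - mu) ** 2))) if vals else float("nan")
        out.append(
            MarkerVarianceRecord(
                marker_id=row["marker_id"],
                p_bar=row["p_bar"],
                p=p,
                var=var,
                mu=mu,
                sigma=sigma,
                z=z,
                usable=bool(row["usable"]),
            )
        )
    return out


def select_rsm(
    table: pd.DataFrame, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> pd.DataFrame:
    """Add a ``selected`` column: any defined |z| above the threshold on a
    usable marker."""
    if z_threshold <= 0:
        raise RsmError("z_threshold must be positive")
    z_cols = [c for c in table.columns if c.startswith("z_")]
    zmat = table[z_cols].to_numpy()
    absz = np.where(np.isnan(zmat), -np.inf, np.abs(zmat))
    hit = absz.max(axis=1) > z_threshold
    out = table.copy()
    out["selected"] = hit & out["usable"].to_numpy()
    return out


def thin_by_distance(
    selected: pd.DataFrame, max_gap_bp: int = DEFAULT_THIN_BP
) -> pd.DataFrame:
    """Collapse each run of selected markers with consecutive gaps at or
    below ``max_gap_bp`` (within a chromosome) to its first marker.

    Input must carry ``chrom`` and ``pos_bp`` sorted by position within
    each chromosome; unsorted input is an error, never silently sorted.
    Adds a ``retained_after_thinning`` column.
    """
    out = selected.copy()
    out["retained_after_thinning"] = False
    for c in dict.fromkeys(out["chrom"]):
        sub = out[out["chrom"] == c]
        if not sub["pos_bp"].is_monotonic_increasing:
            raise RsmError(f"markers unsorted on chromosome {c}")
        prev_pos = None
        for idx, row in sub.iterrows():
            if not row["selected"]:
                continue
            if prev_pos is None or row["pos_bp"] - prev_pos > max_gap_bp:
                out.loc[idx, "retained_after_thinning"] = True
            prev_pos = row["pos_bp"]
    return out


def rsm_marker_ids(table: pd.DataFrame, thinned: bool = True) -> list[str]:
    col = "retained_after_thinning" if thinned else "selected"
    return list(table.loc[table[col], "marker_id"])
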