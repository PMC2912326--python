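"""Genotype-call-rate bookkeeping: measurement, random no-call insertion
to reach target call rates (the data1/data2/data3 experiment), and
marker-level call-rate QC.

Per sample, GCR_i = N_gt / (N_gt + N_ng + N_ig) where N_gt, N_ng and N_ig
count successful genotypes, natural no-calls and randomly inserted
no-calls; the three always sum to the marker total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: the canonical degraded-call-rate grid of the experiment design
CANONICAL_TARGETS = (0.95, 0.90, 0.85)


class CallRateError(ValueError):
    pass


@dataclass
class CallRates:
    per_sample: pd.Series  # GCR per sample
    per_marker: pd.Series  # call rate per marker
    overall: float  # mean of per-sample GCRs


def call_rate(matrix: GenotypeMatrix) -> CallRates:
    """Per-sample GCR, per-marker call rate, and their overall mean."""
    if matrix.n_markers == 0 or matrix.n_samples == 0:
        raise CallRateError("call rate undefined on an empty matrix")
    called = matrix.dosage != MISSING
    per_sample = pd.Series(
        called.mean(axis=1), index=list(matrix.sample_ids), name="gcr"
    )
    per_marker = pd.Series(
        called.mean(axis=0), index=list(matrix.marker_ids), name="call_rate"
    )
    return CallRates(per_sample, per_marker, float(per_sample.mean()))


def n_inserted_no_calls(total: int, n_ng: int, target_gcr: float) -> int:
    """Inserted no-calls needed so GCR = N_gt/total hits the target:
    N_ig = round(total * (1 - target)) - N_ng, floored at zero."""
    return max(int(round(total * (1.0 - target_gcr))) - n_ng, 0)


def degrade_call_rate(
    matrix: GenotypeMatrix, target_gcr: float, seed: int
) -> GenotypeMatrix:
    """Insert no-calls uniformly at random per sample until each sample's
    GCR reaches the target; natural no-calls are untouched."""
    if not 0.0 < target_gcr <= 1.0:
        raise CallRateError("target_gcr must be in (0, 1]")
    total = matrix.n_markers
    n_ng = (matrix.dosage == MISSING).sum(axis=1)
    current = 1.0 - n_ng / total
    too_low = current < target_gcr - 1e-12
    if too_low.any():
        bad = [str(s) for s in matrix.sample_ids[too_low]]
        raise CallRateError(
            f"target {target_gcr} above current call rate for samples: {bad}"
        )
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for i in range(matrix.n_samples):
        n_ig = n_inserted_no_calls(total, int(n_ng[i]), target_gcr)
        if n_ig == 0:
            continue
        called_idx = np.flatnonzero(out.dosage[i] != MISSING)
        hit = rng.choice(called_idx, size=n_ig, replace=False)
        out.dosage[i, hit] = MISSING
    return out


def degrade_grid(
    matrix: GenotypeMatrix, targets=CANONICAL_TARGETS, seed: int = 0
) -> dict[str, GenotypeMatrix]:
    """data0 (untouched) plus one degraded dataset per target rate."""
    out = {"data0": matrix}
    for k, t in enumerate(targets, start=1):
        out[f"data{k}"] = degrade_call_rate(matrix, t, seed=seed + k)
    return out


def filter_markers_by_call_rate(
    matrix: GenotypeMatrix, cutoff: float
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with call rate strictly below the cutoff (a marker at
    exactly the cutoff is retained).  Returns (filtered matrix, dropped
    table with rates)."""
    if not 0.0 <= cutoff <= 1.0:
        raise CallRateError("cutoff must be in [0, 1]")
    rates = (matrix.dosage != MISSING).mean(axis=0)
    keep = rates >= cutoff
    dropped = pd.DataFrame(
        {
            "marker_id": matrix.marker_ids[~keep],
            "call_rate": rates[~keep],
        }
    )
    if len(dropped):
        logger.info(
            "filter_markers_by_call_rate: dropped %d of %d markers below %.2f",
            len(dropped), matrix.n_markers, cutoff,
        )
    return matrix.subset_markers(np.flatnonzero(keep)), dropped
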