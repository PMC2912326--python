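"""Central genotype container shared by every pipeline stage.

Genotypes are stored as dosages of the A1 allele (0, 1 or 2 copies);
``MISSING`` (-1) marks a no-call.  Allele characters are kept per marker so
that PED round trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING: int = -1


class GenotypeDataError(ValueError):
    """Raised when genotype data violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid biallelic genotype matrix.

    Attributes
    ----------
    sample_ids : array of str
        Unique sample identifiers.
    pop_labels : array of str
        Population label per sample (PED family ID); never empty.
    marker_ids : array of str
        Unique marker identifiers.
    chrom : array of str
        Chromosome label per marker.
    pos_bp : array of int
        1-based base-pair position, strictly increasing within a chromosome.
    alleles : (M, 2) array of str
        A1 (minor) and A2 (major) allele characters per marker.
    dosage : (N, M) int8 array
        Copies of A1 per call, or ``MISSING``.
    genetic_distance : array of float, optional
        Morgans column carried through from MAP files (unused downstream).
    """

    sample_ids: np.ndarray
    pop_labels: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray
    dosage: np.ndarray
    genetic_distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.genetic_distance is None:
            self.genetic_distance = np.zeros(self.n_markers, dtype=float)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != self.n_samples or m != self.n_markers:
            raise GenotypeDataError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{self.n_samples} samples x {self.n_markers} markers"
            )
        if len(self.pop_labels) != n:
            raise GenotypeDataError("one population label per sample required")
        if any(not str(p) for p in self.pop_labels):
            raise GenotypeDataError("population labels must be non-empty")
        if len(self.chrom) != m or len(self.pos_bp) != m:
            raise GenotypeDataError("chrom/pos arrays must match marker count")
        if self.alleles.shape != (m, 2):
            raise GenotypeDataError("alleles must be an (M, 2) array")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise GenotypeDataError("dosages must be in {-1, 0, 1, 2}")
        if m and (self.pos_bp < 1).any():
            raise GenotypeDataError("positions must be 1-based (>= 1)")
        for c in dict.fromkeys(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise GenotypeDataError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    # -- subsetting ----------------------------------------------------
    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=self.sample_ids[index],
            pop_labels=self.pop_labels[index],
            dosage=self.dosage[index].copy(),
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            marker_ids=self.marker_ids[index],
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            alleles=self.alleles[index],
            genetic_distance=self.genetic_distance[index],
            dosage=self.dosage[:, index].copy(),
        )

    def samples_in_pop(self, pop: str) -> np.ndarray:
        """Row indices of the samples belonging to ``pop``."""
        idx = np.flatnonzero(self.pop_labels == pop)
        if idx.size == 0:
            raise GenotypeDataError(f"population {pop!r} not present")
        return idx

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        return list(dict.fromkeys(self.pop_labels))

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            sample_ids=self.sample_ids.copy(),
            pop_labels=self.pop_labels.copy(),
            marker_ids=self.marker_ids.copy(),
            chrom=self.chrom.copy(),
            pos_bp=self.pos_bp.copy(),
            alleles=self.alleles.copy(),
            genetic_distance=self.genetic_distance.copy(),
            dosage=self.dosage.copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.pop_labels, other.pop_labels)
            and np.array_equal(self.marker_ids, other.marker_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos_bp, other.pos_bp)
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.dosage, other.dosage)
        )
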