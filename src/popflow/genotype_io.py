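"""Text-format I/O: PLINK PED/MAP, PHYLIP square distance matrices,
eigenvector tables and STRUCTURE export.

The PED family-ID column doubles as the population label.  Allele "0" is
the missing code; a half-missing call ("A 0") is treated as fully missing.
Per marker, A1 is the minor allele over the whole dataset, with ties
broken lexicographically, so parsing is reproducible.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeDataError, GenotypeMatrix

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when a genotype text file is malformed."""


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text fileset into a :class:`GenotypeMatrix`."""
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 columns")
            map_rows.append(parts)
    chrom = np.asarray([r[0] for r in map_rows], dtype=object)
    marker_ids = np.asarray([r[1] for r in map_rows], dtype=object)
    gdist = np.asarray([float(r[2]) for r in map_rows])
    pos_bp = np.asarray([int(r[3]) for r in map_rows], dtype=np.int64)
    m = len(map_rows)

    sample_ids, pop_labels, allele_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} columns "
                    f"(6 + 2 x {m} markers), got {len(parts)}"
                )
            pop_labels.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    n = len(sample_ids)
    a = np.asarray(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), dtype=object)

    alleles = np.empty((m, 2), dtype=object)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    half_missing = 0
    for j in range(m):
        col = a[:, j, :]
        miss = (col == "0").any(axis=1)
        half_missing += int(((col == "0").sum(axis=1) == 1).sum())
        observed = Counter(col[~miss].ravel().tolist())
        if len(observed) > 2:
            raise GenotypeDataError(
                f"marker {marker_ids[j]}: more than two alleles "
                f"{sorted(observed)}"
            )
        if len(observed) == 0:
            a1, a2 = "A", "A"  # fully missing marker: placeholder alleles
        elif len(observed) == 1:
            a1 = a2 = next(iter(observed))
        else:
            # minor first; ties lexicographic
            a1, a2 = sorted(observed, key=lambda al: (observed[al], al))
        alleles[j] = (a1, a2)
        called = ~miss
        dosage[called, j] = (col[called] == a1).sum(axis=1)
    if half_missing:
        logger.info("read_ped_map: %d half-missing calls treated as missing", half_missing)
    return GenotypeMatrix(
        sample_ids=np.asarray(sample_ids, dtype=object),
        pop_labels=np.asarray(pop_labels, dtype=object),
        marker_ids=marker_ids,
        chrom=chrom,
        pos_bp=pos_bp,
        alleles=alleles,
        genetic_distance=gdist,
        dosage=dosage,
    )


def write_ped_map(matrix: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PED/MAP files; MISSING becomes ``0 0``.  Returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for j in range(matrix.n_markers):
            fh.write(
                f"{matrix.chrom[j]}\t{matrix.marker_ids[j]}\t"
                f"{matrix.genetic_distance[j]:g}\t{matrix.pos_bp[j]}\n"
            )
    with open(ped_path, "w") as fh:
        for i in range(matrix.n_samples):
            fields = [
                str(matrix.pop_labels[i]),
                str(matrix.sample_ids[i]),
                "0", "0", "0", "-9",
            ]
            row = matrix.dosage[i]
            for j in range(matrix.n_markers):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    a1, a2 = matrix.alleles[j]
                    fields += [a1] * int(d) + [a2] * (2 - int(d))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def _phylip_names(sample_ids) -> list[str]:
    """Truncate to 10 characters, disambiguating clashes with numeric
    suffixes; raises if disambiguation is impossible."""
    names, seen = [], {}
    for sid in sample_ids:
        base = str(sid)[:10]
        if base not in seen:
            seen[base] = 0
            names.append(base)
            continue
        seen[base] += 1
        suffix = f"~{seen[base]}"
        cand = base[: 10 - len(suffix)] + suffix
        while cand in seen:
            seen[base] += 1
            suffix = f"~{seen[base]}"
            cand = base[: 10 - len(suffix)] + suffix
        seen[cand] = 0
        names.append(cand)
    if len(set(names)) != len(names):
        raise GenotypeDataError("could not disambiguate truncated PHYLIP names")
    return names


def write_distance_phylip(dist, path) -> Path:
    """Write a square PHYLIP distance matrix (names padded to 10 chars)."""
    values = np.asarray(dist.values, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise GenotypeDataError("distance matrix must be square")
    if not np.allclose(values, values.T) or not np.allclose(np.diag(values), 0):
        raise GenotypeDataError("distance matrix must be symmetric with zero diagonal")
    names = _phylip_names(dist.sample_ids)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n")
        for name, row in zip(names, values):
            fh.write(f"{name:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")
    return path


def read_distance_phylip(path) -> tuple[list[str], np.ndarray]:
    """Read a square PHYLIP distance matrix; returns (names, values)."""
    with open(path) as fh:
        header = fh.readline().split()
        n = int(header[0])
        names, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            names.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(rows) != n:
        raise ParseError(f"{path}: expected {n} rows, found {len(rows)}")
    return names, np.asarray(rows)


def export_structure(matrix: GenotypeMatrix, path) -> tuple[Path, Path]:
    """Write STRUCTURE input (two rows per individual, alleles 1/2,
    missing -9) plus a ``.pops`` legend mapping integer codes to labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pops = matrix.populations
    code = {p: k + 1 for k, p in enumerate(pops)}
    with open(path, "w") as fh:
        for i in range(matrix.n_samples):
            d = matrix.dosage[i]
            for hap in range(2):
                alleles = np.where(
                    d == MISSING, -9, np.where(d > hap, 1, 2)
                )
                fh.write(
                    f"{matrix.sample_ids[i]} {code[matrix.pop_labels[i]]} "
                    + " ".join(str(x) for x in alleles)
                    + "\n"
                )
    legend = path.with_suffix(path.suffix + ".pops")
    with open(legend, "w") as fh:
        for p in pops:
            fh.write(f"{code[p]}\t{p}\n")
    return path, legend


def write_embedding_tsv(embedding, pop_labels, path) -> Path:
    """Write sample coordinates as TSV: sample_id, pop, C1..Ck."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    k = embedding.coordinates.shape[1]
    df = pd.DataFrame(
        embedding.coordinates, columns=[f"C{i + 1}" for i in range(k)]
    )
    df.insert(0, "pop", list(pop_labels))
    df.insert(0, "sample_id", list(embedding.sample_ids))
    df.to_csv(path, sep="\t", index=False)
    return path
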