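"""Core data model and I/O for dominant bi-allelic marker panels.

The central object is :class:`BiallelicGenotypeMatrix`, an accessions x
markers table of band presence (1) / absence (0) calls with explicit
missing values.  Accessions are inbred lines treated as homozygous, so a
call is a single haploid allele and the allele frequency of a marker is
simply the presence frequency among non-missing calls.

Also provided: a physical marker map (chromosome, 1-based bp), ancestry
proportion (Q) matrices from model-based clustering runs, a haploid-coded
multi-allelic matrix (SSR/RFLP-like), group assignments, and symmetric
dissimilarity matrices.  Delimited-text readers auto-detect comma vs tab
from the header line; ``NA``, ``N``, ``-`` and the empty string all parse
as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNASSIGNED",
    "BiallelicGenotypeMatrix",
    "MultiAllelicGenotypeMatrix",
    "MarkerMap",
    "QMatrix",
    "GroupAssignment",
    "DissimilarityMatrix",
    "read_biallelic_genotypes",
    "write_biallelic_genotypes",
    "read_marker_map",
    "read_q_matrix",
    "filter_markers",
]

#: Label used for accessions whose maximum ancestry proportion does not
#: exceed the membership threshold.
UNASSIGNED = "UNASSIGNED"

_MISSING_TOKENS = {"NA", "N", "-", "", "NAN"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class BiallelicGenotypeMatrix:
    """Accessions x markers presence/absence calls (NaN = missing)."""

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # float array, values in {0.0, 1.0, nan}

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.marker_ids, "marker")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0))][0]
            raise ValueError(f"genotype calls must be 0, 1 or missing; found {bad!r}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.calls).mean(axis=0)

    def presence_frequency(self) -> np.ndarray:
        """Per-marker presence-allele frequency among non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.calls, axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency, min(p, 1-p)."""
        p = self.presence_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_accessions(self, ids: Sequence[str]) -> "BiallelicGenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [index[a] for a in ids]
        return BiallelicGenotypeMatrix(list(ids), list(self.marker_ids), self.calls[rows])

    def subset_markers(self, ids: Sequence[str]) -> "BiallelicGenotypeMatrix":
        index = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [index[m] for m in ids]
        return BiallelicGenotypeMatrix(list(self.accession_ids), list(ids), self.calls[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accession_ids, columns=self.marker_ids)


@dataclass
class MultiAllelicGenotypeMatrix:
    """Haploid-coded multi-allelic matrix: one allele label per cell.

    Heterozygous calls are assumed to have been resolved upstream by
    randomly sampling one of the two alleles; labels are opaque strings
    and ``None`` marks a missing call.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    alleles: np.ndarray  # object array of str or None

    def __post_init__(self) -> None:
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.locus_ids, "locus")
        self.alleles = np.asarray(self.alleles, dtype=object)
        if self.alleles.shape != (len(self.accession_ids), len(self.locus_ids)):
            raise ValueError("alleles shape does not match ids")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass
class MarkerMap:
    """Physical positions of markers (chromosome label, 1-based bp)."""

    marker_ids: list[str]
    chromosomes: list[str]
    positions_bp: np.ndarray  # int, 1-based

    def __post_init__(self) -> None:
        _check_unique(self.marker_ids, "marker")
        self.positions_bp = np.asarray(self.positions_bp)
        if not np.issubdtype(self.positions_bp.dtype, np.integer):
            as_int = self.positions_bp.astype(np.int64)
            if not np.array_equal(as_int, self.positions_bp):
                raise ValueError("marker positions must be integers")
            self.positions_bp = as_int
        if (self.positions_bp < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        if len(self.chromosomes) != len(self.marker_ids) or len(self.positions_bp) != len(
            self.marker_ids
        ):
            raise ValueError("marker map columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def chromosome_of(self) -> dict[str, str]:
        return dict(zip(self.marker_ids, self.chromosomes))

    def position_of(self) -> dict[str, int]:
        return dict(zip(self.marker_ids, self.positions_bp.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chromosome": self.chromosomes,
                "position_bp": self.positions_bp,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class QMatrix:
    """Accessions x K ancestry proportions; rows sum to 1."""

    accession_ids: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.accession_ids, "accession")
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.accession_ids):
            raise ValueError("q must be n_accessions x K")
        if self.q.shape[1] < 1:
            raise ValueError("K must be >= 1")
        if (self.q < 0).any():
            raise ValueError("negative membership proportion")
        sums = self.q.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("Q-matrix rows must sum to 1 within 1e-6")

    @property
    def K(self) -> int:
        return self.q.shape[1]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.q, index=self.accession_ids, columns=cols)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="accession")


@dataclass
class GroupAssignment:
    """Mapping accession -> group label (1..K) or :data:`UNASSIGNED`."""

    assignments: dict[str, int | str]

    def __post_init__(self) -> None:
        for a, g in self.assignments.items():
            if g != UNASSIGNED and not isinstance(g, (int, np.integer)):
                raise ValueError(f"group label for {a!r} must be an int or UNASSIGNED")

    def group_of(self, accession: str) -> int | str:
        return self.assignments[accession]

    def groups(self) -> list[int]:
        return sorted({g for g in self.assignments.values() if g != UNASSIGNED})

    def members(self, group: int | str) -> list[str]:
        return [a for a, g in self.assignments.items() if g == group]

    def assigned(self) -> list[str]:
        return [a for a, g in self.assignments.items() if g != UNASSIGNED]

    def __len__(self) -> int:
        return len(self.assignments)

    @classmethod
    def from_labels(cls, accession_ids: Sequence[str], labels: Iterable[int | str]) -> "GroupAssignment":
        return cls(dict(zip(accession_ids, labels)))


@dataclass
class DissimilarityMatrix:
    """Symmetric accession dissimilarities in [0, 1] with zero diagonal."""

    accession_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.accession_ids, "accession")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("dissimilarities must lie in [0, 1]")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("dissimilarity matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def subset(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [index[a] for a in ids]
        return DissimilarityMatrix(list(ids), self.values[np.ix_(rows, rows)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.accession_ids, columns=self.accession_ids).to_csv(
            path, index_label="accession"
        )

    @classmethod
    def read(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(a) for a in df.index], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_biallelic_genotypes(
    path: str | Path, delimiter: str | None = None
) -> BiallelicGenotypeMatrix:
    """Read a 0/1/NA genotype table (header = marker ids, first column = accessions).

    Cells outside {0, 1, NA} raise a :class:`ValueError` naming the
    offending row and column; missing cells are recorded as missing,
    never silently as 0.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    accession_ids = [str(a) for a in df.index]
    marker_ids = [str(m) for m in df.columns]
    _check_unique(accession_ids, "accession")
    _check_unique(marker_ids, "marker")
    calls = np.empty(df.shape, dtype=float)
    raw = df.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok.upper() in _MISSING_TOKENS:
                calls[i, j] = np.nan
            elif tok in ("0", "0.0"):
                calls[i, j] = 0.0
            elif tok in ("1", "1.0"):
                calls[i, j] = 1.0
            else:
                raise ValueError(
                    f"invalid call {tok!r} at accession {accession_ids[i]!r}, "
                    f"marker {marker_ids[j]!r}; expected 0, 1 or NA"
                )
    return BiallelicGenotypeMatrix(accession_ids, marker_ids, calls)


def write_biallelic_genotypes(
    gm: BiallelicGenotypeMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write a genotype matrix losslessly (missing written as ``NA``)."""
    out = np.empty(gm.calls.shape, dtype=object)
    out[gm.calls == 0] = "0"
    out[gm.calls == 1] = "1"
    out[np.isnan(gm.calls)] = "NA"
    pd.DataFrame(out, index=gm.accession_ids, columns=gm.marker_ids).to_csv(
        path, sep=delimiter, index_label="accession"
    )


def read_marker_map(
    path: str | Path, coordinate_convention: str = "onebased_tsv"
) -> MarkerMap:
    """Read a marker map.

    ``onebased_tsv``: columns marker / chromosome / position (1-based).
    ``bed``: standard 0-based half-open BED (chrom, start, end, name);
    positions are converted to 1-based via ``start + 1``.
    """
    if coordinate_convention == "onebased_tsv":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 3:
            raise ValueError("marker map needs marker/chromosome/position columns")
        markers = [str(m) for m in df.iloc[:, 0]]
        chroms = [str(c) for c in df.iloc[:, 1]]
        pos = df.iloc[:, 2].to_numpy()
    elif coordinate_convention == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 4:
            raise ValueError("BED marker map needs chrom/start/end/name columns")
        chroms = [str(c) for c in df.iloc[:, 0]]
        pos = df.iloc[:, 1].to_numpy() + 1  # 0-based start -> 1-based
        markers = [str(m) for m in df.iloc[:, 3]]
    else:
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    try:
        pos = np.asarray(pos, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("non-numeric marker position") from exc
    if np.isnan(pos).any() or not np.array_equal(pos, np.floor(pos)):
        raise ValueError("marker positions must be integers")
    return MarkerMap(markers, chroms, pos.astype(np.int64))


def read_q_matrix(path: str | Path) -> QMatrix:
    """Read an ancestry (Q) matrix CSV with an accession id column.

    Rows are renormalized when their sum is within 1e-3 of 1; anything
    further off, or any negative membership, is a hard error.  Native
    clustering-program report files are not parsed — export the plain
    numeric matrix first (see the package docs for a converter recipe).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    q = df.to_numpy(dtype=float)
    if (q < 0).any():
        raise ValueError("negative membership proportion in Q-matrix")
    sums = q.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"Q-matrix row {df.index[i]!r} sums to {sums[i]:.6f}, outside [0.999, 1.001]"
        )
    q = q / sums[:, None]
    return QMatrix([str(a) for a in df.index], q)


# ---------------------------------------------------------------------------
# Filtering


def filter_markers(
    gm: BiallelicGenotypeMatrix, max_missing: float = 0.2, min_maf: float = 0.05
) -> BiallelicGenotypeMatrix:
    """Keep markers with missing fraction strictly below ``max_missing``
    and MAF at least ``min_maf``.

    The missing-data rule is strict ("less than" the threshold); the MAF
    rule is inclusive ("at least").  Idempotent; accession order is
    preserved.  An empty result warns rather than raising.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    miss = gm.missing_fraction()
    maf = gm.maf()
    keep = (miss < max_missing) & ~np.isnan(maf) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("no markers survive filtering", stacklevel=2)
    kept_ids = [m for m, k in zip(gm.marker_ids, keep) if k]
    return BiallelicGenotypeMatrix(
        list(gm.accession_ids), kept_ids, gm.calls[:, keep]
    )
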