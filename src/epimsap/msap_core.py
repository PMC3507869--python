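"""MSAP band-matrix data model, TSV/GenAlEx I/O, distances and PCoA.

The unit of analysis is a binary samples x loci band matrix per restriction
enzyme (HpaII or MspI).  Distances between samples are Euclidean or squared
Euclidean on the 0/1 band vectors; for binary profiles the squared Euclidean
distance is exactly the count of discordant loci.  Principal coordinate
analysis (classical metric MDS) is the Gower double-centring
eigendecomposition of -d^2/2.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MSAPMatrix",
    "DistanceMatrix",
    "PcoaResult",
    "MSAPParseError",
    "read_msap",
    "write_msap",
    "write_genalex",
    "pairwise_distance",
    "pcoa",
    "group_centroids",
]

META_COLUMNS = ("sample", "line", "generation", "enzyme")


class MSAPParseError(ValueError):
    """Raised when an MSAP file violates the expected binary TSV dialect."""


@dataclass
class MSAPMatrix:
    """Binary samples x loci band matrix for one enzyme digest.

    ``values`` holds floats 0.0/1.0 with NaN for missing cells; the index is
    the unique sample ids and columns are locus ids.  ``line_ids`` and
    ``generations`` are per-sample metadata aligned to the index.
    """

    values: pd.DataFrame
    line_ids: pd.Series
    generations: pd.Series
    enzyme: str

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MSAPParseError(f"duplicated sample id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~(np.isnan(arr) | (arr == 0) | (arr == 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MSAPParseError(
                f"non-binary value {arr[i, j]!r} at sample "
                f"{self.values.index[i]!r}, locus {self.values.columns[j]!r}"
            )
        for name, series in (("line_ids", self.line_ids),
                             ("generations", self.generations)):
            if not series.index.equals(self.values.index):
                raise ValueError(f"{name} must be indexed by the sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids) -> "MSAPMatrix":
        """Row subset preserving metadata."""
        return MSAPMatrix(
            values=self.values.loc[sample_ids],
            line_ids=self.line_ids.loc[sample_ids],
            generations=self.generations.loc[sample_ids],
            enzyme=self.enzyme,
        )

    def to_frame(self) -> pd.DataFrame:
        """Full table with metadata columns, as written to TSV."""
        out = pd.DataFrame(
            {
                "sample": self.values.index,
                "line": self.line_ids.to_numpy(),
                "generation": self.generations.to_numpy(),
                "enzyme": self.enzyme,
            }
        )
        bands = self.values.reset_index(drop=True)
        return pd.concat([out, bands], axis=1)


def assert_paired(a: MSAPMatrix, b: MSAPMatrix) -> None:
    """Check the two-enzyme pairing contract (same samples, same loci)."""
    if a.sample_ids != b.sample_ids:
        raise ValueError("paired MSAP matrices must share sample ids and order")
    if a.locus_ids != b.locus_ids:
        raise ValueError("paired MSAP matrices must share locus ids")


def read_msap(path) -> MSAPMatrix:
    """Read an MSAP matrix from TSV (``#`` comment lines allowed).

    Expected columns: ``sample``, ``line``, ``generation``, ``enzyme``
    followed by one column per locus with 0/1 entries (empty = missing).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise MSAPParseError(f"{path}: missing metadata columns {missing}")
    locus_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not locus_cols:
        raise MSAPParseError(f"{path}: no locus columns found")
    enzymes = df["enzyme"].unique()
    if len(enzymes) != 1:
        raise MSAPParseError(f"{path}: mixed enzyme labels {list(enzymes)}")
    values = df[locus_cols].apply(pd.to_numeric, errors="coerce")
    # Cells that are non-empty but failed numeric conversion are a dialect
    # violation, as are numeric values outside {0, 1}.
    raw = df[locus_cols]
    for j, col in enumerate(locus_cols):
        converted = values[col]
        original = raw[col]
        bad = converted.isna() & original.notna()
        bad |= converted.notna() & ~converted.isin([0.0, 1.0])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise MSAPParseError(
                f"{path}: non-binary value {original.iloc[i]!r} at sample "
                f"{df['sample'].iloc[i]!r}, locus {col!r}"
            )
    values = values.astype(float)
    values.index = df["sample"]
    values.index.name = None
    return MSAPMatrix(
        values=values,
        line_ids=pd.Series(df["line"].to_numpy(), index=values.index),
        generations=pd.Series(df["generation"].to_numpy(), index=values.index),
        enzyme=str(enzymes[0]),
    )


def write_msap(path, matrix: MSAPMatrix, header_comment: str | None = None) -> None:
    """Write an MSAP matrix as UTF-8 TSV; missing cells become empty fields."""
    frame = matrix.to_frame()
    locus_cols = matrix.locus_ids
    frame[locus_cols] = frame[locus_cols].astype("Int64")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_genalex(path, matrix: MSAPMatrix, title: str = "MSAP export") -> None:
    """Write a GenAlEx-style binary (haploid) CSV export.

    Layout: first header row with locus/sample/population counts and the
    per-population sizes, second row with the dataset title and population
    names, third row with column headers, then one row per sample
    (sample, population, 0/1 bands).  Populations are the line ids.
    """
    pops = list(dict.fromkeys(matrix.line_ids))
    sizes = [int((matrix.line_ids == p).sum()) for p in pops]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([matrix.n_loci, matrix.n_samples, len(pops), *sizes])
        w.writerow([title, "", "", *pops])
        w.writerow(["Sample", "Pop", *matrix.locus_ids])
        for sid in matrix.sample_ids:
            band = matrix.values.loc[sid]
            cells = ["" if pd.isna(v) else int(v) for v in band]
            w.writerow([sid, matrix.line_ids.loc[sid], *cells])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a metric tag."""

    data: np.ndarray
    ids: list[str]
    metric: str  # "euclidean" | "squared_euclidean"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < 0):
            raise ValueError("distances must be non-negative")
        if self.metric not in ("euclidean", "squared_euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def squared(self) -> np.ndarray:
        """Entries as squared Euclidean distances, whatever the tag."""
        return self.data if self.metric == "squared_euclidean" else self.data**2


def pairwise_distance(matrix: MSAPMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise (squared) Euclidean distances between sample band vectors.

    Missing cells are handled pairwise-complete: for each sample pair, loci
    missing in either profile are excluded from the sum (logged as a
    warning).  A sample with an all-missing profile is an error.
    """
    if metric not in ("euclidean", "squared_euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    X = matrix.values.to_numpy(dtype=float)
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        sid = matrix.sample_ids[int(np.flatnonzero(miss.all(axis=1))[0])]
        raise ValueError(f"sample {sid!r} has an all-missing profile")
    if miss.any():
        logger.warning(
            "%d missing cells: using pairwise-complete locus exclusion",
            int(miss.sum()),
        )
        M = (~miss).astype(float)
        X0 = np.where(miss, 0.0, X)
        X2 = X0**2
        D2 = X2 @ M.T + M @ X2.T - 2.0 * (X0 @ X0.T)
    else:
        sq = (X**2).sum(axis=1)
        D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    D2 = np.maximum(D2, 0.0)
    np.fill_diagonal(D2, 0.0)
    D2 = (D2 + D2.T) / 2.0
    data = D2 if metric == "squared_euclidean" else np.sqrt(D2)
    return DistanceMatrix(data=data, ids=matrix.sample_ids, metric=metric)


@dataclass
class PcoaResult:
    """Principal coordinates, eigenvalues and explained-variance shares.

    ``coordinates`` has one column per retained positive-eigenvalue axis,
    scaled by sqrt(eigenvalue) and centred at zero.  ``eigenvalues`` carries
    the full descending spectrum (negative values included for diagnostics);
    ``proportion_explained`` is relative to the positive eigenvalue total.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centres ``-0.5 * d^2``, eigendecomposes, and returns coordinates
    ``u_k * sqrt(lambda_k)`` on the positive-eigenvalue axes.  Axis signs are
    fixed deterministically by making the largest-magnitude coordinate of
    each axis positive.
    """
    if d.n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    D2 = d.squared()
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-10, 1e-10 * abs(eigval[0]) if eigval.size else 0.0)
    positive = eigval > tol
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, int(n_axes))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for j in range(k):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    pos_total = eigval[positive].sum()
    prop = np.where(positive, eigval / pos_total, 0.0) if pos_total > 0 else (
        np.zeros_like(eigval)
    )
    coordinates = pd.DataFrame(
        coords, index=d.ids, columns=[f"Axis{j + 1}" for j in range(k)]
    )
    return PcoaResult(
        coordinates=coordinates,
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def group_centroids(result: PcoaResult, grouping) -> pd.DataFrame:
    """Arithmetic mean coordinates per group (Fig-4-style group centroids).

    ``grouping`` maps each sample id to a group label (mapping or Series
    covering every sample).  Empty/unassigned samples are an error.
    """
    grouping = pd.Series(grouping)
    missing = [s for s in result.coordinates.index if s not in grouping.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing[:5]}")
    labels = grouping.loc[result.coordinates.index]
    if labels.isna().any():
        raise ValueError("every sample must be assigned a non-null group")
    return result.coordinates.groupby(labels.to_numpy()).mean()
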