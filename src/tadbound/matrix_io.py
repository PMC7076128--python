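"""Input/output for chromosome-specific Hi-C contact matrices and BED tables.

Three plain-text matrix dialects are supported:

* **dense** — an ``n x n`` whitespace-delimited numeric table;
* **triplet** — three columns ``i j count`` where ``i``/``j`` are either
  0-based bin indices or bin start coordinates in bp (never a mixture);
* **coordinate** — an ``n x (n+3)`` table whose first three columns are
  ``chrom start end`` annotations followed by the ``n x n`` numeric block.

All genomic coordinates in outputs are 0-based, half-open (BED standard).
Counts may be non-integer: normalized matrices are accepted, since nothing
downstream assumes integrality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "read_dense",
    "read_triplet",
    "read_coordinate_matrix",
    "read_bed",
    "write_dense",
    "write_results",
    "read_results",
]

#: Relative tolerance below which an almost-symmetric matrix is repaired
#: by averaging with its transpose rather than rejected.
_SYM_RTOL = 1e-6


@dataclass
class ContactMatrix:
    """A chromosome's symmetric binned Hi-C contact matrix.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin size in bp.
    starts : numpy.ndarray
        Ordered bin start coordinates in bp; strictly increasing with a
        constant step equal to ``resolution``.
    counts : numpy.ndarray
        Square symmetric matrix of non-negative, finite interaction
        counts, one row/column per bin.
    """

    chrom: str
    resolution: int
    starts: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        n = self.counts.shape[0]
        if self.starts.shape != (n,):
            raise ValueError("number of bins must equal number of matrix rows")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contains NaN or infinite entries")
        if np.any(self.counts < 0):
            raise ValueError("negative count")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be exactly symmetric")
        if n > 1:
            steps = np.diff(self.starts)
            if np.any(steps <= 0):
                raise ValueError("bin starts must be strictly increasing")
            if np.any(steps != self.resolution):
                raise ValueError("bin starts must step by the resolution")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def ends(self) -> np.ndarray:
        """Bin end coordinates (half-open) in bp."""
        return self.starts + self.resolution


def _symmetrize(counts: np.ndarray, what: str) -> np.ndarray:
    """Average a near-symmetric matrix with its transpose, or raise."""
    scale = max(np.abs(counts).max(), 1.0)
    asym = np.abs(counts - counts.T).max()
    if asym > _SYM_RTOL * scale:
        raise ValueError(
            f"asymmetric {what}: max |C - C^T| = {asym:g} exceeds "
            f"relative tolerance {_SYM_RTOL:g}"
        )
    return (counts + counts.T) / 2.0


def _check_numeric_block(counts: np.ndarray, source: str) -> None:
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"{source}: table is not square "
                         f"(shape {counts.shape})")
    if np.isnan(counts).any():
        raise ValueError(f"{source}: NaN entries present")
    if (counts < 0).any():
        raise ValueError(f"{source}: negative count")


def read_dense(path, chrom: str, resolution: int) -> ContactMatrix:
    """Read an ``n x n`` whitespace-delimited contact matrix.

    Bin starts are laid out as ``0, resolution, 2*resolution, ...``.
    Near-symmetric matrices (relative asymmetry <= 1e-6) are symmetrized
    by averaging; larger asymmetry is an error.
    """
    counts = np.loadtxt(path, ndmin=2, dtype=float)
    _check_numeric_block(counts, str(path))
    counts = _symmetrize(counts, "matrix")
    n = counts.shape[0]
    starts = np.arange(n, dtype=np.int64) * resolution
    return ContactMatrix(chrom, resolution, starts, counts)


def read_triplet(path, chrom: str, resolution: int) -> ContactMatrix:
    """Read a sparse 3-column ``i j count`` contact matrix and densify it.

    The first two columns are either 0-based bin indices or bin start
    coordinates in bp; values >= ``resolution`` switch on the coordinate
    interpretation, in which case every value must be a multiple of the
    resolution.  Absent pairs are zero.  An exact duplicate ``(i, j)``
    record, or a stored mirror ``(j, i)`` conflicting with the upper
    triangle, is an error.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # empty-input notice
        raw = np.loadtxt(path, ndmin=2, dtype=float)
    if raw.size == 0:
        raise ValueError(f"{path}: no records")
    if raw.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, found {raw.shape[1]}")
    ij = raw[:, :2]
    vals = raw[:, 2]
    if np.isnan(raw).any():
        raise ValueError(f"{path}: NaN entries present")
    if (vals < 0).any():
        raise ValueError(f"{path}: negative count")
    if (ij >= resolution).any():
        # coordinate convention: starts in bp
        if np.any(np.mod(ij, resolution) != 0):
            raise ValueError(
                f"{path}: mixed index/coordinate convention — values >= "
                "resolution present but not all multiples of the resolution"
            )
        idx = (ij / resolution).astype(np.int64)
    else:
        if np.any(np.mod(ij, 1) != 0):
            raise ValueError(f"{path}: non-integer bin indices")
        idx = ij.astype(np.int64)
    if (idx < 0).any():
        raise ValueError(f"{path}: negative bin index")
    n = int(idx.max()) + 1
    counts = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for (i, j), v in zip(idx, vals):
        key = (int(i), int(j))
        if key in seen:
            raise ValueError(f"{path}: duplicate pair {key}")
        seen[key] = v
        mirror = (key[1], key[0])
        if mirror != key and mirror in seen and seen[mirror] != v:
            raise ValueError(
                f"{path}: conflicting values for pair {mirror} and its mirror"
            )
        counts[key] = v
        counts[mirror] = v
    starts = np.arange(n, dtype=np.int64) * resolution
    return ContactMatrix(chrom, resolution, starts, counts)


def read_coordinate_matrix(path) -> ContactMatrix:
    """Read the annotated ``n x (n+3)`` dialect (chrom/start/end + block).

    The resolution is inferred as ``end - start`` of the first row; all
    rows must share one chromosome and one bin width.
    """
    table = pd.read_csv(path, sep=r"\s+", header=None)
    if table.shape[1] < 4:
        raise ValueError(f"{path}: expected chrom/start/end plus matrix block")
    chroms = table.iloc[:, 0].astype(str)
    if chroms.nunique() != 1:
        raise ValueError(f"{path}: mixed chromosomes "
                         f"({sorted(chroms.unique())})")
    starts = table.iloc[:, 1].to_numpy(dtype=np.int64)
    ends = table.iloc[:, 2].to_numpy(dtype=np.int64)
    widths = ends - starts
    if len(set(widths.tolist())) != 1:
        raise ValueError(f"{path}: non-constant bin width")
    resolution = int(widths[0])
    counts = table.iloc[:, 3:].to_numpy(dtype=float)
    _check_numeric_block(counts, str(path))
    counts = _symmetrize(counts, "matrix")
    cm = ContactMatrix(str(chroms.iloc[0]), resolution, starts, counts)
    return cm


def read_bed(path) -> pd.DataFrame:
    """Read a BED interval track into a (chrom, start, end) frame.

    Extra columns are ignored; ``#``-comment, ``track`` and ``browser``
    lines are skipped.  Intervals are validated (start < end) and sorted
    within chromosome.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if (not line or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    if not rows:
        raise ValueError(f"{path}: no records")
    track = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if (track["start"] >= track["end"]).any():
        raise ValueError(f"{path}: interval with start >= end")
    return track.sort_values(["chrom", "start"], kind="stable",
                             ignore_index=True)


def write_dense(matrix: ContactMatrix, path) -> None:
    """Write the counts of a :class:`ContactMatrix` in the dense dialect."""
    np.savetxt(path, matrix.counts, fmt="%.10g", delimiter="\t")


def _format_cell(value) -> str:
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as a BED-style TSV with a ``#`` header line.

    Numeric scores are printed with 6 significant digits; missing values
    (placeholder bins) are printed as ``NA``.
    """
    buf = io.StringIO()
    buf.write("#" + "\t".join(map(str, table.columns)) + "\n")
    for row in table.itertuples(index=False):
        buf.write("\t".join(_format_cell(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#' header line")
        columns = header[1:].rstrip("\n").split("\t")
        table = pd.read_csv(fh, sep="\t", names=columns, na_values=["NA"])
    return table
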