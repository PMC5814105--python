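"""Intra-chromosomal Hi-C contact maps: I/O, ICE balancing, distance profiles.

A contact map holds the symmetric counts ``n_ij`` between pairs of fixed-size
genomic bins on one chromosome.  Only intra-chromosomal pairs are modelled;
the genomic distance ``d = j - i`` (in bins) is the central stratification
variable everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class ContactMap:
    """Symmetric sparse contact counts for one chromosome.

    Entries are stored upper-triangular (``i <= j``); queries are symmetric.
    Counts may be real-valued (e.g. after ICE balancing).
    """

    name: str
    bin_size: int
    n_bins: int
    row: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    col: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    val: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=float))

    def __post_init__(self) -> None:
        i = np.asarray(self.row, dtype=np.int64)
        j = np.asarray(self.col, dtype=np.int64)
        v = np.asarray(self.val, dtype=float)
        if not (i.shape == j.shape == v.shape):
            raise ValueError("row, col, val must have equal length")
        if v.size and v.min() < 0:
            raise ValueError("negative contact count")
        if i.size and max(i.max(), j.max()) >= self.n_bins:
            raise ValueError("bin index out of range (>= n_bins)")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        # sum duplicates, including mirrored (i,j)/(j,i) rows
        key = lo * self.n_bins + hi
        uniq, inv = np.unique(key, return_inverse=True)
        merged = np.zeros(uniq.size)
        np.add.at(merged, inv, v)
        self.row = (uniq // self.n_bins).astype(np.int64)
        self.col = (uniq % self.n_bins).astype(np.int64)
        self.val = merged

    def get(self, i: int, j: int) -> float:
        lo, hi = (i, j) if i <= j else (j, i)
        idx = np.searchsorted(self.row * self.n_bins + self.col, lo * self.n_bins + hi)
        key = self.row * self.n_bins + self.col
        if idx < key.size and key[idx] == lo * self.n_bins + hi:
            return float(self.val[idx])
        return 0.0

    def to_csr(self) -> sparse.csr_matrix:
        """Full symmetric CSR matrix (diagonal counted once)."""
        m = sparse.coo_matrix(
            (self.val, (self.row, self.col)), shape=(self.n_bins, self.n_bins)
        )
        off = self.row != self.col
        mt = sparse.coo_matrix(
            (self.val[off], (self.col[off], self.row[off])),
            shape=(self.n_bins, self.n_bins),
        )
        return (m + mt).tocsr()

    def pairs_at_distance(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """(i, count) arrays for the stored entries with ``j - i == d``."""
        mask = (self.col - self.row) == d
        return self.row[mask], self.val[mask]


@dataclass
class DistanceProfile:
    """Per-distance mean and variance of contact counts.

    ``mean_counts[d-1]`` is the average count over *all* eligible pairs at
    separation ``d`` (zeros included), ``var_counts`` the population variance,
    ``pair_counts`` the number of eligible pairs.
    """

    d_max: int
    mean_counts: np.ndarray
    var_counts: np.ndarray
    pair_counts: np.ndarray

    def mean(self, d: int) -> float:
        if not 1 <= d <= self.d_max:
            raise KeyError(f"distance {d} outside profile range 1..{self.d_max}")
        return float(self.mean_counts[d - 1])

    def var(self, d: int) -> float:
        if not 1 <= d <= self.d_max:
            raise KeyError(f"distance {d} outside profile range 1..{self.d_max}")
        return float(self.var_counts[d - 1])


def read_contact_map(path, bin_size: int, n_bins: int, name: str = "chr") -> ContactMap:
    """Read a COO TSV contact map: ``[chrom] bin_i bin_j count`` per row.

    Mirrored and duplicate rows are summed into the upper triangle.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except pd.errors.EmptyDataError:
        return ContactMap(name, bin_size, n_bins)
    if df.shape[1] == 0 or len(df) == 0:
        return ContactMap(name, bin_size, n_bins)
    if df.shape[1] == 4:
        df = df.iloc[:, 1:]
    if df.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    i = df.iloc[:, 0].to_numpy(dtype=np.int64)
    j = df.iloc[:, 1].to_numpy(dtype=np.int64)
    v = df.iloc[:, 2].to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError(f"{path}: negative contact count")
    if i.size and max(i.max(), j.max()) >= n_bins:
        raise ValueError(f"{path}: bin index exceeds n_bins={n_bins}")
    return ContactMap(name, bin_size, n_bins, i, j, v)


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chrom\tbin_i\tbin_j\tcount\n")
        for i, j, v in zip(cmap.row, cmap.col, cmap.val):
            fh.write(f"{cmap.name}\t{i}\t{j}\t{v:g}\n")


def ice_normalize(cmap: ContactMap, tol: float = 1e-5, max_iter: int = 200) -> ContactMap:
    """Balance a contact map so every non-empty row has the same total.

    Sequential iterative correction: each round divides ``n_ij`` by
    ``b_i * b_j`` with ``b_i = rowsum_i / mean(rowsum over non-empty rows)``,
    until the largest relative deviation of a non-empty row sum from the mean
    drops below ``tol``.  Empty rows are left zero.  The mean non-empty row
    sum is restored at the end, so the overall scale is preserved.
    """
    if cmap.val.size == 0 or cmap.val.sum() == 0:
        raise ValueError("all-zero contact map cannot be balanced")
    m = cmap.to_csr().astype(float)
    nonempty = np.asarray(m.sum(axis=1)).ravel() > 0
    target = np.asarray(m.sum(axis=1)).ravel()[nonempty].mean()
    for _ in range(max_iter):
        rowsum = np.asarray(m.sum(axis=1)).ravel()
        mean_sum = rowsum[nonempty].mean()
        dev = np.abs(rowsum[nonempty] / mean_sum - 1.0).max()
        if dev < tol:
            break
        b = np.ones(cmap.n_bins)
        b[nonempty] = rowsum[nonempty] / mean_sum
        inv = sparse.diags(1.0 / b)
        m = inv @ m @ inv
    rowsum = np.asarray(m.sum(axis=1)).ravel()
    m *= target / rowsum[nonempty].mean()
    coo = sparse.triu(m).tocoo()
    return ContactMap(cmap.name, cmap.bin_size, cmap.n_bins, coo.row, coo.col, coo.data)


def distance_profile(
    cmap: ContactMap, d_max: int, valid_bins: np.ndarray | None = None
) -> DistanceProfile:
    """Mean/variance of counts per genomic distance ``d = 1..d_max``.

    All pairs with both bins valid contribute; pairs absent from the sparse
    map count as zero observations.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if d_max >= cmap.n_bins:
        raise ValueError(f"d_max={d_max} must be < n_bins={cmap.n_bins}")
    if valid_bins is None:
        valid = np.ones(cmap.n_bins, dtype=bool)
    else:
        valid = np.zeros(cmap.n_bins, dtype=bool)
        valid[np.asarray(list(valid_bins), dtype=np.int64)] = True
    mean = np.zeros(d_max)
    var = np.zeros(d_max)
    npairs = np.zeros(d_max, dtype=np.int64)
    for d in range(1, d_max + 1):
        i_all = np.arange(cmap.n_bins - d)
        ok = valid[i_all] & valid[i_all + d]
        n = int(ok.sum())
        npairs[d - 1] = n
        if n == 0:
            continue
        i_ent, v_ent = cmap.pairs_at_distance(d)
        keep = valid[i_ent] & valid[i_ent + d]
        v = v_ent[keep]
        s, s2 = v.sum(), (v**2).sum()
        mean[d - 1] = s / n
        var[d - 1] = max(s2 / n - (s / n) ** 2, 0.0)
    return DistanceProfile(d_max, mean, var, npairs)


def distance_normalize(
    cmap: ContactMap,
    profile: DistanceProfile,
    valid_bins: np.ndarray | None = None,
) -> dict[tuple[int, int], float]:
    """Observed-over-expected map ``n_ij / <n(d)>`` for all eligible pairs.

    Pairs absent from the sparse map appear with value 0; distances whose
    profile mean is zero are omitted (the ratio is undefined there).
    """
    if valid_bins is None:
        valid = np.ones(cmap.n_bins, dtype=bool)
    else:
        valid = np.zeros(cmap.n_bins, dtype=bool)
        valid[np.asarray(list(valid_bins), dtype=np.int64)] = True
    out: dict[tuple[int, int], float] = {}
    for d in range(1, profile.d_max + 1):
        mu = profile.mean_counts[d - 1]
        if mu == 0:
            continue
        i_all = np.arange(cmap.n_bins - d)
        ok = valid[i_all] & valid[i_all + d]
        for i in i_all[ok]:
            out[(int(i), int(i + d))] = 0.0
        i_ent, v_ent = cmap.pairs_at_distance(d)
        keep = valid[i_ent] & valid[i_ent + d]
        for i, v in zip(i_ent[keep], v_ent[keep]):
            out[(int(i), int(i + d))] = float(v / mu)
    return out
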