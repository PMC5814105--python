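"""Sequence neighborhoods around contacting bin pairs.

For a pair of bins ``(i, j)`` at separation ``d = j - i``, the neighborhood
is the ordered spin vector of the ``W`` bins windowed around each site: for
``d > W`` the two windows are disjoint and the vector has ``N = 2W`` spins;
for ``d <= W`` the windows merge into one contiguous stretch of
``N = d + W - 1`` spins.  With the default ``W = 10`` this reproduces the
published construction (N = 20, or N = d + 9 at short range).

Ensembles of neighborhoods at one distance are weighted either by the Hi-C
contact count of their pair (CONTACT condition) or by unit occurrence
(BACKGROUND condition), and are closed under left-right reversal — the
orientation of the genome cannot matter for contact formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np

from .contacts import ContactMap
from .genome import MISSING, BinnedChromosome


class Condition(str, Enum):
    CONTACT = "contact"
    BACKGROUND = "background"


@dataclass(frozen=True)
class NeighborhoodScheme:
    """Window geometry: ``window_size`` (W) bins per contacting site.

    W must be even and >= 2.  The window around site ``i`` spans
    ``i - (W/2 - 1) .. i + W/2``; around ``j`` it spans the mirror
    ``j - W/2 .. j + (W/2 - 1)``.
    """

    window_size: int = 10

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.window_size % 2:
            raise ValueError("window_size must be even and >= 2")

    @property
    def left(self) -> int:
        return self.window_size // 2 - 1

    @property
    def right(self) -> int:
        return self.window_size // 2

    def size(self, d: int) -> int:
        """Neighborhood size N at separation d."""
        w = self.window_size
        return d + w - 1 if d <= w else 2 * w

    def position_of_i(self, d: int) -> int:
        return self.left

    def position_of_j(self, d: int) -> int:
        w = self.window_size
        return self.left + d if d <= w else w + w // 2


def neighborhood_indices(i: int, j: int, scheme: NeighborhoodScheme) -> np.ndarray:
    """Ordered genomic bin indices making up the neighborhood of pair (i, j).

    May include negative or out-of-range indices; callers decide whether to
    skip such pairs.
    """
    if j <= i:
        raise ValueError(f"need j > i, got i={i}, j={j}")
    d = j - i
    w = scheme.window_size
    if d <= w:
        return np.arange(i - scheme.left, j + scheme.left + 1)
    return np.concatenate(
        [np.arange(i - scheme.left, i + scheme.right + 1),
         np.arange(j - scheme.right, j + scheme.left + 1)]
    )


@dataclass
class NeighborhoodEnsemble:
    """Weighted spin vectors at one distance under one condition.

    ``spins`` is (n_members, N) with values ±1; closed under reversal (every
    member's mirror image is present with the same weight).
    """

    d: int
    condition: Condition
    spins: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.spins.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class MomentSet:
    """Weighted spin statistics of an ensemble (or exact model expectations).

    ``m[k] = <σ_k>``; ``c[(k, l)] = <σ_k σ_l>`` for k < l; optionally
    ``t[(k, l, m)] = <σ_k σ_l σ_m>``.
    """

    n: int
    m: np.ndarray
    c: dict[tuple[int, int], float]
    t: dict[tuple[int, int, int], float] | None = None

    def c_matrix(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for (k, l), v in self.c.items():
            out[k, l] = out[l, k] = v
        np.fill_diagonal(out, 1.0)
        return out


def extract_ensemble(
    states: BinnedChromosome,
    cmap: ContactMap | None,
    d: int,
    condition: Condition,
    regions: Sequence[tuple[int, int]] | None = None,
    scheme: NeighborhoodScheme = NeighborhoodScheme(),
) -> NeighborhoodEnsemble:
    """Scroll all pairs ``(i, i+d)`` with ``i`` in the given bin regions.

    Pairs whose neighborhood leaves the chromosome or touches a MISSING bin
    are skipped entirely.  CONTACT weights are the pair's count (zero-count
    pairs are omitted); BACKGROUND weights are 1.  Every accepted vector is
    also added reversed with the same weight.
    """
    condition = Condition(condition)
    if condition is Condition.CONTACT and cmap is None:
        raise ValueError("CONTACT condition requires a contact map")
    n_bins = states.n_bins
    if regions is None:
        regions = [(0, n_bins)]
    i_cand = np.concatenate(
        [np.arange(max(a, 0), min(b, n_bins - d)) for a, b in regions]
    ) if regions else np.zeros(0, dtype=int)
    i_cand = np.unique(i_cand)

    # neighborhood index offsets relative to i are the same for all pairs at d
    offsets = neighborhood_indices(0, d, scheme)
    lo, hi = offsets[0], offsets[-1]
    in_range = (i_cand + lo >= 0) & (i_cand + hi < n_bins)
    i_cand = i_cand[in_range]
    if i_cand.size:
        idx = i_cand[:, None] + offsets[None, :]
        spin_block = states.states[idx]
        complete = (spin_block != MISSING).all(axis=1)
        i_cand = i_cand[complete]
        spin_block = spin_block[complete]
    else:
        spin_block = np.zeros((0, offsets.size), dtype=np.int8)

    if condition is Condition.CONTACT:
        counts = np.zeros(n_bins)
        i_ent, v_ent = cmap.pairs_at_distance(d)
        counts[i_ent] = v_ent
        w = counts[i_cand]
        keep = w > 0
        spin_block, w = spin_block[keep], w[keep]
    else:
        w = np.ones(i_cand.size)

    if w.size == 0 or w.sum() == 0:
        raise ValueError(f"empty ensemble at d={d} ({condition.value})")

    spins = np.concatenate([spin_block, spin_block[:, ::-1]])
    weights = np.concatenate([w, w])
    return NeighborhoodEnsemble(d, condition, spins.astype(np.int8), weights)


def ensemble_moments(ens: NeighborhoodEnsemble, order: int = 2) -> MomentSet:
    """Weighted first, second and optionally third spin moments."""
    if ens.total_weight <= 0:
        raise ValueError("ensemble has zero total weight")
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    w = ens.weights / ens.weights.sum()
    s = ens.spins.astype(float)
    n = ens.n
    m = w @ s
    c: dict[tuple[int, int], float] = {}
    t: dict[tuple[int, int, int], float] | None = None
    if order >= 2:
        cw = (s * w[:, None]).T @ s
        for k, l in combinations(range(n), 2):
            c[(k, l)] = float(cw[k, l])
    if order >= 3:
        t = {}
        for k, l, mm in combinations(range(n), 3):
            t[(k, l, mm)] = float(np.sum(w * s[:, k] * s[:, l] * s[:, mm]))
    return MomentSet(n, m, c, t)
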