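"""Binned binary chromatin-state tracks.

A genome is discretized into fixed-size bins (10 kbp by default) and each bin
carries a spin: +1 for the active/euchromatic state, -1 for the
inactive/heterochromatic state, or MISSING (0) where no annotation covers the
bin.  Tracks are built from BED-like interval annotations — e.g. a five-state
"chromatin colors" classification — by collapsing the labels of the intervals
overlapping each bin to the dominant binary group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Spin value marking a bin with no annotation coverage.
MISSING: int = 0

#: Grouping of the five Drosophila chromatin colors into binary states:
#: black/blue heterochromatin (spin down), yellow/green/red euchromatin (spin up).
COLOR_GROUPING: dict[str, int] = {
    "BLACK": -1,
    "BLUE": -1,
    "YELLOW": +1,
    "GREEN": +1,
    "RED": +1,
}

#: Identity grouping for tracks written by :func:`write_state_track`.
#: "MISSING" maps to 0 so explicitly-annotated gaps round-trip.
BINARY_GROUPING: dict[str, int] = {"UP": +1, "DOWN": -1, "MISSING": MISSING}


@dataclass
class BinnedChromosome:
    """Per-chromosome vector of binary chromatin states at a fixed bin size.

    Bin ``k`` covers the 0-based half-open basepair interval
    ``[k*bin_size, (k+1)*bin_size)``.  ``states[k]`` is +1, -1 or MISSING (0).
    """

    name: str
    bin_size: int = 10_000
    states: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        bad = ~np.isin(self.states, (-1, MISSING, 1))
        if bad.any():
            raise ValueError(
                f"states must be -1, +1 or {MISSING} (missing); "
                f"found {np.unique(self.states[bad])}"
            )

    @property
    def n_bins(self) -> int:
        return self.states.size

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of bins with a non-missing state."""
        return self.states != MISSING


def _validate_grouping(grouping: Mapping[str, int]) -> dict[str, int]:
    out = {}
    for label, spin in grouping.items():
        if spin not in (-1, +1, MISSING):
            raise ValueError(f"grouping maps {label!r} to {spin}; must be -1, +1 or 0")
        out[str(label).upper()] = int(spin)
    return out


def binarize_labels(
    intervals_in_bin: Sequence[tuple[float, str]],
    grouping: Mapping[str, int],
) -> int:
    """Collapse the labelled coverage of one bin to a single spin.

    ``intervals_in_bin`` lists ``(overlap_length_bp, label)`` pairs.  The spin
    whose summed coverage is strictly greater wins; ties (and empty input) go
    to -1 and MISSING respectively.  The tie rule reflects heterochromatin
    being the genomic background state.
    """
    grouping = _validate_grouping(grouping)
    up = down = 0.0
    for length, label in intervals_in_bin:
        key = str(label).upper()
        if key not in grouping:
            raise KeyError(f"unknown label {label!r}: not in state grouping")
        spin = grouping[key]
        if spin == +1:
            up += length
        elif spin == -1:
            down += length
        # spin == MISSING: annotated as missing, contributes no coverage
    if up == 0.0 and down == 0.0:
        return MISSING
    return +1 if up > down else -1


def _read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "label"],
            dtype={"chrom": str, "label": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed BED file {path}: {exc}") from exc
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise ValueError(f"malformed line {line} in {path}: non-numeric {col}")
        df[col] = vals.astype(np.int64)
    return df


def read_state_track(
    path,
    bin_size: int = 10_000,
    grouping: Mapping[str, int] = COLOR_GROUPING,
) -> dict[str, BinnedChromosome]:
    """Read a BED-like chromatin-state annotation into binned spin tracks.

    Columns: chrom, start, end, label (tab-separated, ``#`` comments allowed,
    0-based half-open coordinates).  Each bin takes the spin of its dominant
    label group (:func:`binarize_labels`); uncovered bins are MISSING.
    """
    grouping = _validate_grouping(grouping)
    df = _read_bed(path)
    unknown = set(df["label"].str.upper()) - set(grouping)
    if unknown:
        raise KeyError(f"unknown label {sorted(unknown)[0]!r}: not in state grouping")

    chroms: dict[str, BinnedChromosome] = {}
    for name, sub in df.groupby("chrom", sort=True):
        n_bins = int(np.ceil(sub["end"].max() / bin_size))
        up = np.zeros(n_bins)
        down = np.zeros(n_bins)
        for start, end, label in zip(sub["start"], sub["end"], sub["label"]):
            if end <= start:
                continue
            spin = grouping[label.upper()]
            if spin == MISSING:
                continue
            cov = up if spin == +1 else down
            k0, k1 = start // bin_size, (end - 1) // bin_size
            for k in range(k0, k1 + 1):
                lo = max(start, k * bin_size)
                hi = min(end, (k + 1) * bin_size)
                cov[k] += hi - lo
        # tie (up == down > 0) falls into the down branch: heterochromatin wins
        states = np.where(up > down, 1, np.where(down > 0, -1, MISSING))
        chroms[name] = BinnedChromosome(name, bin_size, states.astype(np.int8))
    return chroms


def read_state_tsv(path, name: str = "chr", bin_size: int = 10_000) -> BinnedChromosome:
    """Read the two-column alternate format: ``bin_index<TAB>spin`` per line."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["bin", "spin"])
    n_bins = int(df["bin"].max()) + 1 if len(df) else 0
    states = np.zeros(n_bins, dtype=np.int8)
    states[df["bin"].to_numpy(dtype=np.int64)] = df["spin"].to_numpy(dtype=np.int8)
    return BinnedChromosome(name, bin_size, states)


def write_state_track(chroms: Iterable[BinnedChromosome] | Mapping[str, BinnedChromosome], path) -> None:
    """Write spin tracks as BED intervals labelled UP/DOWN/MISSING.

    Runs of equal state are merged into single intervals.  Round-trips through
    :func:`read_state_track` with :data:`BINARY_GROUPING`.
    """
    if isinstance(chroms, Mapping):
        chroms = chroms.values()
    label_of = {1: "UP", -1: "DOWN", MISSING: "MISSING"}
    with open(path, "w") as fh:
        fh.write("# chromaxent binary chromatin-state track\n")
        for chrom in chroms:
            s = chrom.states
            if s.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [s.size]))
            for a, b in zip(starts, ends):
                fh.write(
                    f"{chrom.name}\t{a * chrom.bin_size}\t{b * chrom.bin_size}"
                    f"\t{label_of[int(s[a])]}\n"
                )
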