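"""Forward prediction: contact maps from chromatin sequence via Bayes' rule.

With a fitted model pair at each distance the distance-normalized contact
probability of a pair (i, j) follows from Bayes' rule:

    P(c|σ, d) / P(c|d) = P(σ|c, d) / P(σ|d),

i.e. the ratio of the CONTACT to the BACKGROUND Ising probability of the
pair's sequence neighborhood σ.  Predicted maps are scored by Pearson
correlation against distance-normalized experimental counts, and a
single-site mutation scan measures how much flipping one bin's chromatin
state degrades the locally predicted structure (Δc = c' − c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import MISSING, BinnedChromosome
from .maxent import IsingModel, ModelBank, pair_index
from .neighborhoods import NeighborhoodScheme, neighborhood_indices


@dataclass
class PredictedMap:
    """Distance-normalized predicted contacts r_ij = P(c|σ,d)/P(c|d).

    Pairs skipped by the boundary/MISSING rules are simply absent.
    """

    ratios: dict[tuple[int, int], float]
    scheme: NeighborhoodScheme
    region: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass
class MutationResult:
    site: int
    original_spin: int
    c: float
    c_prime: float
    delta_c: float
    category: str = "unclassified"


def _log_ratio_tables(bank: ModelBank, d: int) -> tuple[IsingModel, IsingModel, float]:
    mc, mb = bank.models_at(d)
    # log Z difference is cached on the models themselves
    return mc, mb, mb.log_z() - mc.log_z()


def contact_ratio(bank: ModelBank, sigma: np.ndarray, d: int) -> float:
    """P(σ|c,d)/P(σ|d), evaluated in the log domain.

    Equals the distance-normalized contact probability P(c|σ,d)/P(c|d); the
    sequence-independent P(c|d) cancels.
    """
    mc, mb, dlz = _log_ratio_tables(bank, d)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.size != mc.n:
        raise ValueError(f"sigma has {sigma.size} spins, models at d={d} expect {mc.n}")
    dh = mc.h - mb.h
    dj = mc.j - mb.j
    de = float(sigma @ dh)
    if dj.any():
        pk = np.array([k for k, _ in pair_index(mc.n)])
        pl = np.array([l for _, l in pair_index(mc.n)])
        de += float(dj @ (sigma[pk] * sigma[pl]))
    return float(np.exp(de + dlz))


def predict_map(
    states: BinnedChromosome,
    bank: ModelBank,
    region: tuple[int, int] | None = None,
    scheme: NeighborhoodScheme | None = None,
) -> PredictedMap:
    """Predict r_ij for every pair (i, i+d), d in the bank, with i in region.

    Pairs whose neighborhood leaves the chromosome or touches a MISSING bin
    are skipped, mirroring ensemble extraction.
    """
    scheme = scheme or bank.scheme
    n_bins = states.n_bins
    a, b = region if region is not None else (0, n_bins)
    ratios: dict[tuple[int, int], float] = {}
    spins = states.states
    for d in bank.distances:
        mc, mb, dlz = _log_ratio_tables(bank, d)
        offsets = neighborhood_indices(0, d, scheme)
        lo, hi = offsets[0], offsets[-1]
        i_cand = np.arange(max(a, -lo), min(b, n_bins - d, n_bins - hi))
        if i_cand.size == 0:
            continue
        block = spins[i_cand[:, None] + offsets[None, :]]
        ok = (block != MISSING).all(axis=1)
        i_cand, block = i_cand[ok], block[ok].astype(float)
        if i_cand.size == 0:
            continue
        dh = mc.h - mb.h
        dj = mc.j - mb.j
        de = block @ dh
        if dj.any():
            pk = [k for k, _ in pair_index(mc.n)]
            pl = [l for _, l in pair_index(mc.n)]
            de += (block[:, pk] * block[:, pl]) @ dj
        r = np.exp(de + dlz)
        for i, v in zip(i_cand, r):
            ratios[(int(i), int(i + d))] = float(v)
    if not ratios:
        raise ValueError("no valid pairs in region")
    return PredictedMap(ratios, scheme, region)


def map_correlation(
    pred: PredictedMap | Mapping[tuple[int, int], float],
    exp_normalized: Mapping[tuple[int, int], float],
) -> float:
    """Pearson correlation over the common pair set, pooled across distances."""
    p = pred.ratios if isinstance(pred, PredictedMap) else pred
    common = sorted(set(p) & set(exp_normalized))
    if len(common) < 2:
        raise ValueError("need at least 2 common pairs for a correlation")
    x = np.array([p[k] for k in common])
    y = np.array([exp_normalized[k] for k in common])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def per_distance_correlation(
    pred: PredictedMap | Mapping[tuple[int, int], float],
    exp_normalized: Mapping[tuple[int, int], float],
) -> dict[int, float]:
    """Pearson correlation computed separately at each distance."""
    p = pred.ratios if isinstance(pred, PredictedMap) else pred
    by_d: dict[int, list[tuple[int, int]]] = {}
    for (i, j) in set(p) & set(exp_normalized):
        by_d.setdefault(j - i, []).append((i, j))
    out = {}
    for d, keys in sorted(by_d.items()):
        x = np.array([p[k] for k in keys])
        y = np.array([exp_normalized[k] for k in keys])
        if len(keys) >= 2 and x.std() > 0 and y.std() > 0:
            out[d] = float(stats.pearsonr(x, y).statistic)
    return out


def pairs_containing(
    k: int, pred: PredictedMap, scheme: NeighborhoodScheme
) -> list[tuple[int, int]]:
    """Predicted pairs whose neighborhood includes genomic bin k."""
    out = []
    w = scheme.window_size
    for (i, j) in pred.ratios:
        d = j - i
        if d <= w:
            inside = i - scheme.left <= k <= j + scheme.left
        else:
            inside = (i - scheme.left <= k <= i + scheme.right) or (
                j - scheme.right <= k <= j + scheme.left
            )
        if inside:
            out.append((i, j))
    return out


def local_correlation(
    k: int,
    pred: PredictedMap,
    exp_normalized: Mapping[tuple[int, int], float],
    scheme: NeighborhoodScheme | None = None,
) -> float:
    """Correlation c restricted to the local contact map of site k — the
    pairs whose predicted probability the state of k influences."""
    scheme = scheme or pred.scheme
    keys = [p for p in pairs_containing(k, pred, scheme) if p in exp_normalized]
    if len(keys) < 2:
        raise ValueError(f"site {k} participates in fewer than 2 scored pairs")
    x = np.array([pred.ratios[p] for p in keys])
    y = np.array([exp_normalized[p] for p in keys])
    if x.std() == 0 or y.std() == 0:
        raise ValueError(f"zero variance in local map of site {k}")
    return float(stats.pearsonr(x, y).statistic)


def mutation_scan(
    states: BinnedChromosome,
    bank: ModelBank,
    exp_normalized: Mapping[tuple[int, int], float],
    c_threshold: float = 0.6,
    scheme: NeighborhoodScheme | None = None,
    region: tuple[int, int] | None = None,
    pred: PredictedMap | None = None,
) -> list[MutationResult]:
    """Flip each well-predicted site's chromatin state and measure Δc = c' − c.

    Sites whose local correlation c exceeds ``c_threshold`` are flipped one
    at a time; only the pairs containing the site are re-predicted, and c' is
    computed on the same pair set.  The caller's state vector is untouched.
    """
    scheme = scheme or bank.scheme
    if pred is None:
        pred = predict_map(states, bank, region, scheme)
    a, b = region if region is not None else (0, states.n_bins)

    # index pairs by the sites they contain, one pass
    site_pairs: dict[int, list[tuple[int, int]]] = {}
    w = scheme.window_size
    for (i, j) in pred.ratios:
        d = j - i
        if d <= w:
            members = range(i - scheme.left, j + scheme.left + 1)
        else:
            members = list(range(i - scheme.left, i + scheme.right + 1)) + list(
                range(j - scheme.right, j + scheme.left + 1)
            )
        for k in members:
            site_pairs.setdefault(k, []).append((i, j))

    results: list[MutationResult] = []
    work = states.states.copy()
    mutated = BinnedChromosome(states.name, states.bin_size, work)
    for k in range(a, b):
        if states.states[k] == MISSING:
            continue
        keys = [p for p in site_pairs.get(k, []) if p in exp_normalized]
        if len(keys) < 2:
            continue
        x = np.array([pred.ratios[p] for p in keys])
        y = np.array([exp_normalized[p] for p in keys])
        if x.std() == 0 or y.std() == 0:
            continue
        c = float(stats.pearsonr(x, y).statistic)
        if c <= c_threshold:
            continue
        work[k] = -work[k]
        x_prime = np.array(
            [contact_ratio(bank, work[np.asarray(neighborhood_indices(i, j, scheme))], j - i)
             for i, j in keys]
        )
        work[k] = -work[k]
        if x_prime.std() == 0:
            continue
        c_prime = float(stats.pearsonr(x_prime, y).statistic)
        results.append(
            MutationResult(k, int(states.states[k]), c, c_prime, c_prime - c)
        )
    if not results:
        warnings.warn("mutation scan found no sites above the correlation threshold")
    return results


def categorize_sites(
    results: Sequence[MutationResult],
    genes_path=None,
    promoters_path=None,
    bin_size: int = 10_000,
) -> list[MutationResult]:
    """Assign each mutated site to non-overlapping genomic categories:
    promoter (bin overlaps a promoter) > gene_body (overlaps a gene) > no_gene.
    """

    def load_bins(path) -> set[int]:
        if path is None:
            return set()
        try:
            df = pd.read_csv(path, sep="\t", comment="#", header=None,
                             usecols=[0, 1, 2], names=["chrom", "start", "end"])
            starts = df["start"].astype(int)
            ends = df["end"].astype(int)
        except Exception as exc:
            raise ValueError(f"unparseable annotation {path}: {exc}") from exc
        bins: set[int] = set()
        for start, end in zip(starts, ends):
            bins.update(range(start // bin_size, (max(end, start + 1) - 1) // bin_size + 1))
        return bins

    promoter_bins = load_bins(promoters_path)
    gene_bins = load_bins(genes_path)
    out = []
    for r in results:
        if r.site in promoter_bins:
            cat = "promoter"
        elif r.site in gene_bins:
            cat = "gene_body"
        else:
            cat = "no_gene"
        out.append(MutationResult(r.site, r.original_spin, r.c, r.c_prime, r.delta_c, cat))
    return out


def write_predicted_map(pred: PredictedMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# bin_i\tbin_j\td\tratio\n")
        for (i, j), r in sorted(pred.ratios.items()):
            fh.write(f"{i}\t{j}\t{j - i}\t{r:.6g}\n")


def write_mutation_results(results: Sequence[MutationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("# site\tstate\tc\tc_prime\tdelta_c\tcategory\n")
        for r in results:
            fh.write(
                f"{r.site}\t{r.original_spin}\t{r.c:.6g}\t{r.c_prime:.6g}"
                f"\t{r.delta_c:.6g}\t{r.category}\n"
            )
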