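"""Inverse inference: chromatin states from Hi-C counts alone.

Given a fitted model bank and an observed count map {n_ij}, the posterior
probability that bin k is spin-up marginalizes each pair's count likelihood
over all 2^N neighborhoods consistent with σ_k:

    P(σ_k|{n_ij}) ∝ P(σ_k)^(1−M) · Π_{(i,j) ∋ k} Σ_{σ: σ_k' = σ_k}
                     P(n_ij|σ, d) P(σ|d),

where k' is k's position in the pair's neighborhood and M the number of
pairs containing k.  The count likelihood P(n|σ,d) is Gaussian with mean
λ_{σ,d} = <n(d)> · P(c|σ,d)/P(c|d) and a variance either pooled from the
data at each distance or set to λ (Poisson-matched).  All products are
accumulated in the log domain with per-pair log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .contacts import ContactMap
from .genome import MISSING, BinnedChromosome
from .maxent import ModelBank, state_table
from .neighborhoods import NeighborhoodScheme, neighborhood_indices
from .forward import contact_ratio


@dataclass
class CountLikelihoodConfig:
    """How the Gaussian count likelihood's variance is chosen.

    ``pooled`` uses the per-distance empirical variance ζ²(d) from the
    distance profile; ``poisson`` sets ζ² = λ per neighborhood.  ``floor``
    keeps the variance strictly positive.
    """

    variance_mode: str = "pooled"
    floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.variance_mode not in ("pooled", "poisson"):
            raise ValueError("variance_mode must be 'pooled' or 'poisson'")
        if self.floor <= 0:
            raise ValueError("variance floor must be positive")


@dataclass
class PosteriorTrack:
    """Per-bin posterior P(σ_k = +1 | {n_ij}) and pair multiplicity M."""

    p_up: np.ndarray
    m_pairs: np.ndarray
    prior_up: float


def count_mean(bank: ModelBank, sigma: np.ndarray, d: int) -> float:
    """Expected count λ_{σ,d} = <n(d)> · P(c|σ,d)/P(c|d).

    The proportionality constant is fixed by the normalization identity
    E_background[ratio] = 1, so the background-average of λ is <n(d)>.
    """
    if bank.profile is None:
        raise ValueError("bank carries no distance profile")
    return bank.profile.mean(d) * contact_ratio(bank, sigma, d)


def count_likelihood(
    n: float,
    sigma: np.ndarray,
    d: int,
    bank: ModelBank,
    config: CountLikelihoodConfig | None = None,
) -> float:
    """Gaussian density N(λ_{σ,d}, ζ²) evaluated at the observed count n."""
    if not np.isfinite(n):
        raise ValueError("observed count must be finite")
    config = config or CountLikelihoodConfig()
    lam = count_mean(bank, sigma, d)
    if config.variance_mode == "poisson":
        var = max(lam, config.floor)
    else:
        var = max(bank.profile.var(d), config.floor)
    return float(np.exp(-0.5 * (n - lam) ** 2 / var) / np.sqrt(2 * np.pi * var))


def _per_distance_tables(bank: ModelBank, d: int, config: CountLikelihoodConfig):
    """Background log-probs, λ table and variance over all 2^N states at d."""
    mc, mb = bank.models_at(d)
    lb = mb.energies() - mb.log_z()
    lc = mc.energies() - mc.log_z()
    lam = bank.profile.mean(d) * np.exp(lc - lb)
    if config.variance_mode == "poisson":
        var = np.maximum(lam, config.floor)
    else:
        var = np.full_like(lam, max(bank.profile.var(d), config.floor))
    return lb, lam, var


def site_posterior(
    k: int,
    cmap: ContactMap,
    bank: ModelBank,
    prior_up: float = 0.5,
    scheme: NeighborhoodScheme | None = None,
    config: CountLikelihoodConfig | None = None,
) -> float:
    """Posterior P(σ_k = +1 | {n_ij}) for one genomic bin.

    Straightforward per-pair loop; :func:`infer_sequence` computes the same
    quantity vectorized over the whole chromosome.
    """
    scheme = scheme or bank.scheme
    config = config or CountLikelihoodConfig()
    n_bins = cmap.n_bins
    log_score = {+1: 0.0, -1: 0.0}
    m_pairs = 0
    for d in bank.distances:
        lb, lam, var = _per_distance_tables(bank, d, config)
        s_tab = state_table(bank.models_at(d)[0].n)
        offsets = neighborhood_indices(0, d, scheme)
        for p, off in enumerate(offsets):
            i = k - off
            if i < 0 or i + offsets[-1] >= n_bins or i + offsets[0] < 0:
                continue
            n_obs = cmap.get(i, i + d)
            loglik = (
                -0.5 * np.log(2 * np.pi * var)
                - 0.5 * (n_obs - lam) ** 2 / var
                + lb
            )
            up = s_tab[:, p] == 1
            log_score[+1] += float(logsumexp(loglik[up]))
            log_score[-1] += float(logsumexp(loglik[~up]))
            m_pairs += 1
    if m_pairs == 0:
        raise ValueError(f"site {k} participates in no in-range pairs")
    lp_up = np.log(prior_up) if prior_up > 0 else -np.inf
    lp_dn = np.log(1 - prior_up) if prior_up < 1 else -np.inf
    a = (1 - m_pairs) * lp_up + log_score[+1]
    b = (1 - m_pairs) * lp_dn + log_score[-1]
    return float(1.0 / (1.0 + np.exp(b - a)))


def infer_sequence(
    cmap: ContactMap,
    bank: ModelBank,
    prior_up: float = 0.5,
    threshold: float = 0.5,
    scheme: NeighborhoodScheme | None = None,
    config: CountLikelihoodConfig | None = None,
    region: tuple[int, int] | None = None,
) -> tuple[BinnedChromosome, PosteriorTrack]:
    """Infer the full spin track from counts: σ_k = +1 iff p_k >= threshold.

    Bins participating in no pair (chromosome edges, or everything when the
    bank is empty) are MISSING.  The sum over each pair's 2^N neighborhoods
    is shared across the pair's N sites, so the whole chromosome costs one
    (pairs × 2^N) likelihood table per distance.
    """
    scheme = scheme or bank.scheme
    config = config or CountLikelihoodConfig()
    n_bins = cmap.n_bins
    a, b = region if region is not None else (0, n_bins)
    acc = np.zeros((n_bins, 2))  # [:, 0] -> σ_k = +1, [:, 1] -> σ_k = −1
    m_pairs = np.zeros(n_bins, dtype=np.int64)

    for d in bank.distances:
        lb, lam, var = _per_distance_tables(bank, d, config)
        n_states = bank.models_at(d)[0].n
        s_tab = state_table(n_states)
        offsets = neighborhood_indices(0, d, scheme)
        lo, hi = offsets[0], offsets[-1]
        i_cand = np.arange(max(0, -lo), n_bins - hi)
        if i_cand.size == 0:
            continue
        counts = np.zeros(n_bins)
        i_ent, v_ent = cmap.pairs_at_distance(d)
        counts[i_ent] = v_ent
        n_obs = counts[i_cand]
        # (pairs, states) joint log of count likelihood and background prob
        total = (
            -0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (n_obs[:, None] - lam[None, :]) ** 2 / var[None, :]
            + lb[None, :]
        )
        for p in range(n_states):
            up = s_tab[:, p] == 1
            sites = i_cand + offsets[p]
            np.add.at(acc[:, 0], sites, logsumexp(total[:, up], axis=1))
            np.add.at(acc[:, 1], sites, logsumexp(total[:, ~up], axis=1))
            np.add.at(m_pairs, sites, 1)

    lp_up = np.log(prior_up) if prior_up > 0 else -np.inf
    lp_dn = np.log(1 - prior_up) if prior_up < 1 else -np.inf
    p_up = np.full(n_bins, np.nan)
    covered = m_pairs > 0
    with np.errstate(invalid="ignore"):
        score_up = (1 - m_pairs[covered]) * lp_up + acc[covered, 0]
        score_dn = (1 - m_pairs[covered]) * lp_dn + acc[covered, 1]
    p_up[covered] = 1.0 / (1.0 + np.exp(np.clip(score_dn - score_up, -700, 700)))

    states = np.zeros(n_bins, dtype=np.int8)
    states[covered] = np.where(p_up[covered] >= threshold, 1, -1)
    states[:a] = MISSING
    states[b:] = MISSING
    chrom = BinnedChromosome(cmap.name, cmap.bin_size, states)
    return chrom, PosteriorTrack(p_up, m_pairs, prior_up)


def agreement(inferred: BinnedChromosome, truth: BinnedChromosome) -> float:
    """Fraction of bins with equal spin, MISSING bins excluded pairwise."""
    if inferred.n_bins != truth.n_bins:
        raise ValueError("tracks have different lengths")
    ok = (inferred.states != MISSING) & (truth.states != MISSING)
    if not ok.any():
        raise ValueError("no comparable (non-missing) sites")
    return float(np.mean(inferred.states[ok] == truth.states[ok]))


def write_posterior(
    track: PosteriorTrack, chrom: BinnedChromosome, path
) -> None:
    with open(path, "w") as fh:
        fh.write("# bin\tp_up\tm_pairs\tcall\n")
        label = {1: "UP", -1: "DOWN", MISSING: "MISSING"}
        for k in range(chrom.n_bins):
            p = track.p_up[k]
            fh.write(
                f"{k}\t{'nan' if np.isnan(p) else f'{p:.6g}'}\t"
                f"{track.m_pairs[k]}\t{label[int(chrom.states[k])]}\n"
            )
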