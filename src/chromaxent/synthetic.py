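"""Synthetic chromatin sequences and contact maps with planted structure.

The generator produces exactly the statistical situation the model assumes,
which makes parameter recovery a well-posed test of every stage:

* the chromatin track is a stationary two-state Markov chain with a given
  persistence probability (geometric run lengths, like real chromatin
  domains);
* the BACKGROUND Ising model at each distance is the *exact* marginal of
  that chain on the neighborhood positions — a Markov chain restricted to an
  ordered subset of sites is again nearest-neighbour Ising with couplings
  J = atanh((2p−1)^gap) across each genomic gap;
* the CONTACT model adds positive fields at the two contacting positions and
  distance-dependent extra couplings whose sign flips at a configurable
  distance d* (ferromagnetic below, antiferromagnetic above, echoing the
  fitted-parameter transition seen in real data);
* counts are Poisson with mean <n(d)> · P(σ|c,d)/P(σ|d), i.e. the Bayes
  ratio of the planted pair, under a power-law distance-decay depth profile.

Because the planted background matches the true sequence statistics, the
count-weighted neighborhood ensemble converges (in depth) to the planted
CONTACT distribution, so a fit of the simulated data should recover the
planted parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .contacts import ContactMap, DistanceProfile
from .genome import BinnedChromosome
from .maxent import IsingModel, ModelBank, pair_index
from .neighborhoods import NeighborhoodScheme, neighborhood_indices
from .forward import contact_ratio


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults give a 20000-bin chromosome with ~10-bin chromatin domains,
    distances 1..15 at window size 4, and ~100 mean counts per pair at d=1
    decaying as d^-0.75.
    """

    n_bins: int = 20_000
    persistence: float = 0.9
    window_size: int = 4
    d_min: int = 1
    d_max: int = 15
    depth: float = 100.0
    decay_exponent: float = 0.75
    h_contact: float = 0.6
    j_contact: float = 0.2
    d_star: int = 8
    bin_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.d_min < 1 or self.d_max < self.d_min:
            raise ValueError("need 1 <= d_min <= d_max")

    @property
    def scheme(self) -> NeighborhoodScheme:
        return NeighborhoodScheme(self.window_size)

    @property
    def d_range(self) -> range:
        return range(self.d_min, self.d_max + 1)

    def mean_profile(self) -> np.ndarray:
        """<n(d)> for d = 1..d_max: depth · d^−decay_exponent."""
        d = np.arange(1, self.d_max + 1, dtype=float)
        return self.depth * d**-self.decay_exponent


def generate_states(config: SyntheticConfig, rng: np.random.Generator | None = None) -> BinnedChromosome:
    """Stationary two-state Markov chain: σ repeats with prob. `persistence`."""
    if config.n_bins < config.scheme.size(config.d_max) + config.d_max:
        raise ValueError("n_bins too small for the neighborhood scheme")
    rng = rng or np.random.default_rng(config.seed)
    first = 1 if rng.random() < 0.5 else -1
    stay = rng.random(config.n_bins - 1) < config.persistence
    signs = np.where(stay, 1, -1)
    states = first * np.concatenate(([1], np.cumprod(signs)))
    return BinnedChromosome("syn", config.bin_size, states.astype(np.int8))


def _background_model(config: SyntheticConfig, d: int) -> IsingModel:
    """Exact Ising marginal of the Markov chain on the neighborhood positions."""
    scheme = config.scheme
    idx = neighborhood_indices(0, d, scheme)
    n = idx.size
    rho = 2.0 * config.persistence - 1.0  # lag-1 spin autocorrelation
    j = np.zeros(n * (n - 1) // 2)
    order = pair_index(n)
    for p in range(n - 1):
        gap = int(idx[p + 1] - idx[p])
        val = np.arctanh(np.clip(rho**gap, -1 + 1e-12, 1 - 1e-12))
        j[order.index((p, p + 1))] = val
    return IsingModel(n, np.zeros(n), j, condition="background", d=d)


def _contact_model(config: SyntheticConfig, d: int) -> IsingModel:
    """Background plus contact fields and a sign-flipping interior coupling."""
    base = _background_model(config, d)
    scheme = config.scheme
    h = base.h.copy()
    j = base.j.copy()
    pi, pj = scheme.position_of_i(d), scheme.position_of_j(d)
    h[pi] += config.h_contact
    h[pj] += config.h_contact
    sign = 1.0 if d < config.d_star else -1.0
    order = pair_index(base.n)
    idx = neighborhood_indices(0, d, scheme)
    # couple consecutive interior positions strictly between the two sites
    for p in range(base.n - 1):
        if pi <= p < pj and 0 <= idx[p] and idx[p + 1] <= d:
            j[order.index((p, p + 1))] += sign * config.j_contact
    return IsingModel(base.n, h, j, condition="contact", d=d)


def plant_bank(config: SyntheticConfig) -> ModelBank:
    """Planted CONTACT/BACKGROUND model pair per distance plus depth profile."""
    bank = ModelBank(config.scheme, seed=config.seed)
    mean = config.mean_profile()
    for d in config.d_range:
        bank.background[d] = _background_model(config, d)
        bank.contact[d] = _contact_model(config, d)
    # ζ²(d) = λ in expectation for Poisson counts; refined by the fit later
    bank.profile = DistanceProfile(
        config.d_max, mean, mean.copy(), np.zeros(config.d_max, dtype=np.int64)
    )
    return bank


def simulate_contacts(
    states: BinnedChromosome,
    bank: ModelBank,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Poisson counts n_ij ~ Pois(<n(d)> · ratio(σ_ij, d)) for in-range pairs."""
    rng = rng or np.random.default_rng(config.seed + 1)
    scheme = bank.scheme
    n_bins = states.n_bins
    rows, cols, vals = [], [], []
    mean = config.mean_profile()
    for d in bank.distances:
        offsets = neighborhood_indices(0, d, scheme)
        lo, hi = offsets[0], offsets[-1]
        i_cand = np.arange(max(0, -lo), n_bins - hi)
        if i_cand.size == 0:
            continue
        block = states.states[i_cand[:, None] + offsets[None, :]].astype(float)
        mc, mb = bank.models_at(d)
        dh = mc.h - mb.h
        dj = mc.j - mb.j
        de = block @ dh
        if dj.any():
            pk = [k for k, _ in pair_index(mc.n)]
            pl = [l for _, l in pair_index(mc.n)]
            de += (block[:, pk] * block[:, pl]) @ dj
        ratio = np.exp(de + mb.log_z() - mc.log_z())
        lam = mean[d - 1] * ratio
        n = rng.poisson(lam)
        nz = n > 0
        rows.append(i_cand[nz])
        cols.append(i_cand[nz] + d)
        vals.append(n[nz].astype(float))
    return ContactMap(
        states.name,
        states.bin_size,
        n_bins,
        np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64),
        np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64),
        np.concatenate(vals) if vals else np.zeros(0),
    )


def planted_ratios(
    states: BinnedChromosome, bank: ModelBank
) -> dict[tuple[int, int], float]:
    """The generative distance-normalized contact ratios for every simulated
    pair — the ground truth a forward prediction should recover."""
    out: dict[tuple[int, int], float] = {}
    scheme = bank.scheme
    n_bins = states.n_bins
    for d in bank.distances:
        offsets = neighborhood_indices(0, d, scheme)
        lo, hi = offsets[0], offsets[-1]
        for i in range(max(0, -lo), n_bins - hi):
            sigma = states.states[i + offsets]
            out[(i, i + d)] = contact_ratio(bank, sigma, d)
    return out


def make_fixture(config: SyntheticConfig, out_dir) -> dict:
    """Write a complete fixture directory: states BED, contact COO TSV,
    planted-bank JSON, and a manifest with the seed.  Returns the manifest."""
    from .genome import write_state_track
    from .contacts import write_contact_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    states = generate_states(config, rng)
    bank = plant_bank(config)
    cmap = simulate_contacts(states, bank, config, rng)
    write_state_track([states], out / "states.bed")
    write_contact_map(cmap, out / "contacts.tsv")
    bank.save(out / "planted_bank.json")
    manifest = {
        "config": asdict(config),
        "files": ["states.bed", "contacts.tsv", "planted_bank.json"],
        "n_contacts_total": float(cmap.val.sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
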