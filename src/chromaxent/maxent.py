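"""Maximum-entropy (Ising) distributions over spin vectors, by exact enumeration.

The least-committed distribution matching first and second spin moments is
the Boltzmann distribution of an Ising model at kT = 1,

    P(σ) = exp( Σ_k h_k σ_k + Σ_{k<l} J_kl σ_k σ_l ) / Z,

whose fields h_k and couplings J_kl are the Lagrange multipliers of the
moment constraints.  For neighborhoods of up to ~23 spins the 2^N states can
be enumerated exactly, so fitting proceeds by plain moment-matching gradient
steps (Boltzmann learning): Δh_k = α(<σ_k>_data − <σ_k>_model) and likewise
for J.  The problem is convex, so convergence is to the unique solution.

A :class:`ModelBank` collects the fitted CONTACT / BACKGROUND model pair at
every genomic distance together with the contact-count distance profile —
everything the forward (contact prediction) and inverse (sequence inference)
calculations need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .contacts import ContactMap, DistanceProfile, distance_profile
from .genome import BinnedChromosome
from .neighborhoods import (
    Condition,
    MomentSet,
    NeighborhoodScheme,
    ensemble_moments,
    extract_ensemble,
)

#: Default enumeration limit; beyond ~23 spins exact enumeration is hopeless.
ENUM_LIMIT = 20
HARD_CAP = 23

_state_cache: dict[int, np.ndarray] = {}
_pair_cache: dict[int, np.ndarray] = {}


def state_table(n: int) -> np.ndarray:
    """The (2^n, n) table of all spin vectors, cached per n.

    State index ``b`` maps bit ``k`` to ``σ_k = +1`` if set, else −1
    (bit 0 = position 0).  Repeated calls at the same n return the same array.
    """
    if n not in _state_cache:
        b = np.arange(2**n, dtype=np.int64)
        _state_cache[n] = np.where(
            (b[:, None] >> np.arange(n)[None, :]) & 1, 1, -1
        ).astype(np.int8)
    return _state_cache[n]


def pair_table(n: int) -> np.ndarray:
    """(2^n, n(n-1)/2) table of σ_k σ_l products, cached for n <= 16."""
    if n not in _pair_cache:
        s = state_table(n).astype(float)
        cols = [s[:, k] * s[:, l] for k, l in combinations(range(n), 2)]
        tab = np.stack(cols, axis=1) if cols else np.zeros((2**n, 0))
        if n <= 16:
            _pair_cache[n] = tab
        else:
            return tab
    return _pair_cache[n]


def pair_index(n: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle ordering of couplings: (0,1), (0,2), ..."""
    return list(combinations(range(n), 2))


class FitError(RuntimeError):
    """Moment-matching failed to converge within the iteration budget."""


@dataclass
class IsingModel:
    """Fields and couplings of one max-ent distribution.

    ``j`` is the coupling vector in :func:`pair_index` order (all zero for an
    order-1 model).  ``condition``/``d`` tag which ensemble the model was
    fitted to.
    """

    n: int
    h: np.ndarray
    j: np.ndarray | None = None
    order: int = 2
    condition: str | None = None
    d: int | None = None

    def __post_init__(self) -> None:
        if self.n > HARD_CAP:
            raise ValueError(f"N={self.n} exceeds the enumeration cap {HARD_CAP}")
        self.h = np.asarray(self.h, dtype=float)
        if self.h.size != self.n:
            raise ValueError("h must have length n")
        npair = self.n * (self.n - 1) // 2
        if self.j is None:
            self.j = np.zeros(npair)
        self.j = np.asarray(self.j, dtype=float)
        if self.j.size != npair:
            raise ValueError("j must have length n(n-1)/2")
        if self.order == 1 and np.any(self.j != 0):
            raise ValueError("order-1 model must have all couplings zero")
        self._log_z: float | None = None

    def coupling(self, k: int, l: int) -> float:
        if k > l:
            k, l = l, k
        return float(self.j[pair_index(self.n).index((k, l))])

    def j_matrix(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for (k, l), v in zip(pair_index(self.n), self.j):
            out[k, l] = out[l, k] = v
        return out

    # -- enumeration -------------------------------------------------------

    def energies(self) -> np.ndarray:
        """E(σ) = Σ h_k σ_k + Σ_{k<l} J_kl σ_k σ_l for every enumerated state."""
        s = state_table(self.n)
        e = s @ self.h
        if self.j.any():
            if self.n <= 16:
                e = e + pair_table(self.n) @ self.j
            else:
                for (k, l), v in zip(pair_index(self.n), self.j):
                    if v:
                        e = e + v * (s[:, k] * s[:, l])
        return e

    def log_z(self) -> float:
        if self._log_z is None:
            self._log_z = float(logsumexp(self.energies()))
        return self._log_z

    def log_prob(self, sigma: np.ndarray) -> float:
        """Log-probability of one spin vector (natural log)."""
        sigma = np.asarray(sigma, dtype=float)
        e = float(sigma @ self.h)
        for (k, l), v in zip(pair_index(self.n), self.j):
            e += v * sigma[k] * sigma[l]
        return e - self.log_z()


def enumerate_distribution(model: IsingModel, limit: int = ENUM_LIMIT) -> np.ndarray:
    """Probability of every one of the 2^N states, in state-table order."""
    if model.n > limit:
        raise ValueError(
            f"N={model.n} exceeds enumeration limit {limit}; reduce the window size W"
        )
    e = model.energies()
    e = e - e.max()
    p = np.exp(e)
    return p / p.sum()


def model_moments(model: IsingModel, order: int = 2, limit: int = ENUM_LIMIT) -> MomentSet:
    """Exact expectations <σ_k>, <σ_kσ_l> (and <σ_kσ_lσ_m>) under the model."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    p = enumerate_distribution(model, limit)
    s = state_table(model.n).astype(float)
    m = p @ s
    c: dict[tuple[int, int], float] = {}
    t = None
    if order >= 2:
        cvec = p @ (s[:, [k for k, _ in pair_index(model.n)]]
                    * s[:, [l for _, l in pair_index(model.n)]])
        c = dict(zip(pair_index(model.n), map(float, cvec)))
    if order >= 3:
        t = {}
        for k, l, mm in combinations(range(model.n), 3):
            t[(k, l, mm)] = float(np.sum(p * s[:, k] * s[:, l] * s[:, mm]))
    return MomentSet(model.n, m, c, t)


@dataclass
class FitConfig:
    """Boltzmann-learning hyperparameters.

    α is the learning rate, ε the per-constraint convergence tolerance; both
    defaults follow the published fitting procedure.
    """

    learning_rate: float = 0.025
    tolerance: float = 1e-4
    max_iter: int = 50_000
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.tolerance <= 0:
            raise ValueError("learning_rate and tolerance must be positive")


def fit_ising(
    target: MomentSet,
    order: int = 2,
    config: FitConfig | None = None,
    limit: int = ENUM_LIMIT,
    condition: str | None = None,
    d: int | None = None,
) -> tuple[IsingModel, int]:
    """Fit fields (and couplings, for order 2) to the target moments.

    Plain gradient moment matching: each iteration enumerates the model
    distribution, then steps h by α(m_target − m_model) and J by
    α(C_target − C_model), until every constrained moment is within ε.
    Returns the converged model and the iteration count.
    """
    if config is None:
        config = FitConfig()
    if order not in (1, 2):
        raise ValueError("fit order must be 1 or 2")
    n = target.n
    if n > limit:
        raise ValueError(f"N={n} exceeds enumeration limit {limit}")
    m_t = np.asarray(target.m, dtype=float)
    if np.any(np.abs(m_t) >= 1.0):
        raise ValueError("unrealizable target: |<σ_k>| must be < 1 (infinite field)")
    pairs = pair_index(n)
    if order == 2:
        c_t = np.array([target.c[p] for p in pairs]) if pairs else np.zeros(0)
        if np.any(np.abs(c_t) >= 1.0):
            raise ValueError("unrealizable target: |<σ_kσ_l>| must be < 1")
    else:
        c_t = None

    rng = np.random.default_rng(config.seed)
    h = rng.uniform(-config.init_scale, config.init_scale, size=n)
    j = (
        rng.uniform(-config.init_scale, config.init_scale, size=len(pairs))
        if order == 2
        else np.zeros(len(pairs))
    )

    s = state_table(n).astype(float)
    ptab = pair_table(n) if n <= 16 else None
    alpha, eps = config.learning_rate, config.tolerance

    for it in range(config.max_iter):
        e = s @ h
        if order == 2 and len(pairs):
            e = e + (ptab @ j if ptab is not None
                     else IsingModel(n, h, j).energies() - s @ h)
        e -= e.max()
        p = np.exp(e)
        p /= p.sum()
        m_mod = p @ s
        res = np.abs(m_mod - m_t).max() if n else 0.0
        if order == 2 and len(pairs):
            c_mod = p @ ptab if ptab is not None else np.array(
                [np.sum(p * s[:, k] * s[:, l]) for k, l in pairs]
            )
            res = max(res, np.abs(c_mod - c_t).max())
        if res < eps:
            model = IsingModel(n, h, j if order == 2 else None,
                               order=order, condition=condition, d=d)
            return model, it
        h = h + alpha * (m_t - m_mod)
        if order == 2 and len(pairs):
            j = j + alpha * (c_t - c_mod)
    raise FitError(
        f"moment matching did not converge in {config.max_iter} iterations "
        f"(worst residual {res:.3e})"
    )


def model_entropy(model: IsingModel, limit: int = ENUM_LIMIT) -> float:
    """Shannon entropy S = −Σ P log2 P in bits; 2^S is the effective
    number of neighborhoods the distribution stores."""
    p = enumerate_distribution(model, limit)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def kl_divergence(p: IsingModel, q: IsingModel, limit: int = ENUM_LIMIT) -> float:
    """D(p ‖ q) = Σ P_p log2(P_p / P_q), in bits."""
    if p.n != q.n:
        raise ValueError(f"mismatched sizes: {p.n} vs {q.n}")
    pp = enumerate_distribution(p, limit)
    lp = p.energies() - p.log_z()
    lq = q.energies() - q.log_z()
    return float(np.sum(pp * (lp - lq)) / np.log(2))


# -- model bank ------------------------------------------------------------

BANK_SCHEMA_VERSION = 1


@dataclass
class ModelBank:
    """Fitted CONTACT/BACKGROUND model pair per genomic distance.

    Carries the distance profile <n(d)>, ζ²(d) needed to turn contact-
    probability ratios into expected Hi-C counts.
    """

    scheme: NeighborhoodScheme
    contact: dict[int, IsingModel] = field(default_factory=dict)
    background: dict[int, IsingModel] = field(default_factory=dict)
    profile: DistanceProfile | None = None
    iterations: dict[int, tuple[int, int]] = field(default_factory=dict)
    seed: int = 0

    @property
    def distances(self) -> list[int]:
        return sorted(self.contact)

    def models_at(self, d: int) -> tuple[IsingModel, IsingModel]:
        if d not in self.contact:
            raise KeyError(f"no fitted models at distance d={d}")
        return self.contact[d], self.background[d]

    # -- JSON serialization ------------------------------------------------

    def to_dict(self) -> dict:
        def dump(m: IsingModel) -> dict:
            return {
                "n": m.n,
                "order": m.order,
                "h": m.h.tolist(),
                "j": m.j.tolist(),
            }

        out = {
            "schema_version": BANK_SCHEMA_VERSION,
            "window_size": self.scheme.window_size,
            "seed": self.seed,
            "distances": self.distances,
            "contact": {str(d): dump(m) for d, m in self.contact.items()},
            "background": {str(d): dump(m) for d, m in self.background.items()},
            "iterations": {str(d): list(v) for d, v in self.iterations.items()},
        }
        if self.profile is not None:
            out["profile"] = {
                "d_max": self.profile.d_max,
                "mean_counts": self.profile.mean_counts.tolist(),
                "var_counts": self.profile.var_counts.tolist(),
                "pair_counts": self.profile.pair_counts.tolist(),
            }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelBank":
        scheme = NeighborhoodScheme(data["window_size"])
        bank = cls(scheme, seed=data.get("seed", 0))
        for cond, store in (("contact", bank.contact), ("background", bank.background)):
            for key, m in data[cond].items():
                store[int(key)] = IsingModel(
                    m["n"], np.array(m["h"]), np.array(m["j"]),
                    order=m["order"], condition=cond, d=int(key),
                )
        bank.iterations = {int(k): tuple(v) for k, v in data.get("iterations", {}).items()}
        if "profile" in data:
            p = data["profile"]
            bank.profile = DistanceProfile(
                p["d_max"],
                np.array(p["mean_counts"]),
                np.array(p["var_counts"]),
                np.array(p["pair_counts"], dtype=np.int64),
            )
        return bank

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelBank":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_bank(
    states: BinnedChromosome,
    cmap: ContactMap,
    d_range: Sequence[int],
    scheme: NeighborhoodScheme = NeighborhoodScheme(),
    config: FitConfig | None = None,
    regions: Sequence[tuple[int, int]] | None = None,
    order: int = 2,
    limit: int = ENUM_LIMIT,
    profile: DistanceProfile | None = None,
) -> ModelBank:
    """Fit the CONTACT and BACKGROUND max-ent models at every distance in
    ``d_range`` from one chromosome's states and contact counts."""
    if config is None:
        config = FitConfig()
    d_range = sorted(set(int(d) for d in d_range))
    if profile is None:
        valid = np.flatnonzero(states.valid_mask())
        profile = distance_profile(cmap, max(d_range), valid)
    bank = ModelBank(scheme, profile=profile, seed=config.seed)
    for d in d_range:
        try:
            ens_c = extract_ensemble(states, cmap, d, Condition.CONTACT, regions, scheme)
            ens_b = extract_ensemble(states, None, d, Condition.BACKGROUND, regions, scheme)
            mom_c = ensemble_moments(ens_c, order=min(order, 2))
            mom_b = ensemble_moments(ens_b, order=min(order, 2))
            mc, itc = fit_ising(mom_c, order, config, limit, "contact", d)
            mb, itb = fit_ising(mom_b, order, config, limit, "background", d)
        except (ValueError, FitError) as exc:
            raise type(exc)(f"d={d}: {exc}") from exc
        bank.contact[d] = mc
        bank.background[d] = mb
        bank.iterations[d] = (itc, itb)
    return bank
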