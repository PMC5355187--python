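"""Plant species pools and animal partner sets.

A :class:`SpeciesPool` represents the regional plant community available to a
reintroduced animal, with one *occupancy weight* per species: the probability
that any given arena cell contains that species.  Occupancy is the package's
minimal representation of commonness versus rarity — common species occur in
many cells, rare species in few — which is what drives how fast a spreading
population encounters them.

A :class:`PartnerSet` is the set of plant species a given animal can interact
with.  Its size (degree) encodes the generalist/specialist axis: generalists
carry large partner sets, specialists small ones, and the degree is the
maximal interaction credit the animal can cash from the pool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "SpeciesPool",
    "PartnerSet",
    "canonicalize",
    "build_pool",
    "sample_partner_set",
    "rank_skew_weights",
]

_WS = re.compile(r"\s+")


def canonicalize(identifier: str) -> str:
    """Canonical form of a species identifier.

    Trims leading/trailing whitespace, collapses internal whitespace runs to a
    single space and case-folds.  Applied at every ingestion boundary so that
    ``"  Astrocaryum  aculeatissimum "`` and ``"astrocaryum aculeatissimum"``
    refer to the same species.
    """
    return _WS.sub(" ", str(identifier).strip()).casefold()


@dataclass(frozen=True)
class SpeciesPool:
    """A plant pool with per-species occupancy weights.

    Parameters
    ----------
    species_ids
        Unique (after canonicalization) species identifiers, in rank order
        when produced by :func:`build_pool` with a rank-skewed model.
    occupancy_weights
        Per-species cell-occupancy probabilities, each in (0, 1].
    """

    species_ids: tuple[str, ...]
    occupancy_weights: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(canonicalize(s) for s in self.species_ids)
        if len(ids) < 1:
            raise ValueError("a species pool needs at least one species")
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate species after canonicalization: {dupes}")
        w = np.asarray(self.occupancy_weights, dtype=float)
        if w.shape != (len(ids),):
            raise ValueError("occupancy_weights must match species_ids in length")
        if not np.all((w > 0.0) & (w <= 1.0)):
            raise ValueError("every occupancy_weight must lie in (0, 1]")
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(self, "occupancy_weights", w)

    @property
    def size(self) -> int:
        return len(self.species_ids)

    def weight_of(self, species_id: str) -> float:
        try:
            return float(
                self.occupancy_weights[self.species_ids.index(canonicalize(species_id))]
            )
        except ValueError:
            raise KeyError(f"species not in pool: {species_id!r}") from None


@dataclass(frozen=True)
class PartnerSet:
    """An animal's potential interaction partners within a pool.

    The degree (number of partners) is the maximal credit of ecological
    interactions this animal can cash from the pool it was drawn from.
    """

    animal_id: str
    partner_ids: frozenset[str]

    def __post_init__(self) -> None:
        partners = frozenset(canonicalize(s) for s in self.partner_ids)
        if len(partners) < 1:
            raise ValueError("a partner set needs at least one partner species")
        object.__setattr__(self, "partner_ids", partners)
        object.__setattr__(self, "animal_id", str(self.animal_id))

    @property
    def degree(self) -> int:
        return len(self.partner_ids)

    def issubset_of(self, pool: SpeciesPool) -> bool:
        return self.partner_ids <= set(pool.species_ids)


def rank_skew_weights(
    n: int,
    sigma: float,
    base: float = 0.3,
    min_occupancy: float = 0.005,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Rank-sorted lognormal occupancy weights.

    Draws ``base * exp(sigma * Z)`` with standard-normal ``Z``, clips into
    ``[min_occupancy, 1]`` and sorts descending so that rank 1 is the most
    common species.  ``sigma = 0`` degenerates to all weights equal to
    ``base`` (no commonness structure).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if not 0 < base <= 1:
        raise ValueError(f"base occupancy must lie in (0, 1], got {base}")
    if not 0 < min_occupancy <= 1:
        raise ValueError(f"min_occupancy must lie in (0, 1], got {min_occupancy}")
    rng = np.random.default_rng() if rng is None else rng
    raw = base * np.exp(sigma * rng.standard_normal(n))
    w = np.clip(raw, min_occupancy, 1.0)
    return np.sort(w)[::-1]


def build_pool(
    n_species: int,
    occupancy_model: str = "lognormal_rank",
    *,
    seed: int,
    p: float = 1.0,
    sigma: float = 1.5,
    base: float = 0.3,
    min_occupancy: float = 0.005,
) -> SpeciesPool:
    """Build a species pool under a named occupancy model.

    ``uniform`` assigns every species the same weight ``p``; it is the
    degenerate no-abundance-structure case (``p = 1`` puts every species in
    every cell).  ``lognormal_rank`` draws lognormal weights and sorts them
    descending by rank, giving the long-tailed common/rare structure typical
    of plant communities.  Deterministic given ``seed``.
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    rng = np.random.default_rng(seed)
    if occupancy_model == "uniform":
        if not 0 < p <= 1:
            raise ValueError(f"p must lie in (0, 1], got p={p}")
        weights = np.full(n_species, float(p))
    elif occupancy_model == "lognormal_rank":
        if sigma <= 0:
            raise ValueError(f"lognormal_rank requires sigma > 0, got sigma={sigma}")
        weights = rank_skew_weights(
            n_species, sigma=sigma, base=base, min_occupancy=min_occupancy, rng=rng
        )
    else:
        raise ValueError(
            f"unknown occupancy_model {occupancy_model!r}; "
            "expected 'uniform' or 'lognormal_rank'"
        )
    ids = tuple(f"sp{i:05d}" for i in range(1, n_species + 1))
    return SpeciesPool(species_ids=ids, occupancy_weights=weights)


def sample_partner_set(
    pool: SpeciesPool,
    degree: int,
    strategy: str = "uniform",
    *,
    seed: int,
    superset: Optional[PartnerSet] = None,
    animal_id: str = "animal-1",
) -> PartnerSet:
    """Draw a partner set of the requested degree from a pool.

    ``uniform`` draws species uniformly without replacement from the whole
    pool.  ``nested_within`` draws uniformly from ``superset.partner_ids``,
    guaranteeing that a specialist's partners are a subset of a generalist's
    for paired comparisons.  Deterministic given ``seed``.
    """
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    if degree > pool.size:
        raise ValueError(f"degree {degree} exceeds pool size {pool.size}")
    rng = np.random.default_rng(seed)
    if strategy == "uniform":
        candidates = list(pool.species_ids)
    elif strategy == "nested_within":
        if superset is None:
            raise ValueError("nested_within sampling requires a superset partner set")
        if degree > superset.degree:
            raise ValueError(
                f"degree {degree} exceeds superset degree {superset.degree}"
            )
        if not superset.issubset_of(pool):
            raise ValueError("superset partners are not all members of the pool")
        candidates = sorted(superset.partner_ids)
    else:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected 'uniform' or 'nested_within'"
        )
    chosen = rng.choice(len(candidates), size=degree, replace=False)
    return PartnerSet(
        animal_id=animal_id,
        partner_ids=frozenset(candidates[i] for i in chosen),
    )
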