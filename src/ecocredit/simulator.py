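"""Post-reintroduction expansion and interaction-rewiring simulator.

The model: a population is released into a rectangular arena of cells, each
cell stochastically stocked with plant species according to their occupancy
weights.  The population expands deterministically by one von Neumann ring
per step — expansion over space standing in for population growth through
time — and a partner species counts as *rewired* at the first step at which
any occupied cell contains it.  Stochasticity lives entirely in the arena
composition, so replicates differ in species placement but share the same
expansion geometry.

Running many replicates yields a :class:`RewiringTrajectory` whose per-step
mean and min–max envelope reproduce the classic accumulation picture:
steep rewiring while the frontier sweeps through commonly occurring species,
then an asymptotic tail as only rare species remain, ending exactly at the
partner-set degree (every species is force-seeded into at least one cell, so
the full credit is always eventually cashed).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pools import PartnerSet, SpeciesPool, canonicalize

__all__ = [
    "Arena",
    "PopulationState",
    "RewiringTrajectory",
    "CreditLedger",
    "RewiringTimes",
    "populate_arena",
    "expand",
    "trajectory_on_arena",
    "simulate_rewiring",
    "summarize_trajectory",
    "ledger_from_trajectory",
    "rewiring_time",
]

Coordinate = tuple[int, int]
SeedLike = Union[int, np.random.SeedSequence]


@dataclass(eq=False)
class Arena:
    """A grid of cells, each holding a set of plant species.

    ``presence[s, y, x]`` is True when species ``s`` (indexing
    ``species_ids``) occurs in cell ``(x, y)``.  Coordinates are 0-based,
    ``x`` in ``[0, width)`` and ``y`` in ``[0, height)``.
    """

    width: int
    height: int
    species_ids: tuple[str, ...]
    presence: np.ndarray  # bool, shape (S, height, width)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("arena dimensions must be positive")
        self.species_ids = tuple(canonicalize(s) for s in self.species_ids)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.species_ids), self.height, self.width):
            raise ValueError("presence array shape does not match (S, height, width)")
        if not self.presence.reshape(len(self.species_ids), -1).any(axis=1).all():
            raise ValueError("every species must be present in at least one cell")

    def cell_contents(self, x: int, y: int) -> set[str]:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValueError(f"cell ({x}, {y}) outside arena bounds")
        mask = self.presence[:, y, x]
        return {s for s, m in zip(self.species_ids, mask) if m}

    @classmethod
    def from_cell_contents(
        cls,
        width: int,
        height: int,
        contents: Mapping[Coordinate, Iterable[str]],
        species_ids: Optional[Sequence[str]] = None,
    ) -> "Arena":
        """Build an arena from an explicit cell → species mapping (tests, docs)."""
        canon: dict[Coordinate, set[str]] = {}
        for (x, y), species in contents.items():
            if not (0 <= x < width and 0 <= y < height):
                raise ValueError(f"cell ({x}, {y}) outside {width}x{height} arena")
            canon[(x, y)] = {canonicalize(s) for s in species}
        if species_ids is None:
            ids = tuple(sorted(set().union(*canon.values()) if canon else set()))
        else:
            ids = tuple(canonicalize(s) for s in species_ids)
        index = {s: i for i, s in enumerate(ids)}
        presence = np.zeros((len(ids), height, width), dtype=bool)
        for (x, y), species in canon.items():
            for s in species:
                if s not in index:
                    raise ValueError(f"species {s!r} not in declared species_ids")
                presence[index[s], y, x] = True
        return cls(width=width, height=height, species_ids=ids, presence=presence)


@dataclass(frozen=True, eq=False)
class PopulationState:
    """Occupied cells of the reintroduced population at one expansion step."""

    occupied: np.ndarray  # bool, shape (height, width)
    step: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupied", np.asarray(self.occupied, dtype=bool))
        if self.step < 0:
            raise ValueError("step must be non-negative")

    @property
    def occupied_cells(self) -> set[Coordinate]:
        ys, xs = np.nonzero(self.occupied)
        return {(int(x), int(y)) for x, y in zip(xs, ys)}

    @classmethod
    def release(cls, arena: Arena, cell: Union[Coordinate, str] = "center") -> "PopulationState":
        x, y = resolve_release_cell(arena.width, arena.height, cell)
        occ = np.zeros((arena.height, arena.width), dtype=bool)
        occ[y, x] = True
        return cls(occupied=occ, step=0)


def resolve_release_cell(
    width: int, height: int, cell: Union[Coordinate, str]
) -> Coordinate:
    if isinstance(cell, str):
        if cell != "center":
            raise ValueError(f"unknown release cell spec {cell!r}")
        return width // 2, height // 2
    x, y = int(cell[0]), int(cell[1])
    if not (0 <= x < width and 0 <= y < height):
        raise ValueError(f"release cell ({x}, {y}) outside {width}x{height} arena")
    return x, y


@dataclass(eq=False)
class RewiringTrajectory:
    """Cumulative rewired-interaction richness per step, across replicates.

    ``cumulative_richness`` has shape (n_replicates, n_steps); row ``r`` is
    replicate ``r``'s count of distinct partner species rewired by each step.
    """

    steps: np.ndarray
    cumulative_richness: np.ndarray
    degree: int
    animal_id: str = "animal-1"

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        self.cumulative_richness = np.atleast_2d(
            np.asarray(self.cumulative_richness, dtype=int)
        )
        if self.cumulative_richness.shape[1] != self.steps.shape[0]:
            raise ValueError("cumulative_richness columns must match steps")
        if np.any(np.diff(self.cumulative_richness, axis=1) < 0):
            raise ValueError("cumulative richness must be non-decreasing per replicate")
        if np.any(self.cumulative_richness > self.degree):
            raise ValueError("cumulative richness cannot exceed the partner-set degree")

    @property
    def n_replicates(self) -> int:
        return self.cumulative_richness.shape[0]

    @property
    def final_richness(self) -> np.ndarray:
        return self.cumulative_richness[:, -1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (replicate, step, cumulative_richness)."""
        reps, steps = np.meshgrid(
            np.arange(self.n_replicates), self.steps, indexing="ij"
        )
        return pd.DataFrame(
            {
                "replicate": reps.ravel(),
                "step": steps.ravel(),
                "cumulative_richness": self.cumulative_richness.ravel(),
            }
        )


@dataclass(eq=False)
class CreditLedger:
    """Bookkeeping of cashed vs. remaining interaction credit over steps.

    Conservation holds by construction: ``cashed(t) + remaining(t) = credit0``
    at every step, and ``remaining`` is non-increasing because ``cashed`` is
    non-decreasing (rewiring is permanent — links are never lost).
    """

    credit0: float
    cashed: np.ndarray

    def __post_init__(self) -> None:
        self.cashed = np.asarray(self.cashed, dtype=float)
        if self.credit0 < 0:
            raise ValueError("credit0 must be non-negative")
        if self.cashed.size and self.cashed.max(initial=0.0) > self.credit0 + 1e-9:
            raise ValueError(
                f"cashed exceeds credit0={self.credit0}; inconsistent inputs"
            )
        if np.any(self.cashed < 0):
            raise ValueError("cashed values must be non-negative")

    @property
    def remaining(self) -> np.ndarray:
        return self.credit0 - self.cashed


def populate_arena(
    pool: SpeciesPool, width: int, height: int, seed: SeedLike
) -> Arena:
    """Stock an arena from a pool's occupancy weights.

    Each species is independently present in each cell with probability equal
    to its occupancy weight.  Any species that lands in no cell is then
    force-seeded into one uniformly chosen cell, so the realized arena always
    contains the full pool and the full credit is cashable.  Cells hold
    species *sets*, so any arena — down to a single cell — can host the whole
    pool.  Deterministic given ``seed``.
    """
    if width < 1 or height < 1:
        raise ValueError("arena dimensions must be positive")
    rng = np.random.default_rng(seed)
    presence = (
        rng.random((pool.size, height, width))
        < pool.occupancy_weights[:, None, None]
    )
    missing = ~presence.reshape(pool.size, -1).any(axis=1)
    for idx in np.flatnonzero(missing):
        cell = int(rng.integers(0, width * height))
        presence[idx, cell // width, cell % width] = True
    return Arena(
        width=width, height=height, species_ids=pool.species_ids, presence=presence
    )


def expand(state: PopulationState, arena: Arena) -> PopulationState:
    """One expansion step: add every cell 4-adjacent to the occupied set.

    Von Neumann frontier growth clipped to arena bounds; idempotent once the
    whole arena is occupied.
    """
    occ = state.occupied
    if not occ.any():
        raise ValueError("cannot expand an empty occupied set")
    if occ.shape != (arena.height, arena.width):
        raise ValueError("population state does not match arena dimensions")
    new = occ.copy()
    new[1:, :] |= occ[:-1, :]
    new[:-1, :] |= occ[1:, :]
    new[:, 1:] |= occ[:, :-1]
    new[:, :-1] |= occ[:, 1:]
    return PopulationState(occupied=new, step=state.step + 1)


def _partner_indices(arena: Arena, partner_set: PartnerSet) -> np.ndarray:
    index = {s: i for i, s in enumerate(arena.species_ids)}
    try:
        return np.array([index[s] for s in sorted(partner_set.partner_ids)])
    except KeyError as exc:
        raise ValueError(f"partner species {exc.args[0]!r} not present in arena") from None


def trajectory_on_arena(
    arena: Arena,
    partner_set: PartnerSet,
    release_cell: Union[Coordinate, str] = "center",
    lag_steps: int = 0,
) -> np.ndarray:
    """Cumulative rewired richness per step on one explicit arena.

    Expands from the release cell until the arena is fully occupied and
    returns the per-step count of distinct partner species encountered so
    far.  ``lag_steps`` holds the population at the release cell for the
    first ``lag_steps`` steps (establishment lag: Allee effects, reliance on
    supplementary food) before frontier growth begins.
    """
    if lag_steps < 0:
        raise ValueError("lag_steps must be non-negative")
    idx = _partner_indices(arena, partner_set)
    part = arena.presence[idx].reshape(len(idx), -1)
    state = PopulationState.release(arena, release_cell)
    seen = part[:, state.occupied.ravel()].any(axis=1)
    richness = [int(seen.sum())]
    richness.extend([richness[0]] * lag_steps)
    while not state.occupied.all():
        nxt = expand(state, arena)
        new_cells = nxt.occupied & ~state.occupied
        seen |= part[:, new_cells.ravel()].any(axis=1)
        state = nxt
        richness.append(int(seen.sum()))
    return np.asarray(richness, dtype=int)


def replicate_seed(seed: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based per-replicate seed: reproducible independently and in any order."""
    return np.random.SeedSequence([int(seed) % 2**63, int(replicate)])


def simulate_rewiring(
    pool: SpeciesPool,
    partner_set: PartnerSet,
    width: int,
    height: int,
    *,
    release_cell: Union[Coordinate, str] = "center",
    n_replicates: int = 100,
    seed: int,
    lag_steps: int = 0,
) -> RewiringTrajectory:
    """Run the release-and-expansion experiment across replicates.

    Each replicate stocks a fresh arena (seeded from ``(seed, replicate)``,
    independent of the partner set, so nested partner sets can be compared on
    identical arenas by reusing the seed) and records cumulative rewired
    richness from release (step 0) until full arena occupancy.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not partner_set.issubset_of(pool):
        raise ValueError("partner set is not a subset of the pool")
    resolve_release_cell(width, height, release_cell)  # fail fast on bad cell
    rows = [
        trajectory_on_arena(
            populate_arena(pool, width, height, replicate_seed(seed, r)),
            partner_set,
            release_cell=release_cell,
            lag_steps=lag_steps,
        )
        for r in range(n_replicates)
    ]
    # deterministic radial growth from a fixed release cell: every replicate
    # reaches full occupancy at the same step, so rows are equal length
    matrix = np.vstack(rows)
    return RewiringTrajectory(
        steps=np.arange(matrix.shape[1]),
        cumulative_richness=matrix,
        degree=partner_set.degree,
        animal_id=partner_set.animal_id,
    )


def summarize_trajectory(traj: RewiringTrajectory) -> pd.DataFrame:
    """Per-step mean and min–max envelope across replicates.

    The min–max band is the full range of the replicates (a "100% interval"),
    the envelope drawn as the shaded band in accumulation plots.
    """
    if traj.n_replicates < 1:
        raise ValueError("trajectory has no replicates")
    rich = traj.cumulative_richness
    return pd.DataFrame(
        {
            "step": traj.steps,
            "mean": rich.mean(axis=0),
            "min": rich.min(axis=0),
            "max": rich.max(axis=0),
        }
    )


def ledger_from_trajectory(
    traj: RewiringTrajectory,
    credit0: int,
    replicate: Optional[int] = None,
) -> CreditLedger:
    """Credit ledger for one replicate, or for the mean curve (default).

    ``credit0`` is the credit of ecological interactions available at release;
    it must be at least the largest observed richness or the inputs are
    inconsistent.
    """
    observed_max = int(traj.cumulative_richness.max())
    if credit0 < observed_max:
        raise ValueError(
            f"credit0={credit0} smaller than observed richness {observed_max}"
        )
    if replicate is None:
        cashed = traj.cumulative_richness.mean(axis=0)
    else:
        cashed = traj.cumulative_richness[replicate].astype(float)
    return CreditLedger(credit0=float(credit0), cashed=cashed)


@dataclass(frozen=True)
class RewiringTimes:
    """Per-replicate rewiring times; ``None`` marks a replicate that never
    cashed the full credit within the simulated horizon."""

    times: tuple[Optional[int], ...]

    @property
    def reached(self) -> tuple[int, ...]:
        return tuple(t for t in self.times if t is not None)

    @property
    def n_not_reached(self) -> int:
        return sum(1 for t in self.times if t is None)

    @property
    def min(self) -> Optional[int]:
        return min(self.reached) if self.reached else None

    @property
    def median(self) -> Optional[float]:
        return float(statistics.median(self.reached)) if self.reached else None

    @property
    def max(self) -> Optional[int]:
        return max(self.reached) if self.reached else None


def rewiring_time(
    obj: Union[RewiringTrajectory, CreditLedger],
    credit0: Optional[int] = None,
) -> Union[RewiringTimes, Optional[int]]:
    """Smallest step at which the remaining credit reaches zero.

    For a :class:`RewiringTrajectory` the credit defaults to the partner-set
    degree and the result is a :class:`RewiringTimes` (per replicate, with
    min/median/max across replicates).  For a :class:`CreditLedger` the
    result is a single step index, or ``None`` if the credit is never fully
    cashed.
    """
    if isinstance(obj, CreditLedger):
        hit = np.flatnonzero(np.isclose(obj.remaining, 0.0))
        return int(hit[0]) if hit.size else None
    if obj.steps.size < 1:
        raise ValueError("trajectory has no steps")
    target = obj.degree if credit0 is None else int(credit0)
    times: list[Optional[int]] = []
    for row in obj.cumulative_richness:
        hit = np.flatnonzero(row >= target)
        times.append(int(obj.steps[hit[0]]) if hit.size else None)
    return RewiringTimes(times=tuple(times))
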