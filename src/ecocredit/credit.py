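"""Empirical credit accounting from reintroduction monitoring data.

The workflow mirrors how a monitoring study quantifies interaction
restoration after a reintroduction: the *credit of ecological interactions*
at release is the number of local plant species documented as partners of
the reintroduced animal (flora list ∩ diet reference); monitoring records of
animal–plant interactions then cash that credit one species at a time.  The
accumulation of first observations over months since release gives the
interaction-richness curve; its complement against the initial credit is the
remaining-credit ledger; and an asymptotic model fitted to the curve
extrapolates when a given fraction of the credit will be cashed.

Observed richness is a lower bound on true rewiring (interactions may occur
undetected), so curve values are minima; no detection-probability correction
is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .pools import canonicalize

__all__ = [
    "EVIDENCE_TYPES",
    "FloraList",
    "InteractionReference",
    "MonitoringLog",
    "AccumulationCurve",
    "CurveAudit",
    "CreditEstimate",
    "AsymptoticFit",
    "NoFit",
    "SuccessReport",
    "estimate_credit",
    "count_flagged",
    "accumulation_curve",
    "remaining_credit",
    "fit_accumulation",
    "success_assessment",
]

logger = logging.getLogger("ecocredit")

EVIDENCE_TYPES = ("fruit_consumption", "seed_burial", "other")


@dataclass(frozen=True)
class FloraList:
    """Plant species present in the focal area, with optional boolean flags.

    ``flags`` maps a flag name (e.g. ``large_seeded_reliant``) to the set of
    species for which it is true.
    """

    species_ids: frozenset[str]
    flags: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = frozenset(canonicalize(s) for s in self.species_ids)
        flags = {
            str(name): frozenset(canonicalize(s) for s in members)
            for name, members in self.flags.items()
        }
        for name, members in flags.items():
            extra = members - ids
            if extra:
                raise ValueError(
                    f"flag {name!r} set for species not in the flora: {sorted(extra)}"
                )
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(self, "flags", flags)

    def __len__(self) -> int:
        return len(self.species_ids)


@dataclass(frozen=True)
class InteractionReference:
    """Documented interaction partners (e.g. diet records) of one animal."""

    animal_id: str
    plant_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "animal_id", str(self.animal_id))
        object.__setattr__(
            self, "plant_ids", frozenset(canonicalize(s) for s in self.plant_ids)
        )


@dataclass(eq=False)
class MonitoringLog:
    """Time-stamped animal–plant interaction records from post-release monitoring.

    ``events`` holds columns ``time_months`` (non-negative, months since
    release), ``plant_id`` (canonicalized) and ``evidence`` (one of
    :data:`EVIDENCE_TYPES`), stably sorted by time.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.events, columns=["time_months", "plant_id", "evidence"])
        df["time_months"] = pd.to_numeric(df["time_months"], errors="raise").astype(float)
        if (df["time_months"] < 0).any() or not np.isfinite(df["time_months"]).all():
            raise ValueError("event times must be finite and >= 0 (months since release)")
        df["plant_id"] = df["plant_id"].map(canonicalize)
        bad = set(df["evidence"]) - set(EVIDENCE_TYPES)
        if bad:
            raise ValueError(
                f"unknown evidence type(s) {sorted(bad)}; expected one of {EVIDENCE_TYPES}"
            )
        self.events = df.sort_values("time_months", kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, str, str]]
    ) -> "MonitoringLog":
        return cls(
            pd.DataFrame(records, columns=["time_months", "plant_id", "evidence"])
        )

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class CreditEstimate:
    """Initial credit and the species eligible to cash it."""

    credit0: int
    eligible_species: frozenset[str]


@dataclass(frozen=True)
class CurveAudit:
    """Full accounting of monitoring events: nothing is silently dropped.

    ``eligible_first + eligible_repeat + unexpected + beyond_horizon +
    evidence_filtered == total_events``.
    """

    total_events: int
    eligible_first: int
    eligible_repeat: int
    unexpected: int
    beyond_horizon: int
    evidence_filtered: int = 0


@dataclass(eq=False)
class AccumulationCurve:
    """Cumulative distinct-species interaction richness per time bin."""

    bin_edges: np.ndarray  # length B + 1, months
    cumulative_richness: np.ndarray  # length B; integer counts from monitoring
    # data, but exact model-generated real values are accepted for fitting
    first_observations: dict[str, float]
    audit: CurveAudit

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative_richness = np.asarray(self.cumulative_richness)
        if self.bin_edges.size != self.cumulative_richness.size + 1:
            raise ValueError("bin_edges must be one longer than cumulative_richness")
        if np.any(self.cumulative_richness < 0):
            raise ValueError("cumulative richness must be non-negative")
        if np.any(np.diff(self.cumulative_richness) < 0):
            raise ValueError("cumulative richness must be non-decreasing")

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def bin_ends(self) -> np.ndarray:
        return self.bin_edges[1:]

    @property
    def max_richness(self) -> int:
        return int(self.cumulative_richness.max(initial=0))

    def richness_at(self, time_months: float) -> int:
        """Cumulative richness at the end of the bin containing ``time_months``."""
        idx = np.searchsorted(self.bin_ends, time_months)
        idx = min(int(idx), self.cumulative_richness.size - 1)
        return int(self.cumulative_richness[idx])

    def to_frame(self, credit0: Optional[int] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "cumulative_richness": self.cumulative_richness,
            }
        )
        if credit0 is not None:
            df["remaining_credit"] = remaining_credit(self, credit0)
        return df


def estimate_credit(
    flora: FloraList, reference: InteractionReference
) -> CreditEstimate:
    """Credit of ecological interactions cashable by this reintroduction.

    The credit is the number of plant species present in the focal area that
    are documented partners of the animal: ``|flora ∩ reference|``.  The
    intersection itself is returned for downstream eligibility filtering.
    An empty intersection is valid but actionable (little credit to cash, so
    reintroduction may not be the best first intervention); it is logged at
    warning level.
    """
    if len(flora) == 0:
        raise ValueError("flora list is empty; credit estimation needs a flora")
    eligible = flora.species_ids & reference.plant_ids
    if not eligible:
        logger.warning(
            "flora and interaction reference share no species: credit0 = 0 "
            "(animal %s)",
            reference.animal_id,
        )
    return CreditEstimate(credit0=len(eligible), eligible_species=frozenset(eligible))


def count_flagged(
    eligible_species: Iterable[str], flora: FloraList, flag: str
) -> int:
    """Number of eligible species carrying a boolean flag (e.g. large-seeded
    trees that rely on the animal for dispersal)."""
    if flag not in flora.flags:
        raise ValueError(
            f"unknown flag {flag!r}; flora defines {sorted(flora.flags) or 'no flags'}"
        )
    eligible = {canonicalize(s) for s in eligible_species}
    return len(eligible & flora.flags[flag])


def accumulation_curve(
    log: MonitoringLog,
    eligible_species: Iterable[str],
    *,
    bin_width: float = 1.0,
    horizon: Optional[float] = None,
    evidence: Optional[Sequence[str]] = None,
) -> AccumulationCurve:
    """Interaction-richness accumulation curve from a monitoring log.

    A species is rewired at its first observed interaction of any admitted
    evidence type; later records of the same species are repeats.  Events for
    species outside the eligible set are counted as *unexpected* interactions
    and reported in the audit, never silently dropped; likewise events beyond
    the horizon and events excluded by an evidence filter.

    Parameters
    ----------
    bin_width
        Bin width in months (default 1).
    horizon
        Last month covered by the curve; defaults to the latest event time
        rounded up to a whole bin.  Events strictly beyond it are dropped
        (and counted).
    evidence
        Optional subset of :data:`EVIDENCE_TYPES` to admit; default all.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    eligible = {canonicalize(s) for s in eligible_species}
    df = log.events
    total = len(df)

    if horizon is None:
        max_t = float(df["time_months"].max()) if total else 0.0
        n_bins = max(1, math.ceil(max_t / bin_width - 1e-12))
        horizon = n_bins * bin_width
    elif horizon <= 0:
        raise ValueError("horizon must be positive")
    else:
        n_bins = max(1, math.ceil(horizon / bin_width - 1e-12))

    within = df["time_months"] <= horizon
    n_beyond = int((~within).sum())
    df = df[within]

    if evidence is not None:
        admitted = set(evidence)
        bad = admitted - set(EVIDENCE_TYPES)
        if bad:
            raise ValueError(f"unknown evidence type(s) {sorted(bad)}")
        keep = df["evidence"].isin(admitted)
        n_filtered = int((~keep).sum())
        df = df[keep]
    else:
        n_filtered = 0

    is_eligible = df["plant_id"].isin(eligible)
    n_unexpected = int((~is_eligible).sum())
    elig = df[is_eligible]
    firsts = elig.groupby("plant_id")["time_months"].min()
    n_first = len(firsts)
    n_repeat = len(elig) - n_first

    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    # bin b covers (edge_b, edge_{b+1}]; an observation at exactly the horizon
    # falls in the last bin
    bin_idx = np.minimum(
        np.floor(firsts.to_numpy() / bin_width - 1e-12).astype(int).clip(min=0),
        n_bins - 1,
    )
    counts = np.bincount(bin_idx, minlength=n_bins) if n_first else np.zeros(n_bins, int)
    cumulative = np.cumsum(counts)

    audit = CurveAudit(
        total_events=total,
        eligible_first=n_first,
        eligible_repeat=n_repeat,
        unexpected=n_unexpected,
        beyond_horizon=n_beyond,
        evidence_filtered=n_filtered,
    )
    return AccumulationCurve(
        bin_edges=edges,
        cumulative_richness=cumulative,
        first_observations=dict(firsts),
        audit=audit,
    )


def remaining_credit(curve: AccumulationCurve, credit0: int) -> np.ndarray:
    """Per-bin remaining credit: ``credit0 - cumulative(t)``.

    Raises when the curve exceeds ``credit0`` — that signals an eligibility
    filter bug upstream, since the curve counts only eligible species.
    """
    if curve.max_richness > credit0:
        raise ValueError(
            f"curve reaches {curve.max_richness} species but credit0={credit0}; "
            "eligibility filtering is inconsistent"
        )
    return credit0 - curve.cumulative_richness


def _michaelis_menten(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * t / (b + t)


def _negative_exponential(t: np.ndarray, a: float, k: float) -> np.ndarray:
    return a * (1.0 - np.exp(-k * t))


_MODELS = {
    "michaelis_menten": _michaelis_menten,
    "negative_exponential": _negative_exponential,
}


@dataclass(frozen=True)
class NoFit:
    """Sentinel returned when an asymptotic fit is impossible or failed."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class AsymptoticFit:
    """A fitted asymptotic accumulation model.

    ``michaelis_menten`` (Clench): R(t) = a·t / (b + t), with half-saturation
    time b.  ``negative_exponential``: R(t) = a·(1 − e^(−k·t)).  Both are
    non-decreasing on t ≥ 0 with asymptote a, used for descriptive
    extrapolation of rewiring progress, not inference.
    """

    model: str
    asymptote: float
    rate_or_halfsat: float
    residual_sse: float

    def predict(self, t: Union[float, np.ndarray]) -> np.ndarray:
        return _MODELS[self.model](np.asarray(t, dtype=float), self.asymptote, self.rate_or_halfsat)

    def time_to_fraction(self, q: float) -> Optional[float]:
        """Time at which the fitted curve reaches fraction ``q`` of its asymptote.

        Both models approach the asymptote only in the limit, so ``q = 1``
        returns ``None`` (the asymptote is never attained at finite time).
        """
        if not 0 < q <= 1:
            raise ValueError("q must lie in (0, 1]")
        if q == 1:
            return None
        if self.model == "michaelis_menten":
            return self.rate_or_halfsat * q / (1.0 - q)
        return -math.log(1.0 - q) / self.rate_or_halfsat


def fit_accumulation(
    curve: AccumulationCurve, model: str = "michaelis_menten"
) -> Union[AsymptoticFit, NoFit]:
    """Least-squares fit of an asymptotic model to the accumulation curve.

    Fits cumulative richness against bin midpoints with both parameters
    bounded positive.  Initial values: asymptote at the observed maximum,
    time scale at the half-richness time.  Returns a :class:`NoFit` sentinel
    (never raises) for degenerate curves or non-convergence.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODELS)}")
    t = curve.bin_midpoints
    y = curve.cumulative_richness.astype(float)
    if int((y > 0).sum()) < 3:
        return NoFit(reason="need at least 3 non-zero bins to fit an asymptote")
    if np.ptp(y) == 0:
        return NoFit(reason="curve is constant; asymptote is unidentifiable")
    a0 = float(y.max())
    half_idx = int(np.argmax(y >= a0 / 2.0))
    b0 = float(t[half_idx]) if t[half_idx] > 0 else float(np.median(t))
    p0 = (a0, b0) if model == "michaelis_menten" else (a0, math.log(2.0) / b0)
    bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    try:
        popt, _ = curve_fit(
            _MODELS[model], t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        return NoFit(
            reason=f"fit did not converge ({exc}); initial values {p0}, "
            f"bounds positive"
        )
    resid = y - _MODELS[model](t, *popt)
    return AsymptoticFit(
        model=model,
        asymptote=float(popt[0]),
        rate_or_halfsat=float(popt[1]),
        residual_sse=float(np.dot(resid, resid)),
    )


@dataclass(frozen=True)
class SuccessReport:
    """Outcome of the a-priori success criterion.

    ``achieved`` is ``None`` when the assessment is undefined (zero credit:
    nothing to cash, so the criterion does not apply).  ``time_achieved`` is
    the end of the first bin meeting the threshold, or ``None`` ("not yet").
    """

    achieved: Optional[bool]
    proportion_cashed: Optional[float]
    time_achieved: Optional[float]
    threshold: int
    note: str = ""


def success_assessment(
    curve: AccumulationCurve, credit0: int, proportion: float
) -> SuccessReport:
    """Assess reintroduction success against an a-priori cashed-credit proportion.

    The reintroduction is successful when the observed cumulative richness
    reaches ``proportion × credit0``; fractional thresholds round up
    (ceiling), since richness is integer.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    if credit0 < 0:
        raise ValueError("credit0 must be non-negative")
    if credit0 == 0:
        return SuccessReport(
            achieved=None,
            proportion_cashed=None,
            time_achieved=None,
            threshold=0,
            note="assessment undefined: credit0 is zero (nothing to cash)",
        )
    threshold = math.ceil(proportion * credit0 - 1e-9)
    max_cum = curve.max_richness
    achieved = max_cum >= threshold
    hit = np.flatnonzero(curve.cumulative_richness >= threshold)
    time_achieved = float(curve.bin_ends[hit[0]]) if hit.size else None
    return SuccessReport(
        achieved=achieved,
        proportion_cashed=max_cum / credit0,
        time_achieved=time_achieved,
        threshold=threshold,
    )
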