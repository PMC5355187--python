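"""Packaged toy fixture for documentation and tests.

A fully synthetic (constructed, not field-collected) 12-species dataset
shaped like an agouti-reintroduction monitoring study: a focal-area flora
with a large-seeded flag, a one-animal diet reference, and a 15-month
monitoring log.  Its ground truth is documented in :data:`TOY_TRUTH` so the
whole empirical pipeline can be demonstrated and tested without downloads.

A real flora/diet table supplied by the user in the same schemas runs
through the identical code path.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path
from types import MappingProxyType

__all__ = ["toy_flora_path", "toy_diet_path", "toy_monitoring_path", "TOY_TRUTH"]

_DATA = files("ecocredit") / "data"

#: Documented ground truth of the toy fixture (verifiable by hand from the
#: three CSVs): 12 flora species and 10 diet species share 8 (the credit);
#: 5 of the 8 are flagged large-seeded; the log holds 10 events of which 7
#: are eligible first observations (ficus insipida is never observed, so one
#: credit remains), 2 are repeats and 1 is an unexpected interaction.
TOY_TRUTH = MappingProxyType(
    {
        "credit0": 8,
        "flagged_eligible": 5,
        "richness_month_15": 7,
        "remaining_month_15": 1,
        "total_events": 10,
        "eligible_first": 7,
        "eligible_repeat": 2,
        "unexpected": 1,
        "never_observed": "ficus insipida",
    }
)


def toy_flora_path() -> Path:
    return Path(str(_DATA / "toy_synthetic_flora.csv"))


def toy_diet_path() -> Path:
    return Path(str(_DATA / "toy_synthetic_diet.csv"))


def toy_monitoring_path() -> Path:
    return Path(str(_DATA / "toy_synthetic_monitoring.csv"))
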