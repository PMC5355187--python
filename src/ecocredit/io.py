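"""Reading, validating and writing the package's delimited-text schemas.

All files are header-rowed delimited text (comma by default, configurable
for semicolon-delimited ecological datasets), UTF-8, with ``#`` comment
lines permitted (output files carry a provenance comment header).  Species
identifiers are canonicalized on ingestion; duplicate species rows are
collapsed with a logged count; malformed rows are reported with their line
numbers.

Schemas
-------
flora
    ``species_id[,large_seeded_reliant]`` (boolean flag column optional;
    additional boolean flag columns are accepted and exposed as flags).
interaction reference
    ``animal_id,plant_id[,source]``.
monitoring log
    ``time_months,plant_id,evidence``; times are decimal months since
    release (no date parsing — unit conversion is the caller's job).
species pool
    ``species_id,occupancy_weight``.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .credit import (
    EVIDENCE_TYPES,
    AccumulationCurve,
    CurveAudit,
    FloraList,
    InteractionReference,
    MonitoringLog,
)
from .pools import SpeciesPool, canonicalize
from .simulator import RewiringTrajectory, summarize_trajectory

__all__ = [
    "SchemaError",
    "read_table",
    "read_flora",
    "read_reference",
    "read_monitoring",
    "read_curve",
    "read_pool",
    "write_pool",
    "write_trajectory",
    "write_trajectory_summary",
    "write_curve",
    "provenance_header",
]

logger = logging.getLogger("ecocredit")

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


class SchemaError(ValueError):
    """A file failed schema validation; ``errors`` lists (line, message)."""

    def __init__(self, path: Union[str, Path], errors: Sequence[tuple[int, str]]):
        self.path = str(path)
        self.errors = list(errors)
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{self.path}: {detail}{more}")


def _parse_bool(raw: str) -> bool:
    v = raw.strip().casefold()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"unparsable boolean {raw!r}")


def read_table(
    path: Union[str, Path],
    required: Sequence[str],
    optional: Sequence[str] = (),
    delimiter: str = ",",
) -> tuple[list[dict[str, str]], list[str]]:
    """Read a delimited text table with header, skipping ``#`` comment lines.

    Returns the rows as dicts keyed by header name, plus the list of header
    columns actually present.  Raises :class:`SchemaError` on a missing file,
    empty file, missing required column, or short rows.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(path, [(0, "file does not exist")])
    rows: list[dict[str, str]] = []
    errors: list[tuple[int, str]] = []
    header: Optional[list[str]] = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for line_no, raw in enumerate(reader, start=1):
            if not raw or (raw[0].lstrip().startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                missing = [c for c in required if c not in header]
                if missing:
                    raise SchemaError(
                        path, [(line_no, f"missing required column(s) {missing}")]
                    )
                continue
            if len(raw) < len(header):
                errors.append((line_no, f"expected {len(header)} fields, got {len(raw)}"))
                continue
            rows.append({h: v.strip() for h, v in zip(header, raw)})
    if header is None:
        raise SchemaError(path, [(0, "empty file (no header row)")])
    if errors:
        raise SchemaError(path, errors)
    return rows, header


def read_flora(path: Union[str, Path], delimiter: str = ",") -> FloraList:
    """Read a flora list; any non-``species_id`` column is a boolean flag."""
    rows, header = read_table(path, required=["species_id"], delimiter=delimiter)
    flag_cols = [c for c in header if c != "species_id"]
    species: dict[str, dict[str, bool]] = {}
    errors: list[tuple[int, str]] = []
    duplicates = 0
    for i, row in enumerate(rows):
        sid = canonicalize(row["species_id"])
        if not sid:
            errors.append((i + 2, "empty species_id"))
            continue
        flags = {}
        for col in flag_cols:
            try:
                flags[col] = _parse_bool(row.get(col, ""))
            except ValueError as exc:
                errors.append((i + 2, f"column {col!r}: {exc}"))
        if sid in species:
            duplicates += 1
            for col, val in flags.items():
                species[sid][col] = species[sid].get(col, False) or val
        else:
            species[sid] = flags
    if errors:
        raise SchemaError(path, errors)
    if duplicates:
        logger.warning("%s: collapsed %d duplicate species row(s)", path, duplicates)
    return FloraList(
        species_ids=frozenset(species),
        flags={
            col: frozenset(s for s, f in species.items() if f.get(col, False))
            for col in flag_cols
        },
    )


def read_reference(
    path: Union[str, Path],
    animal_id: Optional[str] = None,
    delimiter: str = ",",
) -> InteractionReference:
    """Read a diet/interaction reference list for one animal.

    When the file lists several animals, ``animal_id`` selects one; with a
    single animal it may be omitted.
    """
    rows, _ = read_table(path, required=["animal_id", "plant_id"], delimiter=delimiter)
    if not rows:
        raise SchemaError(path, [(0, "no data rows")])
    animals = {canonicalize(r["animal_id"]) for r in rows}
    if animal_id is None:
        if len(animals) > 1:
            raise ValueError(
                f"{path}: multiple animals {sorted(animals)}; pass animal_id to select one"
            )
        chosen = next(iter(animals))
    else:
        chosen = canonicalize(animal_id)
        if chosen not in animals:
            raise ValueError(f"{path}: animal {animal_id!r} not found in {sorted(animals)}")
    plants = {
        canonicalize(r["plant_id"])
        for r in rows
        if canonicalize(r["animal_id"]) == chosen and canonicalize(r["plant_id"])
    }
    n_rows = sum(1 for r in rows if canonicalize(r["animal_id"]) == chosen)
    if n_rows > len(plants):
        logger.warning(
            "%s: collapsed %d duplicate plant row(s)", path, n_rows - len(plants)
        )
    return InteractionReference(animal_id=chosen, plant_ids=frozenset(plants))


def read_monitoring(path: Union[str, Path], delimiter: str = ",") -> MonitoringLog:
    """Read a monitoring event log (time_months, plant_id, evidence)."""
    rows, _ = read_table(
        path, required=["time_months", "plant_id", "evidence"], delimiter=delimiter
    )
    records: list[tuple[float, str, str]] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(rows):
        line = i + 2
        try:
            t = float(row["time_months"])
        except ValueError:
            errors.append((line, f"unparsable time_months {row['time_months']!r}"))
            continue
        if t < 0:
            errors.append((line, f"negative time_months {t}"))
            continue
        ev = row["evidence"].strip().casefold()
        if ev not in EVIDENCE_TYPES:
            errors.append(
                (line, f"unknown evidence {row['evidence']!r}; expected {EVIDENCE_TYPES}")
            )
            continue
        sid = canonicalize(row["plant_id"])
        if not sid:
            errors.append((line, "empty plant_id"))
            continue
        records.append((t, sid, ev))
    if errors:
        raise SchemaError(path, errors)
    return MonitoringLog.from_records(records)


def read_curve(path: Union[str, Path], delimiter: str = ",") -> AccumulationCurve:
    """Read back an accumulation-curve table written by :func:`write_curve`.

    First-observation detail and the event audit are not stored in the table,
    so the returned curve carries an empty audit; it is sufficient for
    fitting and success assessment.
    """
    rows, _ = read_table(
        path,
        required=["bin_start", "bin_end", "cumulative_richness"],
        delimiter=delimiter,
    )
    if not rows:
        raise SchemaError(path, [(0, "no data rows")])
    errors: list[tuple[int, str]] = []
    starts, ends, cum = [], [], []
    for i, row in enumerate(rows):
        try:
            starts.append(float(row["bin_start"]))
            ends.append(float(row["bin_end"]))
            cum.append(int(float(row["cumulative_richness"])))
        except ValueError as exc:
            errors.append((i + 2, str(exc)))
    if errors:
        raise SchemaError(path, errors)
    edges = np.array(starts + [ends[-1]])
    audit = CurveAudit(
        total_events=0,
        eligible_first=max(cum) if cum else 0,
        eligible_repeat=0,
        unexpected=0,
        beyond_horizon=0,
    )
    return AccumulationCurve(
        bin_edges=edges,
        cumulative_richness=np.array(cum),
        first_observations={},
        audit=audit,
    )


def read_pool(path: Union[str, Path], delimiter: str = ",") -> SpeciesPool:
    """Read a species pool (species_id, occupancy_weight)."""
    rows, _ = read_table(
        path, required=["species_id", "occupancy_weight"], delimiter=delimiter
    )
    ids: list[str] = []
    weights: list[float] = []
    errors: list[tuple[int, str]] = []
    seen: set[str] = set()
    duplicates = 0
    for i, row in enumerate(rows):
        line = i + 2
        sid = canonicalize(row["species_id"])
        if sid in seen:
            duplicates += 1
            continue
        try:
            w = float(row["occupancy_weight"])
        except ValueError:
            errors.append((line, f"unparsable occupancy_weight {row['occupancy_weight']!r}"))
            continue
        if not 0 < w <= 1:
            errors.append((line, f"occupancy_weight {w} outside (0, 1]"))
            continue
        seen.add(sid)
        ids.append(sid)
        weights.append(w)
    if errors:
        raise SchemaError(path, errors)
    if duplicates:
        logger.warning("%s: collapsed %d duplicate species row(s)", path, duplicates)
    return SpeciesPool(species_ids=tuple(ids), occupancy_weights=np.array(weights))


def provenance_header(seed: Optional[int], config: Mapping[str, object]) -> str:
    """Comment lines recording version, seed and a config hash for outputs."""
    digest = hashlib.sha256(
        json.dumps({k: str(v) for k, v in sorted(config.items())}).encode()
    ).hexdigest()[:12]
    return (
        f"# ecocredit {__version__}\n"
        f"# seed={seed}\n"
        f"# config_sha256={digest}\n"
    )


def _write_frame(df: pd.DataFrame, path: Union[str, Path], header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, index=False)


def write_pool(
    pool: SpeciesPool, path: Union[str, Path], header: str = ""
) -> None:
    _write_frame(
        pd.DataFrame(
            {"species_id": pool.species_ids, "occupancy_weight": pool.occupancy_weights}
        ),
        path,
        header,
    )


def write_trajectory(
    traj: RewiringTrajectory, path: Union[str, Path], header: str = ""
) -> None:
    """Long-format trajectory file (replicate, step, cumulative_richness)."""
    _write_frame(traj.to_frame(), path, header)


def write_trajectory_summary(
    traj: RewiringTrajectory,
    credit0: int,
    path: Union[str, Path],
    header: str = "",
) -> None:
    """Per-step summary (step, mean, min, max, remaining_credit_mean)."""
    df = summarize_trajectory(traj)
    df["remaining_credit_mean"] = credit0 - df["mean"]
    _write_frame(df, path, header)


def write_curve(
    curve: AccumulationCurve,
    credit0: Optional[int],
    path: Union[str, Path],
    header: str = "",
) -> None:
    """Accumulation-curve table with remaining credit when credit0 is given."""
    _write_frame(curve.to_frame(credit0=credit0), path, header)
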