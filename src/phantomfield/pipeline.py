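"""Voltage-to-field pipeline for phantom depth recordings.

Given a set of voltage differences dV (mV) measured at every
(electrode, depth) site against a pad-mounted reference, the pipeline:

1. imputes the sites hidden under the stimulating pads (not recordable)
   as the arithmetic mean of the surrounding electrodes' dV at the same
   depth;
2. estimates the field magnitude at each site as EF = dV / distance,
   with the distance taken from the spherical montage geometry; and
3. summarises per-depth extremes and hemispheric means.

The one geometric degeneracy is the reference electrode's own surface
site: its distance is zero, so dV / distance is undefined and the EF
there is instead imputed as the mean of the neighbouring electrodes'
surface EF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    ELECTRODES,
    LEFT_ELECTRODES,
    MIDLINE_ELECTRODES,
    RIGHT_ELECTRODES,
    DepthLevel,
    MontageLayout,
    recording_grid,
)

__all__ = [
    "PhantomMetadata",
    "VoltageRecordingSet",
    "ImputationRule",
    "CONDITION_A_NEIGHBORS",
    "default_neighbors",
    "UndefinedFieldError",
    "compute_ef",
    "impute_pad_voltages",
    "impute_reference_surface",
    "build_field_table",
    "summarize",
    "FIELD_TABLE_COLUMNS",
]

#: Column contract of the field table (and its CSV export).
FIELD_TABLE_COLUMNS = (
    "electrode", "depth", "x_mm", "y_mm", "z_mm",
    "distance_mm", "delta_v_mV", "imputed", "ef_mV_per_mm",
)

#: ``imputed`` column vocabulary.
MEASURED, DV_MEAN, EF_MEAN, PLACEHOLDER = "measured", "dv_mean", "ef_mean", "placeholder"


@dataclass(frozen=True)
class PhantomMetadata:
    """Physical descriptors of one phantom session (not used numerically
    except for the diameter, which must match the montage sphere)."""

    diameter_mm: float
    weight_kg: float | None = None
    temperature_C: float | None = None
    resistance_kohm: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")


class RecordingValidationError(ValueError):
    """Raised with the complete list of violations found in a recording set."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            f"{len(self.violations)} recording-set violation(s):\n  - "
            + "\n  - ".join(self.violations)
        )


@dataclass(frozen=True)
class VoltageRecordingSet:
    """Measured (or simulated) voltage differences for one condition.

    ``delta_v`` maps every (electrode, depth) pair to a dV in mV, or to
    ``None`` for the not-recordable sites under the stimulating pads.
    ``imputed`` marks the pairs whose value was filled in afterwards.
    """

    condition: str
    reference: str
    pads: tuple[str, ...]
    delta_v: Mapping[tuple[str, DepthLevel], float | None]
    metadata: PhantomMetadata
    imputed: frozenset[tuple[str, DepthLevel]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        violations: list[str] = []
        expected = {(e, d) for e in ELECTRODES for d in DepthLevel}
        keys = set(self.delta_v)
        for e, d in sorted(expected - keys, key=lambda k: (ELECTRODES.index(k[0]), k[1])):
            violations.append(f"missing entry ({e}, {d.name})")
        for e, d in sorted(keys - expected, key=str):
            violations.append(f"unexpected entry ({e}, {getattr(d, 'name', d)})")
        for pad in self.pads:
            if pad not in ELECTRODES:
                violations.append(f"unknown pad electrode {pad!r}")
        if self.reference not in ELECTRODES:
            violations.append(f"unknown reference electrode {self.reference!r}")
        pads = set(self.pads)
        for (e, d), v in self.delta_v.items():
            if e not in ELECTRODES:
                continue  # already reported
            if v is None:
                if e not in pads and (e, d) not in self.imputed:
                    violations.append(f"non-pad electrode {e} has no dV at {d.name}")
            else:
                if not math.isfinite(v):
                    violations.append(f"dV at ({e}, {d.name}) is not finite: {v}")
                elif v < 0:
                    violations.append(f"dV at ({e}, {d.name}) is negative: {v}")
                if e in pads and (e, d) not in self.imputed:
                    violations.append(
                        f"pad electrode {e} carries a measured dV at {d.name} "
                        "(pad sites are not recordable)")
        if violations:
            raise RecordingValidationError(violations)

    def value(self, electrode: str, depth: DepthLevel) -> float | None:
        return self.delta_v[(electrode, DepthLevel(depth))]


#: Imputation rule: pad electrode -> ordered tuple of neighbour labels.
ImputationRule = Mapping[str, tuple[str, ...]]

#: Neighbour sets for the motor-cortex pads of the monopolar montage:
#: the five adjacent same-hemisphere electrodes, midline excluded.
CONDITION_A_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "C3": ("F7", "F3", "T3", "P3", "T5"),
    "C4": ("F8", "F4", "T4", "P4", "T6"),
}


def default_neighbors(
    pads: Sequence[str], layout: MontageLayout, k: int = 5
) -> dict[str, tuple[str, ...]]:
    """Derive a surrounding-electrode set for each pad.

    For a lateral pad the neighbours are its ``k`` nearest recordable
    electrodes on the same hemisphere (midline excluded); for a midline
    pad, simply the ``k`` nearest recordable electrodes.  For the
    monopolar motor-cortex pads this reproduces ``CONDITION_A_NEIGHBORS``.
    """
    pads = tuple(pads)
    positions = layout.positions()
    rule: dict[str, tuple[str, ...]] = {}
    for pad in pads:
        if pad not in positions:
            raise KeyError(f"pad electrode {pad!r} not in layout")
        if pad in MIDLINE_ELECTRODES:
            pool = [e for e in layout.labels if e not in pads]
        else:
            side = LEFT_ELECTRODES if pad in LEFT_ELECTRODES else RIGHT_ELECTRODES
            pool = [e for e in layout.labels if e not in pads and e in side]
        pool.sort(key=lambda e: float(np.linalg.norm(positions[e] - positions[pad])))
        if not pool:
            raise ValueError(f"no recordable neighbours available for pad {pad!r}")
        rule[pad] = tuple(sorted(pool[:k], key=ELECTRODES.index))
    return rule


class UndefinedFieldError(ZeroDivisionError):
    """EF = dV / distance is undefined at zero distance (the reference's
    own surface site); the caller must impute instead."""


def compute_ef(delta_v: float, distance: float) -> float:
    """Field-magnitude estimate EF = dV / distance (mV/mm)."""
    if distance == 0:
        raise UndefinedFieldError(
            "distance is zero (reference surface site); EF must be imputed "
            "from neighbouring electrodes")
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    if delta_v < 0:
        raise ValueError(f"delta_v must be >= 0, got {delta_v}")
    return delta_v / distance


def _check_rule(recordings: VoltageRecordingSet, rule: ImputationRule) -> None:
    pads = set(recordings.pads)
    for pad in pads:
        if pad not in rule:
            raise KeyError(f"no neighbour set for pad electrode {pad!r}")
        neighbors = rule[pad]
        if not neighbors:
            raise ValueError(f"empty neighbour set for pad electrode {pad!r}")
        for nb in neighbors:
            if nb in pads:
                raise ValueError(
                    f"neighbour {nb!r} of pad {pad!r} is itself a pad electrode")


def impute_pad_voltages(
    recordings: VoltageRecordingSet, rule: ImputationRule
) -> VoltageRecordingSet:
    """Fill each pad's dV with the mean of its neighbours', per depth.

    Measured values pass through unchanged; the filled pairs are flagged
    in ``imputed``.
    """
    _check_rule(recordings, rule)
    new_dv = dict(recordings.delta_v)
    imputed = set(recordings.imputed)
    for pad in recordings.pads:
        for depth in DepthLevel:
            vals = []
            for nb in rule[pad]:
                v = recordings.delta_v.get((nb, depth))
                if v is None:
                    raise ValueError(
                        f"cannot impute pad {pad} at {depth.name}: neighbour "
                        f"{nb} has no measured dV at {depth.name}")
                vals.append(v)
            new_dv[(pad, depth)] = float(np.mean(vals))
            imputed.add((pad, depth))
    return replace(recordings, delta_v=new_dv, imputed=frozenset(imputed))


def impute_reference_surface(
    partial_table: pd.DataFrame, electrode: str, rule: ImputationRule
) -> float:
    """Surface EF at a zero-distance site: mean of the neighbours' surface EF.

    ``partial_table`` must already hold the neighbours' ``Z0`` rows with
    their ``ef_mV_per_mm`` computed.
    """
    neighbors = rule.get(electrode)
    if not neighbors:
        raise ValueError(f"empty neighbour set for electrode {electrode!r}")
    surf = partial_table[(partial_table["depth"] == "Z0")
                         & (partial_table["electrode"].isin(neighbors))]
    efs = surf["ef_mV_per_mm"].to_numpy(dtype=float)
    if len(efs) != len(neighbors) or np.isnan(efs).any():
        missing = set(neighbors) - set(surf["electrode"])
        raise ValueError(
            f"cannot impute surface EF at {electrode}: neighbour surface EF "
            f"unavailable ({sorted(missing) or 'NaN values'})")
    return float(np.mean(efs))


def build_field_table(
    recordings: VoltageRecordingSet,
    layout: MontageLayout,
    rule: ImputationRule | None = None,
    projection: str = "mirror",
    strict_pad_surface: bool = False,
) -> pd.DataFrame:
    """Full field table: coordinates, distances, dV and EF for all 84 sites.

    A pure function of its inputs.  Pad dVs are imputed with ``rule``
    (default: nearest same-hemisphere neighbours, which for the motor
    pads is the published five-electrode set).  Sites at zero distance
    from the reference get their EF imputed as the neighbours' surface-EF
    mean and carry ``imputed = "ef_mean"``.

    ``strict_pad_surface`` reproduces a published-table quirk: the surface
    EF of non-reference pads is written as 0.0 (flagged ``placeholder``)
    instead of dV / distance.
    """
    if set(layout.labels) != set(ELECTRODES):
        raise ValueError("layout labels do not match the 21-electrode montage")
    if abs(layout.sphere.diameter - recordings.metadata.diameter_mm) > 0.1:
        raise ValueError(
            f"metadata diameter {recordings.metadata.diameter_mm} mm does not "
            f"match layout sphere diameter {layout.sphere.diameter} mm")
    if rule is None:
        rule = {**default_neighbors(recordings.pads, layout),
                **{k: v for k, v in CONDITION_A_NEIGHBORS.items()
                   if k in recordings.pads}}
    full = impute_pad_voltages(recordings, rule)

    points = recording_grid(layout, recordings.reference, projection=projection)
    rows: list[dict] = []
    for p in points:
        dv = full.value(p.electrode, p.depth)
        flag = DV_MEAN if (p.electrode, p.depth) in full.imputed else MEASURED
        rows.append({
            "electrode": p.electrode, "depth": p.depth.name,
            "x_mm": p.position[0], "y_mm": p.position[1], "z_mm": p.position[2],
            "distance_mm": p.distance, "delta_v_mV": dv, "imputed": flag,
            "ef_mV_per_mm": np.nan,
        })
    table = pd.DataFrame(rows, columns=list(FIELD_TABLE_COLUMNS))

    # EF wherever the division is defined
    ok = table["distance_mm"] > 0
    table.loc[ok, "ef_mV_per_mm"] = (
        table.loc[ok, "delta_v_mV"].astype(float) / table.loc[ok, "distance_mm"])

    # zero-distance sites: impute EF from the neighbours' surface EF
    for idx in table.index[~ok]:
        elec = table.at[idx, "electrode"]
        table.at[idx, "ef_mV_per_mm"] = impute_reference_surface(table, elec, rule)
        table.at[idx, "imputed"] = EF_MEAN
        table.at[idx, "delta_v_mV"] = np.nan

    if strict_pad_surface:
        mask = (table["electrode"].isin(set(recordings.pads) - {recordings.reference})
                & (table["depth"] == "Z0"))
        table.loc[mask, "ef_mV_per_mm"] = 0.0
        table.loc[mask, "imputed"] = PLACEHOLDER

    table.attrs.update({
        "condition": recordings.condition,
        "reference": recordings.reference,
        "pads": list(recordings.pads),
        "diameter_mm": recordings.metadata.diameter_mm,
        "projection": projection,
    })
    return table


def _hemisphere(electrode: str) -> str:
    if electrode in LEFT_ELECTRODES:
        return "left"
    if electrode in RIGHT_ELECTRODES:
        return "right"
    return "midline"


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-depth extremes and means of dV and EF.

    Returns one row per (depth, quantity) with min/argmin, max/argmax,
    mean, and left/right hemispheric means (midline excluded from the
    hemispheric means).  NaN entries (e.g. the reference's surface dV)
    are ignored.
    """
    out: list[dict] = []
    hemi = table["electrode"].map(_hemisphere)
    for depth in [d.name for d in DepthLevel]:
        sub = table[table["depth"] == depth]
        sub_h = hemi[sub.index]
        for quantity, col in (("delta_v_mV", "delta_v_mV"),
                              ("ef_mV_per_mm", "ef_mV_per_mm")):
            vals = sub[col].astype(float)
            valid = vals.notna()
            v = vals[valid]
            e = sub.loc[valid, "electrode"]
            out.append({
                "depth": depth,
                "quantity": quantity,
                "min": float(v.min()),
                "argmin": e.iloc[int(np.argmin(v.to_numpy()))],
                "max": float(v.max()),
                "argmax": e.iloc[int(np.argmax(v.to_numpy()))],
                "mean": float(v.mean()),
                "left_mean": float(v[sub_h[valid] == "left"].mean()),
                "right_mean": float(v[sub_h[valid] == "right"].mean()),
            })
    return pd.DataFrame(out)
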