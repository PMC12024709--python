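"""Reading, writing and validation of recordings and field tables.

Recordings travel as a CSV (``electrode,depth,delta_v_mV``, with ``NR``
marking the not-recordable sites under stimulating pads) plus a JSON
metadata sidecar (condition, reference, pads, phantom descriptors).
Field tables are exported with values rounded to two decimals;
comparisons should always use the in-memory, unrounded table.

A measured monopolar-montage recording set (21 electrodes x 4 depths,
240.80 mm phantom, reference C3, pads C3/C4) is bundled with the
package and loadable with :func:`load_condition_a_fixture`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .geometry import ELECTRODES, DepthLevel
from .pipeline import (
    PhantomMetadata,
    RecordingValidationError,
    VoltageRecordingSet,
)

__all__ = [
    "NR",
    "load_recordings",
    "write_recordings",
    "write_field_table",
    "write_summary",
    "load_neighbor_rule",
    "load_condition_a_fixture",
]

#: Not-recordable marker in recordings CSVs.
NR = "NR"

_META_REQUIRED = ("condition", "reference", "pads", "diameter_mm")


def _read_meta(meta_path: str | Path) -> dict:
    with open(meta_path) as fh:
        meta = json.load(fh)
    missing = [k for k in _META_REQUIRED if k not in meta]
    if missing:
        raise RecordingValidationError(
            [f"metadata missing required key {k!r}" for k in missing])
    return meta


def load_recordings(csv_path: str | Path, meta_path: str | Path) -> VoltageRecordingSet:
    """Load and validate a recordings CSV + metadata JSON.

    Every violation found (duplicates, unknown labels, negative or
    missing values, pad/marker mismatches) is reported at once in the
    raised :class:`RecordingValidationError`.
    """
    meta = _read_meta(meta_path)
    try:
        df = pd.read_csv(csv_path, dtype=str)
    except pd.errors.EmptyDataError:
        raise RecordingValidationError(
            [f"recordings file {csv_path} is empty (zero rows)"]) from None
    violations: list[str] = []
    for colname in ("electrode", "depth", "delta_v_mV"):
        if colname not in df.columns:
            violations.append(f"missing column {colname!r}")
    if violations:
        raise RecordingValidationError(violations)
    if len(df) == 0:
        raise RecordingValidationError(["recordings file has zero rows"])

    pads = tuple(meta["pads"])
    delta_v: dict[tuple[str, DepthLevel], float | None] = {}
    seen: set[tuple[str, DepthLevel]] = set()
    for i, row in df.iterrows():
        label = str(row["electrode"]).strip()
        if label not in ELECTRODES:
            violations.append(f"row {i + 2}: unknown electrode label {label!r}")
            continue
        try:
            depth = DepthLevel.parse(row["depth"])
        except ValueError:
            violations.append(f"row {i + 2}: unknown depth {row['depth']!r}")
            continue
        key = (label, depth)
        if key in seen:
            violations.append(f"row {i + 2}: duplicate entry ({label}, {depth.name})")
            continue
        seen.add(key)
        raw = str(row["delta_v_mV"]).strip()
        if raw.upper() in (NR, "N.R.", "NAN", ""):
            delta_v[key] = None
        else:
            try:
                value = float(raw.replace(",", ""))
            except ValueError:
                violations.append(
                    f"row {i + 2}: dV at ({label}, {depth.name}) is not numeric: {raw!r}")
                continue
            if not math.isfinite(value):
                violations.append(
                    f"row {i + 2}: dV at ({label}, {depth.name}) is not finite")
                continue
            if value < 0:
                violations.append(
                    f"row {i + 2}: dV at ({label}, {depth.name}) is negative: {value}")
                continue
            delta_v[key] = value

    for e in ELECTRODES:
        for d in DepthLevel:
            if (e, d) not in seen:
                violations.append(f"missing entry ({e}, {d.name})")
    if violations:
        raise RecordingValidationError(violations)

    metadata = PhantomMetadata(
        diameter_mm=float(meta["diameter_mm"]),
        weight_kg=meta.get("weight_kg"),
        temperature_C=meta.get("temperature_C"),
        resistance_kohm=meta.get("resistance_kohm"),
    )
    return VoltageRecordingSet(
        condition=str(meta["condition"]),
        reference=str(meta["reference"]),
        pads=pads,
        delta_v=delta_v,
        metadata=metadata,
    )


def write_recordings(
    recordings: VoltageRecordingSet, csv_path: str | Path, meta_path: str | Path
) -> None:
    """Write a recording set to the CSV + JSON pair read by ``load_recordings``."""
    rows = []
    for e in ELECTRODES:
        for d in DepthLevel:
            v = recordings.delta_v[(e, d)]
            rows.append({
                "electrode": e, "depth": d.name,
                "delta_v_mV": NR if v is None else f"{v:.6g}",
            })
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    meta = {
        "condition": recordings.condition,
        "reference": recordings.reference,
        "pads": list(recordings.pads),
        **asdict(recordings.metadata),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def write_field_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Export a field table CSV, numeric columns rounded to 2 decimals."""
    out = table.copy()
    for c in ("x_mm", "y_mm", "z_mm", "distance_mm", "delta_v_mV", "ef_mV_per_mm"):
        out[c] = out[c].round(2)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def write_summary(summary: pd.DataFrame, path: str | Path) -> Path:
    """Export a summary table as JSON records."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(summary.to_json(orient="records", indent=2) + "\n")
    return path


def load_neighbor_rule(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Load a pad -> neighbour-list override from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    rule = {}
    for pad, neighbors in raw.items():
        if pad not in ELECTRODES:
            raise ValueError(f"unknown pad electrode {pad!r} in neighbour rule")
        for nb in neighbors:
            if nb not in ELECTRODES:
                raise ValueError(f"unknown neighbour {nb!r} for pad {pad!r}")
        rule[pad] = tuple(neighbors)
    return rule


def load_condition_a_fixture() -> VoltageRecordingSet:
    """The bundled measured monopolar-montage (Condition A) recording set."""
    data = resources.files("phantomfield.data")
    with resources.as_file(data / "condition_a_recordings.csv") as csv_path, \
            resources.as_file(data / "condition_a_meta.json") as meta_path:
        return load_recordings(csv_path, meta_path)


# ---------------------------------------------------------------------------
# Run orchestration


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Either ``recordings_csv``/``meta_json`` point at measured data, or
    ``condition`` selects a simulator preset (A/B/C).  ``neighbors_json``
    optionally overrides the pad-imputation neighbour sets.
    """

    out_dir: str | Path
    recordings_csv: str | Path | None = None
    meta_json: str | Path | None = None
    condition: str | None = None
    diameter_mm: float = 240.80
    seed: int | None = None
    noise_cv: float = 0.05
    sigma_S_per_m: float = 0.5
    neighbors_json: str | Path | None = None
    projection: str = "mirror"
    strict_pad_surface: bool = False
    make_plots: bool = False
    verbose: bool = False

    def __post_init__(self) -> None:
        has_files = self.recordings_csv is not None and self.meta_json is not None
        if has_files == (self.condition is not None):
            raise ValueError(
                "provide either recordings_csv+meta_json or a simulator "
                "condition, not both")
        if self.condition is not None and self.condition.upper() not in "ABC":
            raise ValueError(f"unknown condition {self.condition!r}; expected A, B or C")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Load (or simulate) recordings, build the field table, summarise,
    optionally plot; returns the paths of everything written."""
    from .geometry import MontageLayout
    from .pipeline import build_field_table, summarize
    from .simulate import ForwardModelParams, condition_preset, simulate_recordings

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        log_lines.append(line)
        if config.verbose:
            print(line)

    def fail(stage: str, exc: Exception) -> Exception:
        return RuntimeError(f"stage {stage!r} failed: {exc}")

    try:
        if config.condition is not None:
            montage = condition_preset(config.condition)
            layout = MontageLayout.standard(config.diameter_mm)
            params = ForwardModelParams(
                sigma_S_per_m=config.sigma_S_per_m,
                noise_cv=config.noise_cv, seed=config.seed)
            recordings = simulate_recordings(montage, layout, params,
                                             projection=config.projection)
            log("simulate", f"condition {montage.condition}, seed {config.seed}")
        else:
            recordings = load_recordings(config.recordings_csv, config.meta_json)
            log("load", f"loaded {len(recordings.delta_v)} entries "
                        f"from {config.recordings_csv}")
    except Exception as exc:
        raise fail("load" if config.condition is None else "simulate", exc) from exc

    try:
        layout = MontageLayout.standard(recordings.metadata.diameter_mm)
        rule = (load_neighbor_rule(config.neighbors_json)
                if config.neighbors_json else None)
        table = build_field_table(
            recordings, layout, rule=rule, projection=config.projection,
            strict_pad_surface=config.strict_pad_surface)
        log("field_table", f"{len(table)} rows")
    except Exception as exc:
        raise fail("field_table", exc) from exc

    try:
        summary = summarize(table)
    except Exception as exc:
        raise fail("summarize", exc) from exc

    outputs: dict[str, Path] = {}
    outputs["field_table"] = write_field_table(table, out_dir / "field_table.csv")
    outputs["summary"] = write_summary(summary, out_dir / "summary.json")

    if config.make_plots:
        from .viz import ViewSpec, render_map
        try:
            for quantity in ("dv", "ef"):
                for view in ("anterior", "posterior", "superior"):
                    name = f"{quantity}_{view}.png"
                    spec = ViewSpec(quantity=quantity, depth="all", view=view)
                    outputs[name] = render_map(table, spec, out_dir / name)
                    log("plot", name)
        except Exception as exc:
            raise fail("plot", exc) from exc

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    return outputs
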