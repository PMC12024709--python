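"""Synthetic phantom recordings from a quasi-static point-source model.

The physical experiment injects direct current through surface pads and
reads voltage differences with an oscilloscope.  This module emulates
those recordings so every downstream stage can be exercised without
hardware: each pad is discretised into a grid of point current sources
slightly inset below the sphere surface, the potential anywhere is the
free-space quasi-static monopole superposition

    V(p) = (1 / (4 pi sigma)) * sum_k I_k / |p - p_k|,

and the simulated dV at a recording site is |V(site) - V(reference
pickup)|, the pickup riding on the reference pad exactly as the
recording reference does in the experiment.  Multiplicative Gaussian
noise emulates readout scatter.

The kernel is deliberately simple (homogeneous unbounded medium, single
scalar conductivity): it provides plausible spatial structure for
testing the pipeline, not quantitative biophysics.  It is pluggable via
``potential_at`` should a boundary-corrected Green's function be needed.

Montage presets mirror three standard tDCS configurations:

* ``A`` — monopolar: anodes over both motor cortices (C3, C4, 7x5 cm,
  1 mA each), extracephalic return in the water bath (8x6 cm, -2 mA);
  recording reference on the C3 pad.
* ``B`` — bicephalic fronto-occipital: anodes Fp1/Fp2, returns O1/O2
  (5x5 cm, two 1.4 mA circuits); reference on the O1 pad.
* ``C`` — bicephalic latero-lateral: anodes F7/T5, returns F8/T6
  (5x5 cm, two 1.4 mA circuits); reference on the T6 pad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import DepthLevel, MontageLayout, recording_grid
from .pipeline import PhantomMetadata, VoltageRecordingSet

__all__ = [
    "BATH",
    "PadSpec",
    "StimulusMontage",
    "ForwardModelParams",
    "condition_preset",
    "pad_source_points",
    "potential_at",
    "simulate_recordings",
]

#: Pad location marker for the extracephalic return in the water bath.
BATH = "bath"

#: Radial inset of the bath return below the sphere's bottom pole (mm).
BATH_OFFSET_MM = 20.0


@dataclass(frozen=True)
class PadSpec:
    """One stimulating pad: location, polarity, size and current share."""

    location: str  # electrode label or BATH
    polarity: str  # "anode" | "cathode"
    width_cm: float
    height_cm: float
    current_mA: float  # unsigned share carried by this pad

    def __post_init__(self) -> None:
        if self.polarity not in ("anode", "cathode"):
            raise ValueError(f"polarity must be anode|cathode, got {self.polarity!r}")
        if self.current_mA < 0:
            raise ValueError("current_mA is an unsigned share; use polarity for sign")

    @property
    def signed_current_mA(self) -> float:
        return self.current_mA if self.polarity == "anode" else -self.current_mA


@dataclass(frozen=True)
class StimulusMontage:
    """A stimulation configuration plus the pad carrying the recording
    reference.  Injected currents must sum to zero (charge conservation)."""

    condition: str
    pads: tuple[PadSpec, ...]
    reference: str  # electrode label of the pad carrying the recording pickup
    total_current_mA: float

    def __post_init__(self) -> None:
        net = sum(p.signed_current_mA for p in self.pads)
        if abs(net) > 1e-9:
            raise ValueError(f"injected currents must sum to zero, got {net} mA")
        if self.reference not in self.cephalic_pad_labels:
            raise ValueError(
                f"recording reference {self.reference!r} must ride on a cephalic "
                f"stimulating pad (pads: {sorted(self.cephalic_pad_labels)})")

    @property
    def cephalic_pad_labels(self) -> tuple[str, ...]:
        return tuple(p.location for p in self.pads if p.location != BATH)


def condition_preset(condition: str) -> StimulusMontage:
    """Montage preset ``A``, ``B`` or ``C`` (see module docstring)."""
    c = condition.strip().upper()
    if c == "A":
        return StimulusMontage(
            condition="A",
            pads=(
                PadSpec("C3", "anode", 7.0, 5.0, 1.0),
                PadSpec("C4", "anode", 7.0, 5.0, 1.0),
                PadSpec(BATH, "cathode", 8.0, 6.0, 2.0),
            ),
            reference="C3",
            total_current_mA=2.0,
        )
    if c == "B":
        return StimulusMontage(
            condition="B",
            pads=(
                PadSpec("Fp1", "anode", 5.0, 5.0, 0.7),
                PadSpec("Fp2", "anode", 5.0, 5.0, 0.7),
                PadSpec("O1", "cathode", 5.0, 5.0, 0.7),
                PadSpec("O2", "cathode", 5.0, 5.0, 0.7),
            ),
            reference="O1",
            total_current_mA=1.4,
        )
    if c == "C":
        return StimulusMontage(
            condition="C",
            pads=(
                PadSpec("F7", "anode", 5.0, 5.0, 0.7),
                PadSpec("T5", "anode", 5.0, 5.0, 0.7),
                PadSpec("F8", "cathode", 5.0, 5.0, 0.7),
                PadSpec("T6", "cathode", 5.0, 5.0, 0.7),
            ),
            reference="T6",
            total_current_mA=1.4,
        )
    raise ValueError(f"unknown condition {condition!r}; expected A, B or C")


@dataclass(frozen=True)
class ForwardModelParams:
    """Knobs of the forward model.

    sigma_S_per_m
        Bulk conductivity (S/m).  Default 0.5, a watery-tissue scale.
    pad_grid
        Point sources per pad, rows x columns.  Default 3x3.
    inset_mm
        Radial depth of the sources below the surface (mm); keeps the
        surface pickup non-singular.  Default 2.
    noise_cv
        Coefficient of variation of the multiplicative readout noise.
        Default 0.05; set 0 for a noiseless run.
    seed
        Seed of the noise generator.
    round_step_mV
        Optional readout quantisation step (mV).
    """

    sigma_S_per_m: float = 0.5
    pad_grid: tuple[int, int] = (3, 3)
    inset_mm: float = 2.0
    noise_cv: float = 0.05
    seed: int | None = None
    round_step_mV: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma_S_per_m > 0:
            raise ValueError("sigma must be > 0")
        if self.inset_mm < 0:
            raise ValueError("inset_mm must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if min(self.pad_grid) < 1:
            raise ValueError("pad_grid entries must be >= 1")


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent basis at the surface point with radial unit u."""
    zhat = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(zhat, u)
    if np.linalg.norm(e1) < 1e-12:  # pole: pick +x
        e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def pad_source_points(
    montage: StimulusMontage,
    layout: MontageLayout,
    params: ForwardModelParams = ForwardModelParams(),
) -> list[tuple[np.ndarray, float]]:
    """Discretise each pad into an n x m grid of (position, current) sources.

    Cephalic pads span their physical extent in the tangent plane at the
    electrode and are projected radially onto the sphere, inset by
    ``params.inset_mm``; the bath return sits below the bottom pole,
    offset outward by ``BATH_OFFSET_MM``.  Each source carries
    current / (n * m); the total over all pads is zero by construction.
    """
    sphere = layout.sphere
    center = sphere.center_array
    n, m = params.pad_grid
    sources: list[tuple[np.ndarray, float]] = []
    for pad in montage.pads:
        w_mm, h_mm = pad.width_cm * 10.0, pad.height_cm * 10.0
        if max(w_mm, h_mm) > math.pi * sphere.radius:
            raise ValueError(
                f"pad at {pad.location!r} ({pad.width_cm}x{pad.height_cm} cm) "
                "exceeds the hemisphere circumference")
        share = pad.signed_current_mA / (n * m)
        us = np.linspace(-w_mm / 2, w_mm / 2, n) if n > 1 else np.array([0.0])
        vs = np.linspace(-h_mm / 2, h_mm / 2, m) if m > 1 else np.array([0.0])
        if pad.location == BATH:
            base = center + np.array([0.0, 0.0, -(sphere.radius + BATH_OFFSET_MM)])
            e1 = np.array([1.0, 0.0, 0.0])
            e2 = np.array([0.0, 1.0, 0.0])
            for a in us:
                for b in vs:
                    sources.append((base + a * e1 + b * e2, share))
        else:
            surf = layout.position(pad.location)
            u = (surf - center) / sphere.radius
            e1, e2 = _tangent_basis(u)
            r_src = sphere.radius - params.inset_mm
            for a in us:
                for b in vs:
                    q = surf + a * e1 + b * e2 - center
                    q = q / np.linalg.norm(q)
                    sources.append((center + r_src * q, share))
    return sources


def potential_at(
    points: np.ndarray,
    sources: Sequence[tuple[np.ndarray, float]],
    sigma_S_per_m: float,
) -> np.ndarray:
    """Quasi-static potential (mV) at each point from monopole superposition.

    ``points`` is (N, 3) or (3,) in mm; currents in mA.  Raises if any
    point coincides with a source (singular).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pos = np.array([p for p, _ in sources], dtype=float)  # (K, 3)
    cur = np.array([i for _, i in sources], dtype=float)  # (K,)
    r = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)  # mm
    if np.any(r == 0):
        raise ValueError("evaluation point coincides with a point source")
    # I[mA] / (4 pi sigma r[mm]) is in volts; scale to mV
    v = 1000.0 * (cur[None, :] / (4.0 * math.pi * sigma_S_per_m * r)).sum(axis=1)
    return v if np.asarray(points).ndim > 1 else float(v[0])


def simulate_recordings(
    montage: StimulusMontage,
    layout: MontageLayout,
    params: ForwardModelParams = ForwardModelParams(),
    projection: str = "mirror",
) -> VoltageRecordingSet:
    """Simulate the full 84-site recording set for one montage.

    dV at each site is |V(site) - V(pickup)| with the pickup on the
    surface of the reference pad.  Sites under stimulating pads are
    marked not-recordable, as in the physical protocol.  Noise is
    multiplicative, |1 + eps| with eps ~ Normal(0, cv), drawn in the
    canonical site order from ``numpy.random.default_rng(seed)``.
    """
    sources = pad_source_points(montage, layout, params)
    pickup = layout.position(montage.reference)
    if params.inset_mm == 0:
        raise ValueError("inset_mm must be > 0: the surface pickup would "
                         "coincide with a pad source")
    v_ref = potential_at(pickup, sources, params.sigma_S_per_m)

    points = recording_grid(layout, montage.reference, projection=projection)
    pads = set(montage.cephalic_pad_labels)
    world = np.array([p.world for p in points])
    v = potential_at(world, sources, params.sigma_S_per_m)
    dv = np.abs(v - v_ref)

    rng = np.random.default_rng(params.seed)
    if params.noise_cv > 0:
        dv = dv * np.abs(1.0 + rng.normal(0.0, params.noise_cv, size=dv.shape))
    if params.round_step_mV:
        dv = np.round(dv / params.round_step_mV) * params.round_step_mV

    delta_v: dict[tuple[str, DepthLevel], float | None] = {}
    for p, value in zip(points, dv):
        delta_v[(p.electrode, p.depth)] = (
            None if p.electrode in pads else float(value))
    meta = PhantomMetadata(diameter_mm=layout.sphere.diameter,
                           weight_kg=4.0, temperature_C=24.0)
    return VoltageRecordingSet(
        condition=montage.condition,
        reference=montage.reference,
        pads=tuple(sorted(pads)),
        delta_v=delta_v,
        metadata=meta,
    )
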