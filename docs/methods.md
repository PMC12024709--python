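# Methods

## The measurement model

`phantomfield` analyses voltage recordings made inside a head-sized
spherical phantom during transcranial direct current stimulation (tDCS).
A recording electrode is inserted radially at each of the 21 positions of
the international 10–20 system, one at a time, and the voltage difference
ΔV (mV) against a reference electrode riding on one of the stimulating
pads is read at four depths along the insertion line: the surface (Z0),
one third (Z33) and two thirds (Z66) of the diameter, and the full
diameter (Z100). The electric-field magnitude at each site is estimated
as the average gradient

    EF = ΔV / |E − R|   (mV/mm),

where E is the recording site and R the reference electrode's surface
position, taken as the coordinate origin. This is an average-magnitude
estimate over the chord ER, not a vector field: it assumes the medium is
isotropic and homogeneous, and it inherits the reference's position — all
distances and therefore all EF values are relative to the pad-mounted
reference, not to infinity.

## Spherical 10–20 geometry

The phantom is idealised as a perfect sphere (default diameter
240.80 mm). Electrode angles are not tabulated anywhere in the source
protocol, so the package fixes them from the standard 10–20 percentage
spacings, reverse-checked against the published coordinate grid:

* outer ring (Fp1/Fpz/Fp2, F7/F8, T3/T4, T5/T6, O1/Oz/O2) at 18°
  elevation, azimuths at 0, ±18, ±54, ±90, ±126, ±162, 180° from the
  nasion;
* parasagittal F3/F4, P3/P4 at 36° elevation, azimuth ±36°/±144°;
* Fz/C3/C4/Pz at 54°; Cz at the pole (90°).

With these angles every published surface coordinate is reproduced to
better than ±0.01 mm, and the full 84-row grid (coordinates and
distances) to ±0.005 mm.

Depth placement: with û the outward unit radial at the electrode, the
four sites are R·û (Z0), (R/3)·û (Z33), (R/3)·T(û) (Z66) and R·T(û)
(Z100). The published grid requires T to be the half-turn about the
left–right axis, T(x, y, z) = (x, −y, −z), which keeps deep sites on the
insertion electrode's own side (its Z100 point under the *ipsilateral*
hemisphere). A physically radial alternative T(û) = −û (true antipode,
where a straight rod would actually end) is available via
`projection="antipode"` / `--deep-projection antipode`; the default is
`mirror` because that is what the reference grid encodes. Depth
fractions are exactly 1/3 and 2/3 (the published insertion step
80.27 mm = 240.80/3 confirms thirds rather than a literal 0.33).

## Pad imputation

Sites under the stimulating pads cannot be recorded. Their ΔV at each
depth is imputed as the arithmetic mean of the surrounding electrodes'
ΔV at the same depth. The surrounding set defaults to the five nearest
recordable electrodes on the pad's own hemisphere (plain nearest-k for a
midline pad); for the motor-cortex pads this yields C3 → {F7, F3, T3,
P3, T5} and C4 → {F8, F4, T4, P4, T6}, the sets that reproduce the
published imputed EF values to ±0.05 mV/mm. The rule is overridable per
pad (`--neighbors` JSON).

One site is degenerate: the reference electrode's own surface position
has distance 0, so EF = ΔV/distance is undefined there. Its EF is
imputed directly as the mean of the neighbours' surface EF and flagged
`ef_mean` (ΔV is left blank). An optional strict mode additionally
writes EF = 0.0 at the surface site of non-reference pads, reproducing a
placeholder convention seen in measured tables; the default computes the
ratio normally there.

Any missing ΔV at a non-pad electrode is an error, never silently
imputed, and validation reports every violation in a file at once.

## Forward simulator

The synthetic generator stands in for the physical experiment so the
pipeline can be exercised and property-tested without hardware. Each pad
is discretised into a grid of point current sources (default 3×3) spread
over the pad's physical extent in the tangent plane, projected onto the
sphere and inset radially by 2 mm (keeping the surface pickup
non-singular); an extracephalic return is placed 20 mm below the bottom
pole. The potential is the quasi-static free-space monopole
superposition

    V(p) = (1 / 4πσ) · Σ_k I_k / |p − p_k|,

with a single scalar conductivity σ = 0.5 S/m, and the simulated reading
is ΔV = |V(site) − V(pickup)| with the pickup on the reference pad's
surface, exactly mirroring the physical referencing. Readout noise is
multiplicative, |1 + ε| with ε ~ Normal(0, cv), cv = 0.05 by default,
fully determined by the seed; an optional quantisation step emulates
scope resolution.

Montage presets reflect three standard configurations: (A) monopolar —
anodes C3 and C4 (7×5 cm, 1 mA each), 2 mA total returned through the
bath, reference on the C3 pad; (B) fronto-occipital — anodes Fp1/Fp2,
returns O1/O2 (5×5 cm, two 1.4 mA circuits), reference on O1;
(C) latero-lateral — anodes F7/T5, returns F8/T6, reference on T6.

What the simulator does *not* model: the peel/pulp conductivity
contrast, electrode–gel interface impedance, the bath's volume-conduction
geometry, boundary conditions at the sphere surface (the kernel is
free-space, not an insulated-sphere Green's function), or temporal
dynamics. Passing tests therefore demonstrate that the pipeline's
bookkeeping, imputation and summaries behave correctly on data with
plausible spatial structure — not that the simulator predicts measured
magnitudes, which are never compared against it.

One consequence of pad-mounted referencing worth noting: for a single
active pad the *potential* decays monotonically (1/r) with distance from
the pad, but the *recorded* ΔV — being relative to the pickup on the pad
— rises monotonically with distance. The tests assert both.

## Visualisation

ΔV and EF are drawn per depth on orthographic discs (anterior,
posterior, superior), warm colours high. Shading is inverse-distance
weighting (power 2) over the projected visible electrodes, masked to the
disc; back-facing electrodes are drawn hollow and excluded from
interpolation. Colour bounds are shared across the four depths of one
figure by default (depths are meant to be compared within a figure);
per-depth or explicit bounds are available. The anterior view uses
facing-the-head handedness: the left hemisphere appears on the viewer's
right.

## Numerical conventions

* Units exactly as recorded: ΔV mV, distances mm, EF mV/mm; no SI
  rescaling.
* Degrees in the public API, radians internally; mm everywhere.
* CSV exports round to 2 decimals; all comparisons and downstream
  computation use unrounded values.
* Deterministic ordering everywhere: canonical electrode order
  (Fp1 … O2, the row order of the exported tables), then depth.
* On-sphere membership is validated at 1e−6 relative tolerance before
  depth projection; layout invariants (on-sphere, mirror symmetry) hold
  to 1e−9 relative.

## Known limitations

* The EF estimate is a chord-average magnitude relative to a pad-mounted
  reference; it is not comparable to field values from volume-conductor
  solvers without accounting for the reference.
* The sphere idealisation distorts true recording positions on a real,
  non-spherical phantom.
* The mirror depth projection is a bookkeeping convention, not physics;
  use `antipode` for the physical rod path.
* Four EF entries of the published reference grid (F3, F4, P3, P4) are
  inconsistent with their own ΔV and distance columns; the pipeline
  reproduces the self-consistent arithmetic and these rows are excluded
  from numeric comparisons (the identity EF·distance = ΔV is asserted on
  all outputs instead).
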