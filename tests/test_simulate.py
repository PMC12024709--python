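"""Forward simulator: source construction, potentials, recording sets."""

import math

import numpy as np
import pytest

import phantomfield as pf
from phantomfield.geometry import DepthLevel
from phantomfield.pipeline import CONDITION_A_NEIGHBORS, build_field_table
from phantomfield.simulate import (
    BATH,
    BATH_OFFSET_MM,
    ForwardModelParams,
    PadSpec,
    StimulusMontage,
    condition_preset,
    pad_source_points,
    potential_at,
    simulate_recordings,
)

NOISELESS = ForwardModelParams(noise_cv=0.0)
SINGLE_POINT = ForwardModelParams(noise_cv=0.0, pad_grid=(1, 1))


def recordable_values(rec, depth=None):
    return {k: v for k, v in rec.delta_v.items()
            if v is not None and (depth is None or k[1] == depth)}


class TestPadSourcePoints:
    def test_condition_a_single_point_discretisation(self, layout):
        sources = pad_source_points(condition_preset("A"), layout, SINGLE_POINT)
        currents = sorted(i for _, i in sources)
        assert currents == pytest.approx([-2.0, 1.0, 1.0])
        assert sum(i for _, i in sources) == pytest.approx(0.0, abs=1e-12)

    def test_condition_b_splits_two_circuits(self, layout):
        sources = pad_source_points(condition_preset("B"), layout, SINGLE_POINT)
        currents = sorted(i for _, i in sources)
        assert currents == pytest.approx([-0.7, -0.7, 0.7, 0.7])

    @pytest.mark.parametrize("condition", ["A", "B", "C"])
    def test_currents_conserve_charge(self, layout, condition):
        sources = pad_source_points(condition_preset(condition), layout,
                                    ForwardModelParams())
        assert abs(sum(i for _, i in sources)) < 1e-12

    def test_cephalic_sources_inset_below_surface(self, layout):
        params = ForwardModelParams(inset_mm=2.0)
        montage = condition_preset("B")  # all pads cephalic
        c = layout.sphere.center_array
        for pos, _ in pad_source_points(montage, layout, params):
            assert np.linalg.norm(pos - c) == pytest.approx(
                layout.sphere.radius - 2.0, abs=1e-9)

    def test_bath_return_sits_below_bottom_pole(self, layout):
        sources = pad_source_points(condition_preset("A"), layout, SINGLE_POINT)
        sinks = [pos for pos, i in sources if i < 0]
        assert len(sinks) == 1
        c = layout.sphere.center_array
        assert sinks[0][2] - c[2] == pytest.approx(
            -(layout.sphere.radius + BATH_OFFSET_MM))

    def test_oversized_pad_rejected(self, layout):
        montage = StimulusMontage(
            condition="custom",
            pads=(PadSpec("Cz", "anode", 60.0, 5.0, 1.0),
                  PadSpec(BATH, "cathode", 8.0, 6.0, 1.0)),
            reference="Cz", total_current_mA=1.0)
        with pytest.raises(ValueError, match="hemisphere"):
            pad_source_points(montage, layout, ForwardModelParams())

    def test_unbalanced_montage_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            StimulusMontage(
                condition="custom",
                pads=(PadSpec("C3", "anode", 5.0, 5.0, 1.0),
                      PadSpec(BATH, "cathode", 5.0, 5.0, 0.5)),
                reference="C3", total_current_mA=1.0)


class TestPotential:
    def test_closed_form_single_source(self):
        # 1 mA at 50 mm in sigma = 0.5 S/m: V = 1e-3 / (4 pi 0.5 0.05) V
        v = potential_at(np.array([50.0, 0.0, 0.0]),
                         [(np.zeros(3), 1.0)], 0.5)
        assert v == pytest.approx(1e3 * 1e-3 / (4 * math.pi * 0.5 * 0.05),
                                  rel=1e-12)

    def test_inverse_distance_decay(self):
        src = [(np.zeros(3), 1.0)]
        v1 = potential_at(np.array([40.0, 0.0, 0.0]), src, 0.5)
        v2 = potential_at(np.array([80.0, 0.0, 0.0]), src, 0.5)
        assert v1 / v2 == pytest.approx(2.0, rel=1e-12)

    def test_antisymmetric_pair_cancels_on_bisector(self):
        src = [(np.array([-10.0, 0.0, 0.0]), 1.0),
               (np.array([10.0, 0.0, 0.0]), -1.0)]
        v = potential_at(np.array([0.0, 55.0, 0.0]), src, 0.5)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_singular_at_source_position(self):
        with pytest.raises(ValueError):
            potential_at(np.zeros(3), [(np.zeros(3), 1.0)], 0.5)

    def test_superposition_of_circuits(self, layout):
        """Joint potentials of the two bicephalic circuits equal the sum of
        each circuit simulated alone."""
        params = ForwardModelParams()
        joint = pad_source_points(condition_preset("B"), layout, params)
        m1 = StimulusMontage("c1", (PadSpec("Fp1", "anode", 5, 5, 0.7),
                                    PadSpec("O1", "cathode", 5, 5, 0.7)),
                             reference="O1", total_current_mA=0.7)
        m2 = StimulusMontage("c2", (PadSpec("Fp2", "anode", 5, 5, 0.7),
                                    PadSpec("O2", "cathode", 5, 5, 0.7)),
                             reference="O2", total_current_mA=0.7)
        pts = np.array([p.world for p in pf.recording_grid(layout, "Cz")])
        v_joint = potential_at(pts, joint, 0.5)
        v_split = (potential_at(pts, pad_source_points(m1, layout, params), 0.5)
                   + potential_at(pts, pad_source_points(m2, layout, params), 0.5))
        assert np.allclose(v_joint, v_split, rtol=1e-12)

    def test_polarity_swap_negates_potentials(self, layout):
        sources = pad_source_points(condition_preset("A"), layout,
                                    ForwardModelParams())
        flipped = [(pos, -i) for pos, i in sources]
        pts = np.array([p.world for p in pf.recording_grid(layout, "Cz")])
        assert np.allclose(potential_at(pts, sources, 0.5),
                           -potential_at(pts, flipped, 0.5), rtol=1e-12)


class TestSimulateRecordings:
    def test_84_entries_with_pads_not_recordable(self, layout):
        rec = simulate_recordings(condition_preset("A"), layout, NOISELESS)
        assert len(rec.delta_v) == 84
        for pad in ("C3", "C4"):
            for d in DepthLevel:
                assert rec.value(pad, d) is None
        assert all(v >= 0 for v in recordable_values(rec).values())

    def test_zero_current_montage_gives_zero_voltages(self, layout):
        montage = StimulusMontage(
            condition="null",
            pads=(PadSpec("C3", "anode", 5, 5, 0.0),
                  PadSpec(BATH, "cathode", 5, 5, 0.0)),
            reference="C3", total_current_mA=0.0)
        rec = simulate_recordings(montage, layout, NOISELESS)
        assert all(v == 0.0 for v in recordable_values(rec).values())

    def test_doubling_current_doubles_noiseless_voltages(self, layout):
        base = condition_preset("A")
        doubled = StimulusMontage(
            condition="A2",
            pads=tuple(PadSpec(p.location, p.polarity, p.width_cm, p.height_cm,
                               2 * p.current_mA) for p in base.pads),
            reference=base.reference, total_current_mA=2 * base.total_current_mA)
        r1 = recordable_values(simulate_recordings(base, layout, NOISELESS))
        r2 = recordable_values(simulate_recordings(doubled, layout, NOISELESS))
        for k in r1:
            assert r2[k] == pytest.approx(2 * r1[k], rel=1e-12)

    def test_polarity_swap_leaves_magnitudes_unchanged(self, layout):
        base = condition_preset("B")
        swapped = StimulusMontage(
            condition="B-swapped",
            pads=tuple(PadSpec(p.location,
                               "cathode" if p.polarity == "anode" else "anode",
                               p.width_cm, p.height_cm, p.current_mA)
                       for p in base.pads),
            reference=base.reference, total_current_mA=base.total_current_mA)
        r1 = recordable_values(simulate_recordings(base, layout, NOISELESS))
        r2 = recordable_values(simulate_recordings(swapped, layout, NOISELESS))
        for k in r1:
            assert r2[k] == pytest.approx(r1[k], rel=1e-12)

    def test_condition_b_is_mirror_symmetric(self, layout):
        """The fronto-occipital montage is left-right symmetric, so the
        noiseless dV field must match across homologue pairs."""
        rec = simulate_recordings(condition_preset("B"), layout, NOISELESS)
        pairs = [("F7", "F8"), ("F3", "F4"), ("T3", "T4"),
                 ("T5", "T6"), ("P3", "P4")]
        for left, right in pairs:
            for d in DepthLevel:
                a, b = rec.value(left, d), rec.value(right, d)
                assert abs(a - b) <= 1e-9 * max(abs(a), abs(b))

    def test_single_pad_potential_decays_along_ring(self, layout):
        """Potential from one pad's sources decays monotonically with
        great-circle distance from the pad among the 18-degree ring."""
        montage = StimulusMontage(
            condition="single",
            pads=(PadSpec("T3", "anode", 5, 5, 1.0),
                  PadSpec(BATH, "cathode", 8, 6, 1.0)),
            reference="T3", total_current_mA=1.0)
        sources = [s for s in pad_source_points(montage, layout,
                                                ForwardModelParams())
                   if s[1] > 0]  # the pad alone
        ring = ["T3", "F7", "T5", "Fp1", "O1", "Fpz", "Oz", "Fp2", "O2",
                "F8", "T6", "T4"]  # increasing arc distance from T3
        c = layout.sphere.center_array
        u_pad = (layout.position("T3") - c) / layout.sphere.radius
        arc, pot = [], []
        for e in ring:
            u = (layout.position(e) - c) / layout.sphere.radius
            arc.append(math.acos(np.clip(np.dot(u, u_pad), -1, 1)))
            pot.append(potential_at(layout.position(e), sources, 0.5))
        order = np.argsort(arc)
        assert all(np.diff(np.asarray(pot)[order]) < 1e-12)

    def test_voltage_rises_with_distance_from_pad_reference(self, layout):
        """With the pickup riding the T3 pad, the recorded dV at the ring
        grows monotonically with arc distance from the pad."""
        montage = StimulusMontage(
            condition="single",
            pads=(PadSpec("T3", "anode", 5, 5, 1.0),
                  PadSpec(BATH, "cathode", 8, 6, 1.0)),
            reference="T3", total_current_mA=1.0)
        rec = simulate_recordings(montage, layout, NOISELESS)
        c = layout.sphere.center_array
        u_pad = (layout.position("T3") - c) / layout.sphere.radius
        ring = ["F7", "T5", "Fp1", "O1", "Fpz", "Oz", "Fp2", "O2",
                "F8", "T6", "T4"]
        arc = {e: math.acos(np.clip(np.dot(
            (layout.position(e) - c) / layout.sphere.radius, u_pad), -1, 1))
            for e in ring}
        ordered = sorted(ring, key=arc.get)
        dv = np.array([rec.value(e, DepthLevel.Z0) for e in ordered])
        # ties in arc distance (mirror pairs) may reorder at round-off
        assert all(np.diff(dv) > -1e-9 * dv.max())

    def test_seeded_reproducibility(self, layout):
        params = ForwardModelParams(noise_cv=0.05, seed=42)
        r1 = simulate_recordings(condition_preset("A"), layout, params)
        r2 = simulate_recordings(condition_preset("A"), layout, params)
        assert r1.delta_v == r2.delta_v
        r3 = simulate_recordings(
            condition_preset("A"), layout,
            ForwardModelParams(noise_cv=0.05, seed=43))
        assert r1.delta_v != r3.delta_v

    def test_rounding_step_quantises_readout(self, layout):
        params = ForwardModelParams(noise_cv=0.0, round_step_mV=0.5)
        rec = simulate_recordings(condition_preset("A"), layout, params)
        for v in recordable_values(rec).values():
            assert (v / 0.5) == pytest.approx(round(v / 0.5), abs=1e-9)

    def test_surface_field_peaks_adjacent_to_a_pad(self, layout):
        """End-to-end: the noiseless monopolar simulation, run through the
        field pipeline, puts its maximal surface EF at an electrode
        adjacent to a stimulating pad."""
        rec = simulate_recordings(condition_preset("A"), layout, NOISELESS)
        table = build_field_table(rec, layout)
        surf = table[(table.depth == "Z0") & (table.imputed == "measured")]
        argmax = surf.loc[surf["ef_mV_per_mm"].idxmax(), "electrode"]
        adjacent = set(CONDITION_A_NEIGHBORS["C3"]) | set(
            CONDITION_A_NEIGHBORS["C4"])
        assert argmax in adjacent
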