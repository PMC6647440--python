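import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uteroflow import network as nw
from uteroflow.network import (NetworkModel, ParticipantInfo, VesselSegment,
                               area_to_diameter, build_uteroovarian,
                               init_wave_speed, load_network, load_packaged,
                               murray_fill, place_venous_valves, scale_lengths,
                               vein_from_artery, wall_viscosity, write_network)


@pytest.fixture(scope="module")
def table1():
    return load_packaged("uteroovarian_table1.csv")


class TestVesselTable:
    def test_packaged_table_values(self, table1):
        comm = table1.segments[64]
        assert comm.name == "Communicating artery"
        assert comm.length == 5.0
        assert comm.area_ref_np == pytest.approx(0.004418)
        assert comm.area_ref_p == pytest.approx(0.048105)
        spiral = table1.segments[66]
        assert spiral.multiplicity == 50
        assert spiral.area_ref_np == pytest.approx(0.000314)
        vein = table1.segments[270]
        assert vein.region == "systemic_vein"
        assert vein.area_ref_p == pytest.approx(0.7854)

    def test_empty_table_rejected(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text(",".join(nw.CSV_HEADER) + "\n")
        with pytest.raises(nw.NetworkError, match="no segments"):
            load_network(f)

    def test_duplicate_id_rejected(self, tmp_path):
        f = tmp_path / "dup.csv"
        row = "1,a,systemic_artery,left,3,0.1,0.1,1,,\n"
        f.write_text(",".join(nw.CSV_HEADER) + "\n" + row + row)
        with pytest.raises(nw.NetworkError, match="duplicate"):
            load_network(f)

    def test_dangling_parent_rejected(self, tmp_path):
        f = tmp_path / "dangle.csv"
        f.write_text(",".join(nw.CSV_HEADER) + "\n"
                     + "1,a,systemic_artery,left,3,0.1,0.1,1,99,\n")
        with pytest.raises(nw.NetworkError, match="dangling"):
            load_network(f)

    def test_nonpositive_geometry_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text(",".join(nw.CSV_HEADER) + "\n"
                     + "1,a,systemic_artery,left,-3,0.1,0.1,1,,\n")
        with pytest.raises(nw.NetworkError, match="length"):
            load_network(f)

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip(self, table1, tmp_path, fmt):
        p = tmp_path / f"rt.{fmt}"
        write_network(table1, p)
        back = load_network(p)
        assert sorted(back.segments) == sorted(table1.segments)
        for sid, seg in table1.segments.items():
            b = back.segments[sid]
            assert (b.name, b.region, b.multiplicity) == (seg.name, seg.region,
                                                          seg.multiplicity)
            assert b.length == seg.length
            assert b.area_ref_np == seg.area_ref_np
            assert b.area_ref_p == seg.area_ref_p
            assert tuple(b.parent_ids) == tuple(seg.parent_ids)
            assert b.bed_id == seg.bed_id


class TestGeometry:
    def test_uterine_artery_diameter_at_term(self):
        # pregnant-state ascending uterine artery: 2.47 mm lumen
        assert area_to_diameter(0.048105) * 10 == pytest.approx(2.47, abs=0.005)

    def test_spiral_artery_diameter_non_pregnant(self):
        assert area_to_diameter(0.000314) * 10 == pytest.approx(0.2, abs=0.001)

    def test_unit_circle(self):
        assert area_to_diameter(math.pi / 4) == pytest.approx(1.0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            area_to_diameter(0.0)

    def test_murray_two_equal_children(self):
        d = murray_fill(1.0, 2)
        assert d[0] == d[1] == pytest.approx(2 ** (-1 / 2.76))

    def test_murray_single_child_conserves_diameter(self):
        assert murray_fill(0.37, 1) == [pytest.approx(0.37)]

    def test_murray_classic_exponent(self):
        d = murray_fill(1.0, 2, exponent=3.0)
        assert d[0] == pytest.approx(2 ** (-1 / 3))

    @given(st.integers(1, 6), st.floats(0.05, 5.0),
           st.lists(st.floats(0.1, 10.0), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_murray_conserves_power_sum(self, n, D, weights):
        d = murray_fill(D, n, split_weights=weights[:n])
        assert sum(x ** 2.76 for x in d) == pytest.approx(D ** 2.76, rel=1e-12)

    def test_vein_rule(self):
        assert vein_from_artery(0.04) == pytest.approx(0.0625)
        a = 0.37
        ratio = area_to_diameter(vein_from_artery(a)) / area_to_diameter(a)
        assert ratio == pytest.approx(1.25)

    def test_table_values_override_vein_rule(self, table1):
        # the tabulated ovarian vein keeps its printed area, which is not
        # 1.5625x the ovarian artery
        assert table1.segments[270].area_ref_np == pytest.approx(0.0767)
        assert table1.segments[270].area_ref_np != pytest.approx(
            vein_from_artery(table1.segments[62].area_ref_np), rel=0.05)


class TestElasticProperties:
    def test_wave_speed_systemic_artery(self):
        assert init_wave_speed(0.5, "systemic_artery") == pytest.approx(641, rel=0.01)

    def test_wave_speed_systemic_vein(self):
        assert init_wave_speed(0.5, "systemic_vein") == pytest.approx(355, rel=0.01)

    def test_wave_speed_k1_zero_limit(self):
        # with k1 = 0 the law reduces to sqrt(2 k3 / 3 rho), diameter-free
        import uteroflow.parameters as par
        k1, k2, k3 = par.WAVE_SPEED_COEFFS["systemic_artery"]
        ref = math.sqrt(2 * k3 / (3 * par.RHO))
        got = math.sqrt(2 / (3 * par.RHO) * (0.0 + k3))
        assert got == pytest.approx(ref)

    def test_wall_viscosity_artery(self):
        assert wall_viscosity(math.pi / 4, "systemic_artery") == pytest.approx(500.0)

    def test_wall_viscosity_pulmonary_constant(self):
        assert wall_viscosity(0.01, "pulmonary_artery") == 200.0
        assert wall_viscosity(10.0, "pulmonary_vein") == 200.0

    def test_wall_viscosity_large_vessel_asymptote(self):
        assert wall_viscosity(1e6, "systemic_artery") == pytest.approx(400.0, rel=1e-3)


class TestHeightScaling:
    def test_reference_height_is_identity(self, table1):
        p = ParticipantInfo("ref", 30, 185.42, "PP")
        scaled = scale_lengths(table1, p)
        assert scaled.segments[64].length == pytest.approx(5.0)

    @pytest.mark.parametrize("height,gamma", [(164.6, 0.8877), (168.0, 0.9061)])
    def test_participant_heights(self, table1, height, gamma):
        p = ParticipantInfo("x", 30, height, "T1")
        scaled = scale_lengths(table1, p)
        assert scaled.segments[64].length == pytest.approx(5.0 * gamma, abs=5e-4)

    @given(st.floats(120, 210), st.floats(120, 210))
    @settings(max_examples=25, deadline=None)
    def test_scaling_composes_multiplicatively(self, h1, h2):
        net = NetworkModel()
        net.segments[1] = VesselSegment(1, "v", 10.0, 0.5, 0.5)
        a = scale_lengths(scale_lengths(net, ParticipantInfo("a", 1, h1, "PP")),
                          ParticipantInfo("b", 1, h2, "PP"))
        g = (h1 / 185.42) * (h2 / 185.42)
        assert a.segments[1].length == pytest.approx(10.0 * g, rel=1e-12)


class TestVenousValves:
    def _vein(self, length, vena_cava=False):
        net = NetworkModel()
        net.segments[1] = VesselSegment(1, "v", length, 0.5, 0.5,
                                        region="systemic_vein",
                                        is_vena_cava=vena_cava)
        return place_venous_valves(net)

    def test_nine_cm_vein_two_valves(self):
        sites = self._vein(9.0).valve_sites
        assert [(s.segment_id, s.position) for s in sites] == [(1, 4.0), (1, 8.0)]

    def test_vena_cava_excluded(self):
        assert self._vein(9.0, vena_cava=True).valve_sites == []

    def test_short_vein_no_valve(self):
        assert self._vein(3.0).valve_sites == []

    def test_cumulative_spacing_across_series(self):
        net = NetworkModel()
        net.segments[1] = VesselSegment(1, "a", 3.0, 0.5, 0.5,
                                        region="systemic_vein")
        net.segments[2] = VesselSegment(2, "b", 3.0, 0.5, 0.5,
                                        region="systemic_vein", parent_ids=(1,))
        sites = place_venous_valves(net).valve_sites
        # 6 cm of cumulative path -> one valve 1 cm into the second vein
        assert [(s.segment_id, s.position) for s in sites] == [(2, 1.0)]


class TestUteroOvarianBuilder:
    def test_post_partum_has_no_placenta(self):
        net = build_uteroovarian("PP")
        assert all(b.name != "placenta" for b in net.beds.values())
        assert net.segments[66].area_ref("PP") == pytest.approx(0.000314)

    def test_term_pregnancy_has_placenta(self):
        net = build_uteroovarian("T3")
        names = {b.name for b in net.beds.values()}
        assert "placenta" in names
        assert net.segments[67].area_ref("T3") == pytest.approx(0.048105)

    def test_trimester_interpolation(self):
        seg = build_uteroovarian("T1").segments[64]
        w = 1.0 / 3.0
        assert seg.area_ref("T1") == pytest.approx(
            (1 - w) * 0.004418 + w * 0.048105)

    def test_arterial_and_venous_sides_mirror(self):
        net = build_uteroovarian("T3", sides="left")
        arteries = [s for s in net.segments.values()
                    if s.region == "systemic_artery"]
        veins = [s for s in net.segments.values() if s.region == "systemic_vein"]
        assert len(arteries) == len(veins)
        assert sorted(a.length for a in arteries) == sorted(v.length for v in veins)
        assert sorted(a.multiplicity for a in arteries) == \
            sorted(v.multiplicity for v in veins)

    def test_both_sides_symmetric(self):
        net = build_uteroovarian("T3", sides="both")
        left = [s for s in net.segments.values() if s.side == "left"]
        right = [s for s in net.segments.values() if s.side == "right"]
        assert len(left) == len(right)
        assert sorted(s.length for s in left) == sorted(s.length for s in right)

    def test_merged_doubles_multiplicity(self):
        both = build_uteroovarian("T3", sides="both")
        merged = build_uteroovarian("T3", sides="merged")
        assert merged.segments[65].multiplicity == 2 * 4
        assert len(merged.segments) == len(both.segments) // 2
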