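import math

import numpy as np
import pytest

from cephalo.core import ContractError, ImageSpace, LandmarkSet, N_LANDMARKS
from cephalo.measures import (
    MEASURE_NAMES,
    MeasureError,
    TYPE1,
    TYPE2,
    TYPE3,
    classify,
    compute_measure,
    default_measures,
    scr,
)


def build_set(scheme, space, overrides):
    """A generic non-degenerate landmark set with selected indices overridden."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(200.0, 1000.0, size=(N_LANDMARKS, 2))
    for idx, xy in overrides.items():
        coords[idx - 1] = xy
    return LandmarkSet(scheme, space, coords)


class TestComputeMeasure:
    def test_anb_hand_trigonometry(self, scheme, space1200):
        # rays from L2=(0,0) to L5=(0,100) and L6=(5,100): atan(5/100) apart
        ls = build_set(scheme, space1200, {5: (0, 100), 2: (0, 0), 6: (5, 100)})
        defs = default_measures()
        expected = math.degrees(math.atan(5.0 / 100.0))
        assert compute_measure(defs["ANB"], ls) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2.8624, abs=1e-3)

    def test_fhi_ratio(self, scheme, space1200):
        ls = build_set(
            scheme, space1200, {1: (0, 0), 10: (65, 0), 2: (300, 0), 8: (300, 100)}
        )
        defs = default_measures()
        assert compute_measure(defs["FHI"], ls) == pytest.approx(0.65)

    def test_mw_in_mm(self, scheme, space1200):
        ls = build_set(scheme, space1200, {11: (500, 500), 12: (510, 500)})
        defs = default_measures()
        assert compute_measure(defs["MW"], ls) == pytest.approx(3.5)

    def test_degenerate_geometry_names_measure(self, scheme, space1200):
        ls = build_set(scheme, space1200, {5: (100, 100), 2: (100, 100)})
        defs = default_measures()
        with pytest.raises(MeasureError, match="ANB"):
            compute_measure(defs["ANB"], ls)

    def test_snb_sna_use_stated_vertices(self, scheme, space1200):
        ls = build_set(
            scheme,
            space1200,
            {1: (0, -100), 2: (0, 0), 5: (100, 0), 6: (100, 100)},
        )
        defs = default_measures()
        assert compute_measure(defs["SNA"], ls) == pytest.approx(90.0)
        assert compute_measure(defs["SNB"], ls) == pytest.approx(135.0)


BOUNDARY_CASES = [
    # (measure, value, expected class) covering every band edge and the
    # corrected policies for SNB / ODI / MW
    ("ANB", 4.0, TYPE1),
    ("ANB", 3.2, TYPE1),
    ("ANB", 5.7, TYPE1),
    ("ANB", 6.0, TYPE2),
    ("ANB", 3.0, TYPE3),
    ("SNB", 76.0, TYPE1),
    ("SNB", 74.6, TYPE1),
    ("SNB", 78.7, TYPE1),
    ("SNB", 74.0, TYPE2),  # retrognathic below (corrected)
    ("SNB", 80.0, TYPE3),  # prognathic above (corrected)
    ("SNA", 80.0, TYPE1),
    ("SNA", 79.4, TYPE1),
    ("SNA", 83.2, TYPE1),
    ("SNA", 84.0, TYPE2),
    ("SNA", 79.0, TYPE3),
    ("ODI", 79.0, TYPE1),
    ("ODI", 78.4, TYPE1),
    ("ODI", 80.5, TYPE1),
    ("ODI", 81.0, TYPE2),
    ("ODI", 70.0, TYPE3),  # open tendency below the normal band (corrected)
    ("APDI", 80.0, TYPE1),
    ("APDI", 77.6, TYPE1),
    ("APDI", 85.2, TYPE1),
    ("APDI", 77.0, TYPE2),  # class 2 tendency is BELOW
    ("APDI", 86.0, TYPE3),
    ("FHI", 0.70, TYPE1),
    ("FHI", 0.65, TYPE1),
    ("FHI", 0.75, TYPE1),
    ("FHI", 0.80, TYPE2),  # short face above
    ("FHI", 0.60, TYPE3),
    ("FMA", 30.0, TYPE1),
    ("FMA", 26.8, TYPE1),
    ("FMA", 31.4, TYPE1),
    ("FMA", 32.0, TYPE2),
    ("FMA", 26.0, TYPE3),
    ("MW", 3.0, TYPE1),
    ("MW", 2.0, TYPE1),
    ("MW", 4.5, TYPE1),
    ("MW", 1.0, TYPE2),  # edge-to-edge side (corrected)
    ("MW", 5.0, TYPE3),  # large overjet
]


class TestClassify:
    @pytest.mark.parametrize("name,value,expected", BOUNDARY_CASES)
    def test_truth_table(self, name, value, expected):
        defs = default_measures()
        assert classify(defs[name], value) == expected

    def test_exhaustive_and_exclusive(self):
        defs = default_measures()
        rng = np.random.default_rng(0)
        for d in defs.values():
            lo, hi = d.lo, d.hi
            probes = np.concatenate(
                [rng.uniform(lo - 50, hi + 50, 200), [lo, hi, lo - 1e-9, hi + 1e-9]]
            )
            for v in probes:
                label = classify(d, float(v))
                assert label in (TYPE1, TYPE2, TYPE3)

    def test_nonfinite_rejected(self):
        defs = default_measures()
        with pytest.raises(ValueError):
            classify(defs["ANB"], float("nan"))


class TestInvariance:
    @staticmethod
    def transform(coords, rot_deg, t, s):
        th = math.radians(rot_deg)
        rm = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        return s * coords @ rm.T + t

    @pytest.mark.parametrize("name", ["ANB", "SNA", "SNB", "FMA"])
    def test_angles_similarity_invariant(self, name, scheme, space1200):
        defs = default_measures()
        ls = build_set(scheme, space1200, {})
        base = compute_measure(defs[name], ls)
        for rot, t, s in [(30.0, (50, -20), 2.0), (-117.0, (5, 5), 0.3), (179.0, (0, 0), 1.0)]:
            coords = self.transform(ls.coords, rot, np.array(t, dtype=float), s)
            moved = LandmarkSet(scheme, space1200, coords)
            assert compute_measure(defs[name], moved) == pytest.approx(base, abs=1e-9)

    def test_fhi_scale_invariant(self, scheme, space1200):
        defs = default_measures()
        ls = build_set(scheme, space1200, {})
        base = compute_measure(defs["FHI"], ls)
        scaled = LandmarkSet(scheme, space1200, ls.coords * 3.7)
        assert compute_measure(defs["FHI"], scaled) == pytest.approx(base, abs=1e-9)

    def test_mw_scales_with_pixel_spacing(self, scheme):
        ls1 = build_set(scheme, ImageSpace(1200, 1200, mm_per_px=0.35), {})
        ls2 = LandmarkSet(ls1.scheme, ImageSpace(1200, 1200, mm_per_px=0.70), ls1.coords)
        defs = default_measures()
        assert compute_measure(defs["MW"], ls2) == pytest.approx(
            2.0 * compute_measure(defs["MW"], ls1)
        )


class TestSCR:
    def test_perfect_match_is_100(self, scheme, space1200):
        sets = [build_set(scheme, space1200, {13: (300.0 + i, 400.0)}) for i in range(5)]
        report = scr(sets, sets)
        assert set(report.scr) == set(MEASURE_NAMES)
        assert all(v == 100.0 for v in report.scr.values())

    def test_single_measure_mismatch(self, scheme, space1200):
        # ANB ~2.86 deg (type3); widen to ~7.97 deg (type2) by moving L6 only
        # changes ANB's class; keep all other landmarks identical
        gt = build_set(scheme, space1200, {5: (0, 100), 2: (0, 0), 6: (5, 100)})
        pred_coords = gt.coords.copy()
        pred_coords[5] = (14.0, 100.0)  # L6
        pred = LandmarkSet(scheme, space1200, pred_coords)
        report = scr([gt], [pred])
        assert report.scr["ANB"] == 0.0
        for unaffected in ("FHI", "FMA", "MW"):  # recipes not involving L6
            assert report.scr[unaffected] == 100.0

    def test_length_mismatch(self, scheme, space1200):
        s = [build_set(scheme, space1200, {})]
        with pytest.raises(ContractError):
            scr(s, s * 2)

    def test_matches_brute_force_loop(self, scheme, space1200):
        rng = np.random.default_rng(31)
        defs = default_measures()
        gt_sets, pred_sets = [], []
        for i in range(12):
            g = build_set(scheme, space1200, {7: tuple(rng.uniform(300, 900, 2))})
            p = LandmarkSet(scheme, space1200, g.coords + rng.normal(0, 15, (N_LANDMARKS, 2)))
            gt_sets.append(g)
            pred_sets.append(p)
        report = scr(gt_sets, pred_sets)
        for name, d in defs.items():
            matches = 0
            for g, p in zip(gt_sets, pred_sets):
                cg = classify(d, compute_measure(d, g))
                cp = classify(d, compute_measure(d, p))
                matches += cg == cp
            assert report.scr[name] == pytest.approx(100.0 * matches / 12)
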