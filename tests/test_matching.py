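"""Curve distances, the strict 10 mm criterion, count columns and maps."""

import numpy as np
import pytest

from endocompare.curves import CurveSet, LabeledCurve
from endocompare.matching import (MatchReport, ScalarField, curve_distance,
                                  displacement_map, distance_field, match_curves,
                                  summarize)

import trimesh


def line(p0, p1, n=20, label="s", side="unassigned"):
    t = np.linspace(0, 1, n)[:, None]
    return LabeledCurve(points=np.asarray(p0) + t * (np.asarray(p1) - np.asarray(p0)),
                        label=label, side=side)


# ---------------------------------------------------------------------------
# brute-force oracle: dense resampling + vertex-to-vertex minima


def oracle_mean_distance(endo, brains, step=0.01):
    from endocompare.geometry import resample_polyline
    if not brains:
        return None
    dense = [resample_polyline(b.points, step) for b in brains]
    cloud = np.vstack(dense)
    d = np.linalg.norm(endo.points[:, None, :] - cloud[None, :, :], axis=2).min(axis=1)
    return float(d.mean())


def oracle_counts(endo, brain, tau):
    matched = 0
    for c in endo:
        same = [b for b in brain if b.label == c.label and c.label != "unlabeled"]
        d = oracle_mean_distance(c, same)
        matched += d is not None and d < tau
    labels = lambda cs: len({c.label for c in cs if c.label != "unlabeled"})
    return {
        "TC-E": len(endo), "NS-E": labels(endo), "TC-B": len(brain),
        "NS-B": labels(brain), "NC-EB": matched, "NS-EB": len(endo) - matched,
    }


# ---------------------------------------------------------------------------


class TestCurveDistance:
    def test_identical_curves_zero(self):
        c = line([0, 0, 0], [10, 0, 0])
        assert curve_distance(c, [c]) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_translate_equals_offset(self):
        a = line([0, 0, 0], [10, 0, 0])
        b = line([0, 3, 0], [10, 3, 0])
        assert curve_distance(b, [a]) == pytest.approx(3.0, abs=1e-12)

    def test_mean_of_pointwise_minima(self):
        # two endocast points at 2 mm and 4 mm from the brain segment
        brain = line([0, 0, 0], [10, 0, 0])
        endo = LabeledCurve(points=np.array([[5.0, 2.0, 0.0], [5.0, 4.0, 0.0]]), label="s")
        assert curve_distance(endo, [brain]) == pytest.approx(3.0, abs=1e-12)

    def test_absent_when_no_same_label_curve(self):
        c = line([0, 0, 0], [10, 0, 0])
        assert curve_distance(c, []) is None

    def test_label_mismatch_rejected(self):
        c = line([0, 0, 0], [10, 0, 0], label="a")
        other = line([0, 0, 0], [10, 0, 0], label="b")
        with pytest.raises(ValueError):
            curve_distance(c, [other])

    def test_directional_asymmetry(self):
        # short curve near a long one: endocast->brain differs from brain->endocast
        short = line([0, 1, 0], [2, 1, 0], label="s")
        long_ = line([0, 0, 0], [30, 0, 0], label="s")
        d_sb = curve_distance(short, [long_])
        d_bs = curve_distance(long_, [short])
        assert d_sb == pytest.approx(1.0, abs=1e-9)
        assert d_bs > 5 * d_sb  # far tail of the long curve dominates

    def test_fragments_used_jointly(self):
        # a brain curve split into two fragments must behave like the whole
        endo = line([0, 1, 0], [10, 1, 0], label="s", n=41)
        whole = line([0, 0, 0], [10, 0, 0], label="s")
        frag1 = line([0, 0, 0], [5, 0, 0], label="s")
        frag2 = line([5, 0, 0], [10, 0, 0], label="s")
        assert curve_distance(endo, [whole]) == pytest.approx(
            curve_distance(endo, [frag1, frag2]), abs=1e-9
        )


class TestMatchCurves:
    def test_identical_sets_all_matched(self):
        cs = CurveSet(curves=[line([0, 0, 0], [10, 0, 0], label="a"),
                              line([0, 5, 0], [10, 5, 0], label="b")])
        rep = match_curves(cs, cs)
        assert rep.NC_EB == rep.TC_E == 2
        assert rep.NS_EB == 0

    def test_exactly_tau_is_not_matched(self):
        brain = CurveSet(curves=[line([0, 0, 0], [10, 0, 0], label="a")])
        endo = CurveSet(curves=[line([0, 10.0, 0], [10, 10.0, 0], label="a")])
        rep = match_curves(endo, brain, tau=10.0)
        assert rep.per_curve[0].mean_distance == pytest.approx(10.0, abs=1e-12)
        assert not rep.per_curve[0].matched
        assert rep.NS_EB == 1

    def test_just_under_tau_is_matched(self):
        brain = CurveSet(curves=[line([0, 0, 0], [10, 0, 0], label="a")])
        endo = CurveSet(curves=[line([0, 9.999, 0], [10, 9.999, 0], label="a")])
        assert match_curves(endo, brain, tau=10.0).NC_EB == 1

    def test_order_invariance(self, rng):
        curves = [line([0, i, 0], [10, i, 0], label=f"l{i % 3}") for i in range(6)]
        endo = CurveSet(curves=curves)
        brain = CurveSet(curves=[line([0, i, 0.5], [10, i, 0.5], label=f"l{i % 3}") for i in range(6)])
        rep1 = match_curves(endo, brain)
        perm = rng.permutation(6)
        rep2 = match_curves(CurveSet(curves=[curves[i] for i in perm]), brain)
        assert rep1.counts == rep2.counts

    def test_split_brain_fragments_invariance(self):
        endo = CurveSet(curves=[line([0, 1, 0], [20, 1, 0], label="s", n=41)])
        whole = CurveSet(curves=[line([0, 0, 0], [20, 0, 0], label="s", n=41)])
        split = CurveSet(curves=[line([0, 0, 0], [9, 0, 0], label="s"),
                                 line([9, 0, 0], [20, 0, 0], label="s")])
        d1 = match_curves(endo, whole).per_curve[0].mean_distance
        d2 = match_curves(endo, split).per_curve[0].mean_distance
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_counts_against_bruteforce_oracle(self, rng):
        labels = ["a", "b", "c"]
        for _ in range(25):
            def rand_set(n):
                out = []
                for _k in range(n):
                    p0 = rng.uniform(-10, 10, 3)
                    p1 = p0 + rng.uniform(-12, 12, 3)
                    while np.linalg.norm(p1 - p0) < 1e-3:
                        p1 = p0 + rng.uniform(-12, 12, 3)
                    out.append(line(p0, p1, n=8, label=labels[rng.integers(len(labels))]))
                return CurveSet(curves=out)

            endo = rand_set(int(rng.integers(1, 6)))
            brain = rand_set(int(rng.integers(1, 6)))
            rep = match_curves(endo, brain, tau=6.0)
            assert rep.counts == oracle_counts(endo, brain, tau=6.0)

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            MatchReport(per_curve=[], TC_E=2, NS_E=3, TC_B=2, NS_B=1, NC_EB=1, NS_EB=1)


class TestSummarize:
    ROWS = [
        {"name": "I1", "TC-E": 139, "NS-E": 15, "TC-B": 149, "NS-B": 17, "NC-EB": 110, "NS-EB": 10},
        {"name": "I2", "TC-E": 169, "NS-E": 18, "TC-B": 153, "NS-B": 17, "NC-EB": 118, "NS-EB": 23},
        {"name": "I3", "TC-E": 178, "NS-E": 16, "TC-B": 193, "NS-B": 19, "NC-EB": 165, "NS-EB": 5},
        {"name": "I4", "TC-E": 152, "NS-E": 18, "TC-B": 165, "NS-B": 17, "NC-EB": 118, "NS-EB": 16},
        {"name": "I5", "TC-E": 249, "NS-E": 17, "TC-B": 174, "NS-B": 18, "NC-EB": 204, "NS-EB": 15},
    ]

    def test_published_count_rows_mean(self):
        df = summarize(self.ROWS)
        mean = df[df.specimen == "Mean"].iloc[0]
        assert mean["NC-EB"] == 143
        assert mean["TC-B"] == 167
        assert mean["NS-EB"] == 14
        assert mean["NS-E"] == 17
        assert mean["NS-B"] == 18

    def test_mean_matched_ratio_is_80_percent(self):
        df = summarize(self.ROWS)
        mean_ratio = df[df.specimen == "Mean"].iloc[0]["ratio"]
        assert round(100 * mean_ratio) == 80
        assert (df[df.specimen != "Mean"]["ratio"] > 0.69).all()

    def test_single_report_mean_equals_row(self):
        df = summarize(self.ROWS[:1])
        row, mean = df.iloc[0], df.iloc[1]
        for k in ("TC-E", "NC-EB", "NS-EB"):
            assert row[k] == mean[k]


class TestScalarMaps:
    def _mesh(self):
        return trimesh.creation.icosphere(subdivisions=3, radius=20.0)

    def _report(self, curves, matched_dists):
        from endocompare.matching import CurveMatch
        per = [CurveMatch(curve_id=i, label=c.label, mean_distance=d, matched=d is not None and d < 10)
               for i, (c, d) in enumerate(zip(curves, matched_dists))]
        nm = sum(p.matched for p in per)
        return MatchReport(per_curve=per, TC_E=len(per), NS_E=len(per), TC_B=len(per),
                           NS_B=len(per), NC_EB=nm, NS_EB=len(per) - nm)

    def test_vertex_on_curve_gets_curve_distance(self):
        mesh = self._mesh()
        v = np.asarray(mesh.vertices)
        pts = v[:5] + 0  # polyline through actual vertices
        c = LabeledCurve(points=pts, label="a")
        cs = CurveSet(curves=[c])
        rep = self._report([c], [4.0])
        f = distance_field(mesh, rep, cs, influence_radius=10.0)
        assert f.mask[0]
        assert f.values[0] == pytest.approx(4.0, abs=1e-6)

    def test_constant_when_all_distances_equal(self):
        mesh = self._mesh()
        v = np.asarray(mesh.vertices)
        c1 = LabeledCurve(points=v[:5], label="a")
        c2 = LabeledCurve(points=v[100:105], label="b")
        cs = CurveSet(curves=[c1, c2])
        rep = self._report([c1, c2], [3.0, 3.0])
        f = distance_field(mesh, rep, cs, influence_radius=1e6)
        assert np.allclose(f.values[f.mask], 3.0, atol=1e-9)

    def test_no_overshoot(self, rng):
        mesh = self._mesh()
        v = np.asarray(mesh.vertices)
        curves, dists = [], []
        for k in range(4):
            i = int(rng.integers(0, len(v) - 6))
            curves.append(LabeledCurve(points=v[i:i + 5], label=f"l{k}"))
            dists.append(float(rng.uniform(1, 9)))
        cs = CurveSet(curves=curves)
        f = distance_field(mesh, self._report(curves, dists), cs, influence_radius=15.0)
        got = f.values[f.mask]
        assert got.min() >= min(dists) - 1e-9
        assert got.max() <= max(dists) + 1e-9

    def test_vertices_near_unmatched_curve_masked(self):
        mesh = self._mesh()
        v = np.asarray(mesh.vertices)
        c1 = LabeledCurve(points=v[:5], label="a")
        c2 = LabeledCurve(points=v[300:305], label="b")
        cs = CurveSet(curves=[c1, c2])
        rep = self._report([c1, c2], [3.0, 20.0])  # second fails the criterion
        f = distance_field(mesh, rep, cs, influence_radius=10.0)
        assert not f.mask[300]
        assert f.mask[0]

    def test_displacement_identical_meshes_zero(self):
        mesh = self._mesh()
        raw, clipped = displacement_map(mesh, mesh)
        assert np.allclose(raw.values, 0.0, atol=1e-9)

    def test_displacement_inflated_sphere(self):
        inner = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
        outer = trimesh.creation.icosphere(subdivisions=4, radius=22.0)
        raw, clipped = displacement_map(inner, outer)
        assert np.all(np.abs(raw.values - 2.0) < 0.05)

    def test_clip_contract(self):
        inner = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
        outer = trimesh.creation.icosphere(subdivisions=3, radius=28.0)
        raw, clipped = displacement_map(inner, outer, render_clip=5.0)
        assert np.all(raw.values >= clipped.values - 1e-12)
        assert np.all(clipped.values <= 5.0 + 1e-12)

    def test_scalar_field_rejects_negative_values(self):
        with pytest.raises(ValueError):
            ScalarField(values=np.array([-1.0]), mask=np.array([True]))
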