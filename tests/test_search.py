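"""Surface patterns, safety checks and the constrained geometry search."""

import numpy as np
import pytest

import drsopt as d
from drsopt.search import GridSpec


class TestPatterns:
    def test_point_power_density_matches_instrument(self):
        src = d.point_source(power_mw=45.0, diameter=0.1)
        assert d.power_density(src) == pytest.approx(45.0 / (np.pi * 0.05**2))
        # ~5700 mW/mm² to two significant figures
        assert round(d.power_density(src), -2) == 5700.0

    def test_line_power_densities(self):
        built = d.line_source(width=1.5)  # the Powell-lens instrument line
        modelled = d.line_source(width=2.0)
        assert d.power_density(built) == pytest.approx(3.0)
        assert d.power_density(modelled) == pytest.approx(2.25)

    def test_mpe_check(self):
        passes, margin = d.mpe_check(d.line_source(width=1.5))
        assert passes and margin == pytest.approx(0.0, abs=1e-9)
        assert not d.mpe_check(d.point_source())[0]
        assert d.mpe_check(d.point_source(power_mw=0.0))[0]

    def test_containment_and_disjointness(self):
        line = d.line_source()
        assert line.within_search_area()
        far = d.rectangle_detector((4.9, 0.0), length=10.0, width=2.0)
        assert not far.within_search_area()
        rect = d.rectangle_detector((2.5, 0.0))
        assert line.disjoint_from(rect)
        assert not line.disjoint_from(d.rectangle_detector((1.5, 0.0)))

    def test_areas(self):
        assert d.point_detector().area == pytest.approx(0.01)
        assert d.line_source().area == pytest.approx(20.0)
        assert d.SurfacePattern("disk", radius=3.0).area == pytest.approx(np.pi * 9)

    def test_sample_points_cover_shape(self):
        pts = d.line_source().sample_points()
        assert np.abs(pts[:, 0]).max() <= 1.0
        assert np.abs(pts[:, 1]).max() <= 5.0
        assert len(pts) > 10
        assert len(d.point_source().sample_points()) == 1


class TestGrid:
    def test_441_positions(self):
        grid = GridSpec()
        pos = grid.positions()
        assert len(pos) == 441
        assert grid.pitch == pytest.approx(0.5)
        assert pos.min() == -5.0 and pos.max() == 5.0


class TestSNRSurface:
    def test_point_reflection_symmetry(self, point_surface):
        s = point_surface.snr
        asym = np.abs(s - s[::-1, ::-1]).max() / s.max()
        assert asym < 0.01

    def test_argmax_off_centre(self, point_surface):
        # the optimum detector is radially offset from the excitation spot
        assert point_surface.argmax_offset > 0.0
        assert point_surface.snr[10, 10] < point_surface.max_snr

    def test_matches_per_point_oracle(self, optimizer, point_surface, disc,
                                      solver, refs):
        # element-wise recomputation through yield_table + compute_snr
        for pos in [(1.0, 0.0), (2.5, -1.5), (0.0, 3.0), (-4.0, 4.0)]:
            table = d.yield_table(disc, solver.optics, d.point_source(),
                                  d.point_detector(pos), solver=solver)
            oracle = d.compute_snr(table, refs)
            assert point_surface.result_at(*pos).snr == pytest.approx(
                oracle.snr, rel=1e-10)

    def test_offset_implant_skews_surface(self, refs):
        # breaking the phantom symmetry shifts SNR toward the implant side
        ph = d.build_phantom(implant_center=(2.0, 0.0))
        disc = d.build_discretization(ph)
        solver = d.DiffusionSolver(disc, d.default_optics())
        opt = d.GeometryOptimizer(solver, refs)
        surf = opt.snr_surface(d.point_source())
        right = surf.snr[11:, :].sum()
        left = surf.snr[:10, :].sum()
        assert right > left
        assert surf.argmax_position[0] > 0


class TestDetectorIntegration:
    def test_single_point_rectangle_equals_point(self, line_surface, optimizer):
        rect = d.rectangle_detector((2.5, 0.0), length=0.1, width=0.1)
        r = optimizer.integrate_detector_area(line_surface, rect)
        p = line_surface.result_at(2.5, 0.0)
        assert r.snr == pytest.approx(p.snr, rel=1e-12)

    def test_symmetric_pair_is_sqrt2(self, line_surface, optimizer):
        a = optimizer.integrate_detector_area(
            line_surface, d.rectangle_detector((2.5, 0.0)))
        b = optimizer.integrate_detector_area(
            line_surface, d.rectangle_detector((-2.5, 0.0)))
        pair = d.combine_detectors([a, b])
        assert pair.snr == pytest.approx(np.sqrt(2) * a.snr, rel=1e-9)

    def test_column_rectangle_equals_explicit_combination(self, line_surface,
                                                          optimizer):
        # 21 grid points in a narrow column, combined by hand
        rect = d.rectangle_detector((2.5, 0.0), length=10.0, width=0.4)
        r = optimizer.integrate_detector_area(line_surface, rect)
        ax = line_surface.grid.axis()
        i = int(np.argmin(np.abs(ax - 2.5)))
        parts = [(line_surface.signal[i, j], line_surface.noise[i, j])
                 for j in range(21)]
        assert len(parts) == 21
        manual = d.combine_detectors(parts)
        assert r.snr == pytest.approx(manual.snr, rel=1e-12)

    def test_empty_rectangle_rejected(self, line_surface, optimizer):
        with pytest.raises(ValueError):
            optimizer.integrate_detector_area(
                line_surface, d.rectangle_detector((2.6, 2.6),
                                                   length=0.1, width=0.1))


class TestFiberBundle:
    def test_equals_explicit_point_combination(self, optimizer):
        src = d.line_source()
        bundle = optimizer.fiber_subset_snr(src, offset_mm=1.5)
        singles = [optimizer.fiber_subset_snr(src, offset_mm=1.5, n_fibers=1,
                                              span=(y, y))
                   for y in np.linspace(-0.5, 0.5, 7)]
        manual = d.combine_detectors(singles)
        assert bundle.snr == pytest.approx(manual.snr, rel=1e-10)

    def test_doubling_to_symmetric_pair(self, optimizer):
        src = d.line_source()
        one = optimizer.fiber_subset_snr(src, offset_mm=1.5)
        pair = d.combine_detectors([
            one, optimizer.fiber_subset_snr(src, offset_mm=-1.5)])
        assert pair.snr == pytest.approx(np.sqrt(2) * one.snr, rel=1e-6)


class TestOptimize:
    def test_single_candidate_returned(self, optimizer):
        src = d.line_source()
        det = d.rectangle_detector((2.5, 0.0))
        ranked = optimizer.optimize([("only", src, (det,))])
        assert len(ranked) == 1 and ranked[0].name == "only"
        assert ranked[0].feasible

    def test_line_outranks_point_under_mpe(self, optimizer):
        ranked = optimizer.optimize()
        top = ranked[0]
        assert top.feasible and top.source.shape == "line"
        pp = next(c for c in ranked if c.name == "point-point")
        assert not pp.mpe_pass  # 45 mW on a 0.1 mm spot exceeds the skin MPE
        assert ranked.index(top) < ranked.index(pp)

    def test_top_rank_matches_re_evaluation(self, optimizer, line_surface):
        ranked = optimizer.optimize()
        top = ranked[0]
        parts = [optimizer.integrate_detector_area(line_surface, det)
                 for det in top.detectors]
        again = d.combine_detectors(parts)
        assert top.result.snr == pytest.approx(again.snr, rel=1e-10)

    def test_reported_optima_satisfy_constraints(self, optimizer):
        for cand in optimizer.optimize():
            if cand.feasible:
                assert cand.mpe_pass
                assert all(cand.source.disjoint_from(det)
                           for det in cand.detectors)

    def test_infeasible_set_rejected(self, optimizer):
        src = d.point_source()  # fails MPE at 45 mW
        det = d.point_detector((1.5, 0.0))
        with pytest.raises(RuntimeError):
            optimizer.optimize([("bad", src, (det,))])
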