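"""Stripe tracing, event measurement, coverage accumulation, Gaussian fit."""

import numpy as np
import pytest

from crystafm import kinetics as kin
from crystafm import synthetic as syn
from crystafm.core import Lattice2D


@pytest.fixture
def lattice():
    return Lattice2D(10.8, 6.6, 100.0, origin=(2.0, 2.0))


def render(stripes, lattice, blur=0.0, noise=0.0, seed=0):
    scan = syn.ScanParams(tip_blur_sigma=blur, noise_sigma=noise, seed=seed)
    return syn.render_topograph(
        stripes, syn.RepeatUnitTemplate(), syn.LayerModel(), lattice, scan
    )


def make_trace(row, lo, hi, frame=0, stripe_id=0, pitch=3.6):
    return kin.StripeTrace(
        frame=frame, stripe_id=stripe_id, row=row, slot_lo=lo, slot_hi=hi,
        polyline=np.array([[lo * pitch, 0], [hi * pitch, 0]]),
        length=(hi - lo) * pitch,
    )


class TestTraceStripes:
    def test_programmed_stripes_found(self, lattice):
        stripes = [syn.Stripe(0, 8, 5, 15), syn.Stripe(1, 10, 8, 20),
                   syn.Stripe(2, 12, 3, 10)]
        topo = render(stripes, lattice, blur=0.5)
        traces = kin.trace_stripes(topo, lattice)
        assert sorted(t.row for t in traces) == [8, 10, 12]
        by_row = {t.row: t for t in traces}
        for s in stripes:
            assert by_row[s.row].slot_lo == s.slot_lo
            assert by_row[s.row].slot_hi == s.slot_hi

    def test_bare_membrane_empty(self, lattice):
        topo = render([], lattice, blur=0.5, noise=0.1, seed=5)
        assert kin.trace_stripes(topo, lattice) == []

    def test_trace_length_is_slots_times_pitch(self, lattice):
        topo = render([syn.Stripe(0, 9, 4, 14)], lattice, blur=0.5)
        traces = kin.trace_stripes(topo, lattice)
        assert len(traces) == 1
        assert traces[0].length == pytest.approx(10 * 3.6, abs=topo.pixel_size)


class TestMatchAndMeasure:
    def test_single_end_growth(self, lattice):
        t0 = [make_trace(0, 0, 14)]  # 50.4 nm
        t1 = [make_trace(0, 0, 17)]  # 61.2 nm
        recs = kin.match_and_measure(t0, t1, lattice=lattice)
        assert len(recs) == 1
        assert recs[0].association == pytest.approx([3 * 3.6])
        assert recs[0].dissociation == []

    def test_split_counts_gap_as_dissociation(self, lattice):
        t0 = [make_trace(0, 0, 10)]
        t1 = [make_trace(0, 0, 4), make_trace(0, 6, 10, stripe_id=1)]
        recs = kin.match_and_measure(t0, t1, lattice=lattice)
        assert len(recs) == 1
        assert recs[0].dissociation == pytest.approx([2 * 3.6])
        assert recs[0].association == []

    def test_new_and_vanished_traces(self, lattice):
        t0 = [make_trace(0, 0, 5, stripe_id=0)]
        t1 = [make_trace(3, 10, 14, stripe_id=7)]
        recs = kin.match_and_measure(t0, t1, lattice=lattice)
        by_id = {r.stripe_id: r for r in recs}
        assert by_id[0].dissociation == pytest.approx([5 * 3.6])
        new = [r for r in recs if r.stripe_id != 0]
        assert len(new) == 1
        assert new[0].association == pytest.approx([4 * 3.6])

    def test_oracle_equivalence_with_generator_log(self, lattice):
        growth = syn.GrowthParams(k_assoc=1.0, k_dissoc=0.6, k_nucleate=0.0)
        # slot limits keep every admissible site inside the field of view
        movie, log = syn.simulate_growth(
            lattice, growth, n_frames=12, seed=21,
            init_stripes=[syn.Stripe(0, 8, 10, 20), syn.Stripe(1, 11, 12, 22)],
            slot_limits=(5, 30),
        )
        scan = syn.ScanParams(tip_blur_sigma=0.0, noise_sigma=0.0)
        layers = syn.LayerModel()
        tmpl = syn.RepeatUnitTemplate()
        for fr in range(movie.n_frames - 1):
            a = kin.trace_stripes(
                syn.render_topograph(movie.frames[fr], tmpl, layers, lattice, scan),
                lattice, frame=fr)
            b = kin.trace_stripes(
                syn.render_topograph(movie.frames[fr + 1], tmpl, layers, lattice, scan),
                lattice, frame=fr + 1)
            recs = kin.match_and_measure(a, b, lattice=lattice)
            sub = log[log.frame == fr + 1]
            assert sum(sum(r.association) for r in recs) == pytest.approx(
                sub[sub.event.isin(["assoc", "nucleate"])].length_nm.sum())
            assert sum(sum(r.dissociation) for r in recs) == pytest.approx(
                sub[sub.event == "dissoc"].length_nm.sum())

    def test_conservation_identity(self, lattice):
        growth = syn.GrowthParams(k_assoc=1.1, k_dissoc=0.8, k_nucleate=0.1)
        movie, _ = syn.simulate_growth(
            lattice, growth, n_frames=20, seed=4,
            init_stripes=[syn.Stripe(0, 9, 10, 18)], slot_limits=(5, 28),
        )
        scan = syn.ScanParams(tip_blur_sigma=0.0, noise_sigma=0.0)
        tmpl, layers = syn.RepeatUnitTemplate(), syn.LayerModel()
        traced = [
            kin.trace_stripes(
                syn.render_topograph(f, tmpl, layers, lattice, scan), lattice,
                frame=i)
            for i, f in enumerate(movie.frames)
        ]
        total = lambda traces: sum(t.length for t in traces)
        net = 0.0
        for i in range(len(traced) - 1):
            recs = kin.match_and_measure(traced[i], traced[i + 1], lattice=lattice)
            net += sum(sum(r.association) - sum(r.dissociation) for r in recs)
        assert total(traced[-1]) - total(traced[0]) == pytest.approx(net)


class TestCoverage:
    def test_running_sum(self):
        r1 = kin.KineticsRecord(0, 1, 0, association=[10.0], dissociation=[])
        r2 = kin.KineticsRecord(1, 2, 0, association=[5.0], dissociation=[3.0])
        series = kin.cumulative_coverage([[r1], [r2]])
        np.testing.assert_allclose(series.coverage, [10.0, 12.0])

    def test_all_zero(self):
        recs = [[kin.KineticsRecord(i, i + 1, 0)] for i in range(4)]
        series = kin.cumulative_coverage(recs)
        np.testing.assert_allclose(series.coverage, 0.0)

    def test_negative_increment_allowed(self):
        r = kin.KineticsRecord(0, 1, 0, association=[2.0], dissociation=[9.0])
        series = kin.cumulative_coverage([[r]])
        assert series.coverage[0] == pytest.approx(-7.0)


class TestUnitSizeStats:
    def test_uniform_events(self):
        recs = [kin.KineticsRecord(0, 1, 0, association=[3.6, 3.6, 3.6])]
        stats = kin.unit_size_stats(recs)
        assert stats["association"].median == pytest.approx(3.6)
        assert stats["association"].notch == 0.0
        assert stats["dissociation"] is None

    def test_median_of_three(self):
        recs = [kin.KineticsRecord(0, 1, 0, association=[3.6, 7.2, 10.8])]
        assert kin.unit_size_stats(recs)["association"].median == pytest.approx(7.2)

    def test_generator_event_length_median(self, lattice):
        # Monte-Carlo: Poisson(1.2) net events/end/frame; compare measured
        # median against the median of the ground-truth log itself
        growth = syn.GrowthParams(k_assoc=1.2, k_dissoc=0.4, k_nucleate=0.0)
        _, log = syn.simulate_growth(
            lattice, growth, n_frames=60, seed=13,
            init_stripes=[syn.Stripe(0, 8, 40, 50)], slot_limits=(0, 100),
        )
        assoc = log[log.event == "assoc"].length_nm
        recs = [
            kin.KineticsRecord(0, 1, 0, association=list(assoc), dissociation=[])
        ]
        stats = kin.unit_size_stats(recs)
        assert stats["association"].median == pytest.approx(np.median(assoc))
        assert stats["association"].n == len(assoc)


class TestGaussianFit:
    @staticmethod
    def model(x, A, c, w, o):
        return o + A * np.exp(-((x - c) ** 2) / (2 * w**2))

    def test_exact_gaussian_recovered(self):
        x = np.linspace(0, 100, 80)
        y = self.model(x, 5.0, 42.0, 8.0, 1.5)
        fit = kin.gaussian_fit(x, y)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-6)
        assert fit.center == pytest.approx(42.0, abs=1e-6)
        assert fit.width == pytest.approx(8.0, abs=1e-6)
        assert fit.offset == pytest.approx(1.5, abs=1e-6)
        assert fit.residual_norm < 1e-8

    def test_noise_shrinks_errors(self):
        x = np.linspace(0, 100, 200)
        rng = np.random.default_rng(2)
        noise = rng.normal(size=x.size)
        errs = []
        for sigma in (0.5, 0.05):
            y = self.model(x, 5.0, 42.0, 8.0, 1.5) + sigma * noise
            fit = kin.gaussian_fit(x, y)
            errs.append(abs(fit.center - 42.0) + abs(fit.width - 8.0))
        assert errs[1] < errs[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kin.gaussian_fit([0, 1, 2, 3], [0, 1, 0, 0])
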