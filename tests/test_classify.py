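"""Channel totals, protein signature fitting, and strain classification."""

import math

import numpy as np
import pytest

from colonylapse import (
    ChannelTotals,
    GrowthModelFit,
    ProteinSignature,
    Timelapse,
    channel_totals,
    classify_colonies,
    fit_signature,
    load_signatures,
    save_signatures,
)
from colonylapse.detect import SquareROI


def _tot(i, R, G, B=0.0):
    return ChannelTotals(colony_id=i, R_total=R, G_total=G, B_total=B)


def _sig(label, slope):
    return ProteinSignature(label=label, slope=slope, angle=math.atan(slope), n_colonies=2)


def _flat_fit(Amax, t0=-50.0):
    return GrowthModelFit(
        colony_id=0, Amax=Amax, mu_max=0.5, t0=t0, residual_rms=0.0, n_points_used=10
    )


class TestChannelTotals:
    def test_uniform_mask_totals(self):
        frames = np.zeros((2, 40, 40, 3))
        frames[:, :, :] = (10.0, 20.0, 0.0)
        stack = Timelapse(frames=frames, times=np.arange(2.0))
        roi = SquareROI(0, (20.0, 20.0), 15, (5, 36), (5, 36))
        fit = _flat_fit(Amax=200.0)
        tot = channel_totals(stack, roi, fit, (20.0, 20.0))
        from colonylapse.expression import circle_mask

        n = circle_mask((31, 31), (15.0, 15.0), fit.radius(1.0)).sum()
        assert tot.R_total == 10.0 * n
        assert tot.G_total == 20.0 * n
        assert tot.B_total == 0.0

    def test_time_sum_reference(self):
        frames = np.zeros((3, 40, 40, 3))
        frames[:, :, :] = (5.0, 1.0, 2.0)
        stack = Timelapse(frames=frames, times=np.arange(3.0))
        roi = SquareROI(0, (20.0, 20.0), 15, (5, 36), (5, 36))
        fit = _flat_fit(Amax=200.0)
        endpoint = channel_totals(stack, roi, fit, (20.0, 20.0), reference="endpoint")
        summed = channel_totals(stack, roi, fit, (20.0, 20.0), reference="time_sum")
        assert summed.R_total == 3 * endpoint.R_total

    def test_background_only_roi_zero(self):
        stack = Timelapse(frames=np.zeros((2, 30, 30, 3)), times=np.arange(2.0))
        roi = SquareROI(0, (15.0, 15.0), 10, (5, 26), (5, 26))
        tot = channel_totals(stack, roi, _flat_fit(Amax=100.0), (15.0, 15.0))
        assert tot.R_total == tot.G_total == tot.B_total == 0.0

    def test_matches_pixel_loop_oracle(self, single_colony_plate, single_colony_roi):
        corrected, _, _ = single_colony_plate
        fit = _flat_fit(Amax=900.0, t0=1.0)
        tot = channel_totals(corrected, single_colony_roi, fit, (60.0, 60.0))
        radius = fit.radius(corrected.times[-1])
        roi = single_colony_roi
        sums = [0.0, 0.0, 0.0]
        for r in range(roi.row_range[0], roi.row_range[1]):
            for c in range(roi.col_range[0], roi.col_range[1]):
                if (r - 60.0) ** 2 + (c - 60.0) ** 2 <= radius**2:
                    for ch in range(3):
                        sums[ch] += corrected.frames[-1, r, c, ch]
        assert (tot.R_total, tot.G_total, tot.B_total) == tuple(sums)


class TestFitSignature:
    def test_exact_line(self):
        totals = [_tot(i, R, 2.0 * R) for i, R in enumerate([10, 20, 50])]
        sig = fit_signature(totals, "gfp")
        assert np.isclose(sig.slope, 2.0)
        assert np.isclose(sig.angle, math.atan(2.0))
        assert sig.n_colonies == 3

    def test_single_colony_rejected(self):
        with pytest.raises(ValueError, match="insufficient colonies"):
            fit_signature([_tot(0, 10, 20)], "gfp")

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="insufficient colonies"):
            fit_signature([_tot(0, 0, 0), _tot(1, 0, 0)], "gfp")

    def test_least_squares_slope(self):
        """Through-origin slope equals sum(RG)/sum(R^2), checked against
        a brute-force scan of the objective."""
        rng = np.random.default_rng(8)
        R = rng.uniform(10, 100, 12)
        G = 1.7 * R + rng.normal(0, 3, 12)
        totals = [_tot(i, r, max(g, 0)) for i, (r, g) in enumerate(zip(R, G))]
        sig = fit_signature(totals, "x")
        slopes = np.linspace(sig.slope - 0.2, sig.slope + 0.2, 2001)
        Ru = np.array([t.R_total for t in totals])
        Gu = np.array([t.G_total for t in totals])
        sse = ((Gu[None, :] - slopes[:, None] * Ru[None, :]) ** 2).sum(axis=1)
        assert abs(slopes[np.argmin(sse)] - sig.slope) <= 1e-3


class TestClassify:
    SIGS = [_sig("a_high", 2.5), _sig("b_mid", 1.0), _sig("c_low", 0.35)]

    def test_on_line_colony(self):
        res = classify_colonies([_tot(0, 10.0, 25.0)], self.SIGS)
        assert res[0].assigned_label == "a_high"
        assert res[0].angular_distance == 0.0

    def test_tie_goes_to_first_label(self):
        sigs = [_sig("beta", 1.0), _sig("alpha", 3.0)]
        mid = math.tan((math.atan(1.0) + math.atan(3.0)) / 2)
        res = classify_colonies([_tot(0, 10.0, 10.0 * mid)], sigs)
        assert res[0].assigned_label == "alpha"
        assert res[0].runner_up_margin <= 1e-12

    def test_zero_signal_unclassifiable(self):
        res = classify_colonies([_tot(0, 0.0, 0.0)], self.SIGS)
        assert res[0].assigned_label is None

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            R, G = rng.uniform(1, 100, 2)
            c = rng.uniform(0.01, 100)
            r0 = classify_colonies([_tot(0, R, G)], self.SIGS)[0]
            r1 = classify_colonies([_tot(0, c * R, c * G)], self.SIGS)[0]
            assert r0.assigned_label == r1.assigned_label

    def test_signature_order_irrelevant(self):
        rng = np.random.default_rng(6)
        totals = [
            _tot(i, r, g) for i, (r, g) in enumerate(rng.uniform(5, 80, (15, 2)))
        ]
        a = classify_colonies(totals, self.SIGS)
        b = classify_colonies(totals, list(reversed(self.SIGS)))
        assert [x.assigned_label for x in a] == [x.assigned_label for x in b]

    def test_training_self_consistency(self):
        """Colonies drawn around well-separated lines classify back to
        their own signature."""
        rng = np.random.default_rng(9)
        slopes = {"a_high": 2.5, "b_mid": 1.0, "c_low": 0.35}
        sigs, totals, expected = [], [], []
        i = 0
        for label, slope in slopes.items():
            R = rng.uniform(200, 2000, 10)
            G = slope * R + rng.normal(0, 2.0, 10)
            sub = [_tot(i + k, r, max(g, 0)) for k, (r, g) in enumerate(zip(R, G))]
            sigs.append(fit_signature(sub, label))
            totals.extend(sub)
            expected.extend([label] * 10)
            i += 10
        res = classify_colonies(totals, sigs)
        assert [r.assigned_label for r in res] == expected

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            classify_colonies([_tot(0, 1, 1)], [_sig("x", 1.0), _sig("x", 2.0)])

    def test_no_signatures_rejected(self):
        with pytest.raises(ValueError):
            classify_colonies([_tot(0, 1, 1)], [])


class TestSignatureIO:
    def test_roundtrip(self, tmp_path):
        sigs = [_sig("gfp", 2.5), _sig("rfp", 0.35)]
        path = tmp_path / "signatures.csv"
        save_signatures(sigs, path)
        loaded = load_signatures(path)
        assert loaded == sigs
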