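import numpy as np
import pandas as pd
import pytest

from conftest import high_confidence_dyads
from nucphase.io import filter_fragment_length
from nucphase.pileup import (
    density_shift,
    dyad_composite,
    edge_profiles,
    horizontal_density,
    lattice_step_shift,
    rotate_pileup,
    signal_mode,
    verticalizing_angle,
)
from nucphase.types import FragmentSet, Signal1D


def _fs(records):
    return FragmentSet("s", pd.DataFrame(records, columns=["chrom", "start", "end"]))


def _dyads(rows):
    return pd.DataFrame(rows, columns=["chrom", "position", "strand"])


EXACT_ANGLE = float(np.degrees(np.arctan(0.5)))


class TestVerticalizingAngle:
    def test_shared_edge_slope_gives_27_degrees(self):
        assert round(verticalizing_angle(2.0)) == 27
        assert verticalizing_angle(2.0) == pytest.approx(26.565, abs=0.001)


class TestComposite:
    def test_centered_fragment_lands_at_length_150_position_0(self):
        d = 5000
        fs = _fs([("chrI", d - 75, d + 75)])
        for strand in ("+", "-"):
            comp = dyad_composite(fs, _dyads([("chrI", d, strand)]))
            assert comp.matrix[150 - comp.len_lo, comp.w] == 1
            assert comp.total == 1

    def test_lattice_offsets_appear_as_lattice_columns(self):
        d = 5000
        fs = _fs(
            [("chrI", d + off - 75, d + off + 75) for off in (-10, 0, 10)]
        )
        comp = dyad_composite(fs, _dyads([("chrI", d, "+")]))
        cols = np.flatnonzero(comp.matrix.sum(axis=0)) - comp.w
        assert list(cols) == [-10, 0, 10]

    def test_minus_orientation_flips_relative_axis(self):
        d = 5000
        fs = _fs([("chrI", d + 10 - 75, d + 10 + 75)])
        comp = dyad_composite(fs, _dyads([("chrI", d, "-")]))
        cols = np.flatnonzero(comp.matrix.sum(axis=0)) - comp.w
        assert list(cols) == [-10]

    def test_empty_dyad_set_rejected(self):
        with pytest.raises(ValueError):
            dyad_composite(_fs([("chrI", 0, 150)]), _dyads([]))


class TestRotation:
    def test_single_point_follows_rotation_matrix_oracle(self):
        # point at (x=+5, y=+10): CCW by 27 deg -> x' = 5cos27 - 10sin27 = -0.08
        d = 5000
        fs = _fs([("chrI", d + 5 - 85, d + 5 + 85)])  # length 170, midpoint d+5
        comp = dyad_composite(fs, _dyads([("chrI", d, "+")]))
        t = rotate_pileup(comp, angle_deg=27.0, rescale=False)
        ys, xs = np.nonzero(t.matrix)
        th = np.radians(27.0)
        expect_x = round(5 * np.cos(th) - 10 * np.sin(th))
        expect_y = round(5 * np.sin(th) + 10 * np.cos(th))
        assert (xs[0] + t.x_min, ys[0] + t.y_min) == (expect_x, expect_y)

    def test_left_half_rotates_clockwise(self):
        d = 5000
        fs = _fs([("chrI", d - 5 - 85, d - 5 + 85)])  # (x=-5, y=+10)
        comp = dyad_composite(fs, _dyads([("chrI", d, "+")]))
        t = rotate_pileup(comp, angle_deg=27.0, rescale=False)
        ys, xs = np.nonzero(t.matrix)
        th = np.radians(27.0)
        assert xs[0] + t.x_min == round(-5 * np.cos(th) + 10 * np.sin(th))

    @pytest.mark.parametrize("transform", ["rotation", "shear"])
    def test_slope2_diagonals_collapse_to_single_column(self, transform):
        """Shared-edge diagonals (slope +-2) must verticalize on each half."""
        d = 5000
        records = []
        for k in range(1, 12):  # right half: midpoint +k, length 160+2k
            records.append(("chrI", d + k - (160 + 2 * k) // 2, d + k + (160 + 2 * k + 1) // 2))
        fs = _fs(records)
        fs = FragmentSet("s", fs.frame.assign())
        comp = dyad_composite(fs, _dyads([("chrI", d, "+")]), len_range=(140, 200))
        angle = EXACT_ANGLE if transform == "rotation" else 27.0
        t = rotate_pileup(comp, angle_deg=angle, transform=transform)
        dens = t.matrix.sum(axis=0)
        top = dens.max()
        peak = np.argmax(dens)
        window = dens[max(0, peak - 1) : peak + 2].sum()
        assert window >= 0.95 * dens.sum()

    def test_rotation_conserves_total_signal(self, wt_small):
        fs = filter_fragment_length(wt_small.fragments, 140, 180)
        comp = dyad_composite(fs, high_confidence_dyads(wt_small))
        for transform in ("rotation", "shear"):
            t = rotate_pileup(comp, transform=transform)
            assert abs(t.total - comp.total) <= 0.01 * comp.total

    def test_empty_composite_gives_empty_transform(self):
        fs = _fs([("chrI", 100, 250)])
        comp = dyad_composite(fs, _dyads([("chrII", 5000, "+")]))
        t = rotate_pileup(comp)
        assert t.total == 0

    def test_invalid_angle_rejected(self):
        fs = _fs([("chrI", 4925, 5075)])
        comp = dyad_composite(fs, _dyads([("chrI", 5000, "+")]))
        with pytest.raises(ValueError):
            rotate_pileup(comp, angle_deg=60.0)


class TestHorizontalDensity:
    def test_single_cell_gives_delta_function(self):
        fs = _fs([("chrI", 4925, 5075)])
        comp = dyad_composite(fs, _dyads([("chrI", 5000, "+")]))
        dens = horizontal_density(rotate_pileup(comp))
        assert dens.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (dens.values > 0).sum() == 1

    def test_area_is_one(self, wt_small):
        fs = filter_fragment_length(wt_small.fragments, 140, 180)
        comp = dyad_composite(fs, high_confidence_dyads(wt_small))
        dens = horizontal_density(rotate_pileup(comp))
        assert dens.values.sum() == pytest.approx(1.0, abs=1e-9)


def brute_force_shift(a, b, max_shift):
    """Oracle: explicit-loop mean-centered cross-correlation table."""
    va = a - a.mean()
    vb = b - b.mean()
    n = len(va)
    best, best_s = -np.inf, None
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), -s)):
        cc = 0.0
        for x in range(n):
            if 0 <= x + s < n:
                cc += va[x] * vb[x + s]
        if cc > best + 1e-12:
            best, best_s = cc, s
    return best_s


class TestDensityShift:
    def _signal(self):
        rng = np.random.default_rng(0)
        base = np.zeros(201)
        for c, w in [(60, 0.2), (100, 0.6), (140, 0.2)]:
            base += w * np.exp(-0.5 * ((np.arange(201) - c) / 4.0) ** 2)
        return base / base.sum()

    def test_identical_signals_give_zero(self):
        a = self._signal()
        sig = Signal1D(a, 100, 100)
        assert density_shift(sig, sig, 30) == 0

    @pytest.mark.parametrize("shift", [10, -7, 3])
    def test_translated_signal_matches_brute_force_oracle(self, shift):
        a = self._signal()
        b = np.roll(a, shift)
        result = density_shift(Signal1D(a, 100, 100), Signal1D(b, 100, 100), 30)
        assert result == shift
        assert result == brute_force_shift(a, b, 30)

    def test_zero_variance_rejected(self):
        flat = Signal1D(np.ones(101), 50, 50)
        with pytest.raises(ValueError, match="zero-variance"):
            density_shift(flat, flat, 10)


class TestLatticeShift:
    def _bump(self, center, sd=5.5):
        x = np.arange(-150, 151)
        return np.exp(-0.5 * ((x - center) / sd) ** 2)

    def test_identical_distributions_give_zero(self):
        a = Signal1D(self._bump(0), 150, 150)
        assert lattice_step_shift(a, a) == 0

    def test_dominant_mixture_component_recovered_despite_overlap(self):
        # heavily overlapping 10 bp-spaced settings: a plain cross-correlation
        # argmax is pulled below the modal step, the decomposition is not
        a = Signal1D(self._bump(0), 150, 150)
        mix = (
            0.05 * self._bump(-10)
            + 0.25 * self._bump(0)
            + 0.70 * self._bump(10)
        )
        b = Signal1D(mix, 150, 150)
        assert lattice_step_shift(a, b) == 10

    def test_pure_translation_by_lattice_multiple(self):
        a = Signal1D(self._bump(0), 150, 150)
        b = Signal1D(self._bump(-20), 150, 150)
        assert lattice_step_shift(a, b) == -20


class TestEdges:
    def test_half_open_edge_convention(self):
        d = 5000
        fs = _fs([("chrI", d - 75, d + 75)])
        prof = edge_profiles(fs, _dyads([("chrI", d, "+")]))
        assert signal_mode(prof.upstream) == -75
        assert signal_mode(prof.downstream) == 74

    def test_edge_totals_match_fragment_count(self, wt_small):
        fs = filter_fragment_length(wt_small.fragments, 140, 180)
        prof = edge_profiles(fs, high_confidence_dyads(wt_small))
        assert prof.upstream.total() == prof.downstream.total() == prof.n_fragments

    def test_mode_tie_resolves_to_smallest_position(self):
        sig = Signal1D(np.array([0.0, 1.0, 1.0, 0.0, 0.0]), 2, 2)
        assert signal_mode(sig) == -1
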