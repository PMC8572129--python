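"""Windowed LBP registration with entropy tie-break."""

import numpy as np
import pytest

from respireg import (
    PhantomConfig,
    RegistrationError,
    SliceDescriptor,
    candidate_window,
    generate_phantom,
    ground_truth_match,
    register_phase,
    register_slice,
)

from conftest import SMALL_CONFIG, SMALL_RANGE


def make_descriptor(hot_bin: int, entropy: float) -> SliceDescriptor:
    hist = np.zeros(256)
    hist[hot_bin] = 1.0
    return SliceDescriptor(lbp_histogram=hist, entropy=entropy, n_pixels=100)


def blend_descriptor(a: int, b: int, w: float, entropy: float) -> SliceDescriptor:
    hist = np.zeros(256)
    hist[a] = 1.0 - w
    hist[b] = w
    return SliceDescriptor(lbp_histogram=hist, entropy=entropy, n_pixels=100)


class TestCandidateWindow:
    def test_margin_five_around_mid_slice(self):
        # 0-based slice 59 with margin 5 spans 54..64 (1-based 55..65)
        assert list(candidate_window(59, 5, 92)) == list(range(54, 65))

    def test_clipped_at_volume_start(self):
        assert list(candidate_window(0, 5, 92)) == list(range(0, 6))

    def test_zero_margin(self):
        assert list(candidate_window(10, 0, 92)) == [10]

    def test_out_of_range_target(self):
        with pytest.raises(IndexError):
            candidate_window(92, 5, 92)


class TestRegisterSlice:
    def test_exact_match_wins(self):
        sources = [make_descriptor(i, float(i)) for i in range(10)]
        target = make_descriptor(4, 4.0)
        result = register_slice(target, sources, target_slice=6, margin=3)
        assert result.matched_slice == 4
        assert result.lbp_error == 0.0
        assert result.entropy_error == 0.0
        assert not result.tie_broken

    def test_entropy_breaks_exact_lbp_tie(self):
        # slices 3 and 5 share the same histogram; entropies 3.0 vs 2.0
        sources = [None] * 8
        sources[3] = make_descriptor(7, 3.0)
        sources[5] = make_descriptor(7, 2.0)
        target = make_descriptor(9, 2.1)  # equal LBP error 2.0 to both
        result = register_slice(target, sources, target_slice=4, margin=2)
        assert result.tie_broken
        assert result.matched_slice == 5  # entropy error 0.1 < 0.9

    def test_near_tie_within_relative_tolerance(self):
        # LBP errors differ by <1%: entropy must decide
        sources = [None] * 8
        sources[3] = blend_descriptor(7, 8, 0.5000, 9.0)
        sources[5] = blend_descriptor(7, 8, 0.5010, 1.0)
        target = blend_descriptor(7, 8, 0.0, 1.05)
        result = register_slice(target, sources, target_slice=4, margin=2)
        assert result.tie_broken
        assert result.matched_slice == 5

    def test_residual_tie_prefers_nearest_then_lower(self):
        sources = [make_descriptor(7, 1.0) for _ in range(9)]
        target = make_descriptor(7, 1.0)
        result = register_slice(target, sources, target_slice=4, margin=3)
        assert result.matched_slice == 4  # nearest to the target index
        result = register_slice(target, sources, target_slice=4, margin=0)
        assert result.matched_slice == 4

    def test_all_candidates_unusable(self):
        with pytest.raises(RegistrationError):
            register_slice(make_descriptor(1, 1.0), [None] * 6, 3, margin=2)

    def test_candidates_trace_covers_window(self):
        sources = [make_descriptor(i, float(i)) for i in range(12)]
        result = register_slice(make_descriptor(2, 2.0), sources, 6, margin=4)
        assert [c.slice_index for c in result.candidates] == list(range(2, 11))
        matched = next(
            c for c in result.candidates if c.slice_index == result.matched_slice
        )
        assert matched.lbp_error == result.lbp_error


class TestRegisterPhase:
    def test_self_registration_is_identity(self, small_dataset):
        reg = register_phase(
            small_dataset.volume, 0, source_phase=0, slice_range=SMALL_RANGE
        )
        assert len(reg.results) == SMALL_RANGE[1] - SMALL_RANGE[0] + 1
        for r in reg.results:
            assert r.matched_slice == r.target_slice
            assert r.lbp_error == 0.0
            assert r.entropy_error == 0.0

    def test_peak_phase_recovers_ground_truth(self, small_dataset):
        peak = SMALL_CONFIG.n_phases // 2
        reg = register_phase(
            small_dataset.volume, peak, source_phase=0, slice_range=SMALL_RANGE
        )
        hits = sum(
            abs(r.matched_slice - ground_truth_match(small_dataset, peak, r.target_slice))
            <= 1
            for r in reg.results
        )
        assert hits / len(reg.results) >= 0.9

    def test_matches_stay_inside_window(self, small_dataset):
        peak = SMALL_CONFIG.n_phases // 2
        reg = register_phase(
            small_dataset.volume, peak, source_phase=0, slice_range=SMALL_RANGE, margin=3
        )
        for r in reg.results:
            assert abs(r.matched_slice - r.target_slice) <= 3

    def test_unrestricted_margin_equals_exhaustive_search(self, small_dataset):
        peak = SMALL_CONFIG.n_phases // 2
        windowed = register_phase(
            small_dataset.volume,
            peak,
            source_phase=0,
            slice_range=SMALL_RANGE,
            margin=SMALL_CONFIG.n_slices,
        )
        for r in windowed.results:
            errors = {c.slice_index: c.lbp_error for c in r.candidates}
            assert r.matched_slice == min(errors, key=errors.get)

    def test_recovery_error_monotone_in_amplitude(self):
        """Larger breathing motion never makes recovery easier."""
        base = dict(image_size=128, n_slices=24, n_phases=6, seed=3)
        mean_errors = []
        for amplitude in (0.0, 2.0, 4.0):
            ds = generate_phantom(PhantomConfig(amplitude_slices=amplitude, **base))
            reg = register_phase(ds.volume, 3, source_phase=0, slice_range=SMALL_RANGE)
            mean_errors.append(
                np.mean(
                    [
                        abs(r.matched_slice - ground_truth_match(ds, 3, r.target_slice))
                        for r in reg.results
                    ]
                )
            )
        assert mean_errors == sorted(mean_errors)

    def test_invalid_slice_range(self, small_dataset):
        with pytest.raises(ValueError):
            register_phase(small_dataset.volume, 1, slice_range=(17, 9), source_phase=0)
        with pytest.raises(ValueError):
            register_phase(small_dataset.volume, 1, slice_range=(0, 5), source_phase=0)

    def test_registration_table_layout(self, small_dataset):
        reg = register_phase(
            small_dataset.volume, 2, source_phase=0, slice_range=SMALL_RANGE
        )
        frame = reg.to_frame()
        assert list(frame.columns) == [
            "phase",
            "target_slice",
            "matched_slice",
            "lbp_error",
            "entropy_error",
            "tie_broken",
            "skipped_reason",
        ]
        # 1-based reporting
        assert frame["target_slice"].min() == SMALL_RANGE[0]
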