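"""Spectrum I/O, alignment and bucketing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from csfnmr.spectra import (
    AxisError,
    BucketConfigurationError,
    DEFAULT_EXCLUSIONS,
    ExclusionWindow,
    METHANOL_WINDOW,
    SpectrumParseError,
    Spectrum1D,
    WATER_WINDOW,
    align_spectra,
    bucket_spectrum,
    build_bucket_table,
    read_spectrum,
    write_spectrum,
)


def lorentz(x, c, fwhm=0.003):
    return 1.0 / (1.0 + ((x - c) / (fwhm / 2)) ** 2)


# ---------------------------------------------------------------------------
# Spectrum1D + I/O


class TestSpectrumType:
    def test_ascending_input_is_reversed_keeping_pairs(self):
        sp = Spectrum1D("s", [1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        assert sp.ppm[0] == 4.0 and sp.ppm[-1] == 1.0
        assert sp.intensity[0] == 40.0 and sp.intensity[-1] == 10.0

    def test_non_uniform_axis_rejected(self):
        with pytest.raises(AxisError, match="uniform"):
            Spectrum1D("s", [3.0, 2.0, 0.5], [1.0, 1.0, 1.0])

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(AxisError):
            Spectrum1D("s", [1.0, 3.0, 2.0], [0.0, 0.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(AxisError):
            Spectrum1D("s", [1.0, 2.0], [0.0])


class TestReadWrite:
    def test_two_column_round_trip_exact(self, tmp_path, rng):
        x = np.linspace(0.0, 10.0, 257)
        sp = Spectrum1D("roundtrip", x, rng.normal(size=257), group_label="case")
        path = tmp_path / "roundtrip.txt"
        write_spectrum(sp, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.ppm, sp.ppm, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.intensity, sp.intensity, rtol=0, atol=1e-12)
        assert back.sample_id == "roundtrip"
        assert back.group_label == "case"

    def test_four_row_ascending_file(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("1.0 5\n2.0 6\n3.0 7\n4.0 8\n")
        sp = read_spectrum(path)
        assert sp.ppm.size == 4
        assert sp.ppm[0] > sp.ppm[-1]

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1.0 5\n2.0 six\n3.0 7\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(path)

    def test_comma_separated_and_comments(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("# a comment\n1.0,5\n2.0,6\n3.0,7\n")
        sp = read_spectrum(path)
        assert sp.intensity.tolist() == [7.0, 6.0, 5.0]

    def test_jcamp_xydata(self, tmp_path):
        body = (
            "##TITLE=demo\n##JCAMP-DX=4.24\n##XUNITS=PPM\n##YUNITS=ARBITRARY\n"
            "##FIRSTX=0.0\n##LASTX=3.0\n##NPOINTS=4\n##YFACTOR=0.5\n"
            "##XYDATA=(X++(Y..Y))\n0.0 2 4\n2.0 6 8\n##END=\n"
        )
        path = tmp_path / "demo.jdx"
        path.write_text(body)
        sp = read_spectrum(path, dialect="jcamp")
        assert sp.ppm.size == 4
        # YFACTOR applied; descending storage
        assert sp.intensity.tolist() == [4.0, 3.0, 2.0, 1.0]

    def test_jcamp_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.jdx"
        path.write_text("##TITLE=x\n##XYDATA=(X++(Y..Y))\n0 1 2\n##END=\n")
        with pytest.raises(SpectrumParseError, match="NPOINTS|FIRSTX"):
            read_spectrum(path, dialect="jcamp")


# ---------------------------------------------------------------------------
# Bucketing


class TestBucketing:
    @pytest.mark.parametrize(
        "exclusions, expected",
        [
            ((), 470),
            ((WATER_WINDOW,), 435),
            ((WATER_WINDOW, METHANOL_WINDOW), 433),
        ],
    )
    def test_default_bucket_counts(self, small_axis, exclusions, expected):
        sp = Spectrum1D("s", small_axis, np.ones_like(small_axis))
        values, mids = bucket_spectrum(sp, exclusions=exclusions)
        assert mids.size == expected
        assert values.size == expected

    def test_no_midpoint_inside_exclusion(self, small_axis):
        sp = Spectrum1D("s", small_axis, np.ones_like(small_axis))
        _, mids = bucket_spectrum(sp)
        for win in DEFAULT_EXCLUSIONS:
            assert not np.any((mids > win.low) & (mids < win.high))

    def test_zero_spectrum_gives_zero_integrals(self, small_axis):
        sp = Spectrum1D("s", small_axis, np.zeros_like(small_axis))
        values, _ = bucket_spectrum(sp)
        assert np.all(values == 0.0)

    def test_integration_linearity(self, small_axis, rng):
        y1 = rng.normal(size=small_axis.size)
        y2 = rng.normal(size=small_axis.size)
        a, b = 2.5, -0.75
        v1, _ = bucket_spectrum(Spectrum1D("1", small_axis, y1))
        v2, _ = bucket_spectrum(Spectrum1D("2", small_axis, y2))
        v3, _ = bucket_spectrum(Spectrum1D("3", small_axis, a * y1 + b * y2))
        np.testing.assert_allclose(v3, a * v1 + b * v2, rtol=1e-9, atol=1e-12)

    @given(
        low=st.floats(0.0, 2.0),
        span=st.floats(0.5, 8.0),
        width=st.floats(0.01, 0.3),
        win_lo=st.floats(0.0, 9.0),
        win_len=st.floats(0.05, 1.5),
    )
    def test_bucket_count_closed_form(self, low, span, width, win_lo, win_len):
        """Retained count = floor(span/width) - buckets overlapping the window."""
        high = low + span
        window = ExclusionWindow(win_lo, win_lo + win_len)
        n_tiles = int(np.floor(span / width + 1e-9))
        edges = low + width * np.arange(n_tiles + 1)
        dropped = sum(
            1
            for k in range(n_tiles)
            if edges[k] < window.high - 1e-9 and edges[k + 1] > window.low + 1e-9
        )
        x = np.linspace(low - 0.5, high + 0.5, 4096)
        if width <= x[1] - x[0]:
            return
        sp = Spectrum1D("s", x, np.ones_like(x))
        if n_tiles == dropped:
            with pytest.raises(BucketConfigurationError):
                bucket_spectrum(sp, low, high, width, (window,))
            return
        _, mids = bucket_spectrum(sp, low, high, width, (window,))
        assert mids.size == n_tiles - dropped

    def test_width_not_exceeding_step_rejected(self):
        x = np.linspace(0.0, 10.0, 101)  # 0.1 ppm step
        sp = Spectrum1D("s", x, np.ones_like(x))
        with pytest.raises(BucketConfigurationError):
            bucket_spectrum(sp, width=0.02)


class TestBucketTable:
    def test_identical_spectra_give_identical_rows(self, small_axis):
        y = lorentz(small_axis, 3.0)
        spectra = [Spectrum1D(f"s{i}", small_axis, y) for i in range(3)]
        table = build_bucket_table(spectra)
        assert table.values.shape[0] == 3
        np.testing.assert_array_equal(table.values[0], table.values[1])
        np.testing.assert_array_equal(table.values[0], table.values[2])

    def test_single_spectrum_435_under_water_only(self, small_axis):
        sp = Spectrum1D("s", small_axis, np.ones_like(small_axis))
        table = build_bucket_table([sp], exclusions=(WATER_WINDOW,))
        assert table.values.shape == (1, 435)

    def test_scaling_a_spectrum_doubles_its_row(self, small_axis):
        y = lorentz(small_axis, 1.5) + lorentz(small_axis, 7.2)
        t1 = build_bucket_table([Spectrum1D("a", small_axis, y)])
        t2 = build_bucket_table([Spectrum1D("a", small_axis, 2.0 * y)])
        np.testing.assert_allclose(t2.values, 2.0 * t1.values, rtol=1e-12)

    def test_tsv_round_trip(self, small_axis, tmp_path, rng):
        y = rng.normal(size=small_axis.size)
        table = build_bucket_table([Spectrum1D("a", small_axis, y)])
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        from csfnmr.spectra import BucketTable

        back = BucketTable.from_tsv(path)
        assert back.sample_ids == ["a"]
        np.testing.assert_allclose(back.bucket_midpoints, table.bucket_midpoints, atol=5e-4)
        np.testing.assert_allclose(back.values, table.values, rtol=1e-9)

    def test_subset_reorders_rows(self, small_axis, rng):
        spectra = [
            Spectrum1D(f"s{i}", small_axis, rng.normal(size=small_axis.size)) for i in range(3)
        ]
        table = build_bucket_table(spectra)
        sub = table.subset(["s2", "s0"])
        np.testing.assert_array_equal(sub.values[0], table.values[2])
        np.testing.assert_array_equal(sub.values[1], table.values[0])


# ---------------------------------------------------------------------------
# Alignment


class TestAlignment:
    def test_identical_spectra_unchanged(self, small_axis):
        y = lorentz(small_axis, 2.0) + lorentz(small_axis, 5.5)
        spectra = [Spectrum1D(f"s{i}", small_axis, y) for i in range(3)]
        out = align_spectra(spectra)
        for o in out:
            np.testing.assert_array_equal(o.intensity, y[::-1])

    def test_flat_spectrum_unchanged(self, small_axis):
        spectra = [Spectrum1D(f"s{i}", small_axis, np.full(small_axis.size, 3.3)) for i in range(3)]
        out = align_spectra(spectra)
        for o in out:
            assert np.all(o.intensity == 3.3)
            assert o.intensity.size == small_axis.size

    def test_displaced_peak_recovered(self):
        """Exhaustive-shift oracle: a +3-point displacement is undone."""
        x = np.linspace(0.0, 4.0, 4096)
        y = lorentz(x, 2.0)
        displaced = np.roll(y, 3)
        spectra = [
            Spectrum1D("ref1", x, y),
            Spectrum1D("ref2", x, y.copy()),
            Spectrum1D("moved", x, displaced),
        ]
        out = align_spectra(spectra, segment_width=0.08, max_shift=0.01)
        apexes = [o.ppm[np.argmax(o.intensity)] for o in out]
        assert apexes[2] == pytest.approx(apexes[0], abs=1e-12)

    def test_generator_jitter_reduced_by_alignment(self):
        """Generator ground truth: chemical-shift jitter of ~0.002 ppm SD makes
        per-sample citrate apexes scatter; alignment pulls them together."""
        from csfnmr.synthetic import render_spectrum

        spectra = [
            render_spectrum(
                {"Citric acid": 1.0, "Lactic acid": 1.0},
                noise_sd=0.0,
                jitter_sd=0.002,
                tsp_amplitude=0.0,
                axis=(-0.2, 10.0, 16384),
                seed=seed,
                sample_id=f"s{seed}",
            )
            for seed in range(10)
        ]

        def citrate_apex(sp):
            window = (sp.ppm > 2.6) & (sp.ppm < 2.7)
            return sp.ppm[window][np.argmax(sp.intensity[window])]

        true_apex = 2.655  # tallest citrate line without jitter
        before = np.mean([abs(citrate_apex(s) - true_apex) for s in spectra])
        out = align_spectra(spectra, segment_width=0.08, max_shift=0.01)
        after = np.mean([abs(citrate_apex(s) - true_apex) for s in out])
        assert after < before

    def test_mismatched_axes_rejected(self):
        a = Spectrum1D("a", np.linspace(0, 4, 64), np.zeros(64))
        b = Spectrum1D("b", np.linspace(0, 5, 64), np.zeros(64))
        with pytest.raises(AxisError):
            align_spectra([a, b])

    def test_tiny_max_shift_warns_and_noops(self, small_axis):
        y = lorentz(small_axis, 2.0)
        spectra = [Spectrum1D("a", small_axis, y), Spectrum1D("b", small_axis, np.roll(y, 2))]
        with pytest.warns(UserWarning):
            out = align_spectra(spectra, max_shift=1e-5)
        np.testing.assert_array_equal(out[1].intensity, spectra[1].intensity)
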