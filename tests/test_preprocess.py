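"""Referencing, bucketing, normalization and scaling."""

import numpy as np
import pandas as pd
import pytest

from metabopls.cohort import CohortConfig, MetaboliteSpec, MultipletDef, Spectrum, render_spectrum
from metabopls import io as mio
from metabopls.preprocess import (
    SCHEMES,
    BucketScheme,
    ScaledMatrix,
    assemble_matrix,
    bucket_grid,
    bucket_spectrum,
    normalize_total_area,
    reference_to_peak,
    scale_matrix,
)


def brute_force_bucket_count(scheme):
    """Independent enumeration of bucket intervals against exclusions."""
    high, low = scheme.region
    n = int(round((high - low) / scheme.width))
    total, retained = 0, 0
    for k in range(n):
        lo = low + k * scheme.width
        hi = lo + scheme.width
        total += 1
        inside = any(
            lo >= elow - 1e-9 and hi <= ehigh + 1e-9
            for ehigh, elow in scheme.exclusions
        )
        retained += not inside
    return total, retained


def flat_spectrum(lo=-0.5, hi=10.5, n=5001, value=0.0):
    return Spectrum(np.linspace(hi, lo, n), np.full(n, value))


class TestBucketGeometry:
    @pytest.mark.parametrize(
        "name,total,retained",
        [("serum-600", 4250, 3925), ("urine-600", 1900, 1580)],
    )
    def test_builtin_scheme_counts(self, name, total, retained):
        scheme = SCHEMES[name]
        centers, mask = bucket_grid(scheme)
        assert centers.size == total
        assert int(mask.sum()) == retained
        assert brute_force_bucket_count(scheme) == (total, retained)
        assert np.all(np.diff(centers) < 0)  # descending ppm

    def test_misaligned_exclusion_rejected(self):
        with pytest.raises(ValueError, match="multiple of width"):
            BucketScheme(region=(2.0, 1.0), width=0.25, exclusions=((1.6, 1.25),))

    def test_overlapping_exclusions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BucketScheme(
                region=(2.0, 1.0), width=0.25,
                exclusions=((1.75, 1.25), (1.5, 1.25)),
            )


class TestBucketing:
    def test_linear_intensity_exact_integrals(self):
        """Trapezoidal bucketing is exact for piecewise-linear intensity."""
        scheme = BucketScheme(region=(2.0, 1.0), width=0.25)
        s = Spectrum(np.linspace(2.5, 0.5, 2001), np.linspace(2.5, 0.5, 2001))
        values, mask = bucket_spectrum(s, scheme)
        edges = 1.0 + 0.25 * np.arange(5)
        expected = (edges[1:] ** 2 - edges[:-1] ** 2) / 2.0  # integral of x dx
        assert np.allclose(values, expected[::-1], rtol=1e-12)
        assert mask.all()

    def test_integral_conservation(self):
        """Sum over all buckets equals the trapezoidal integral over the
        region to 1e-9 relative, excluded buckets included."""
        rng = np.random.default_rng(3)
        scheme = SCHEMES["urine-600"]
        s = flat_spectrum(n=30001)
        s.intensity = rng.uniform(0, 1, s.ppm.size)
        values, _ = bucket_spectrum(s, scheme)
        x = s.ppm[::-1]
        y = s.intensity[::-1]
        high, low = scheme.region
        grid = np.union1d(x[(x > low) & (x < high)], [low, high])
        total = np.trapezoid(np.interp(grid, x, y), grid)
        assert values.sum() == pytest.approx(total, rel=1e-9)

    def test_narrow_spectrum_rejected(self):
        s = flat_spectrum(lo=1.0, hi=5.0)
        with pytest.raises(ValueError, match="narrower"):
            bucket_spectrum(s, SCHEMES["serum-600"])


class TestReferencing:
    def _singlet(self, center, fluid="urine"):
        cfg = CohortConfig(
            fluid=fluid, ppm_min=-0.5, ppm_max=10.5, points=22001,
            noise_sd=0.0, shift_jitter_sd=0.0, seed=0,
        )
        lib = [MetaboliteSpec("ref", (MultipletDef(center, "s"),), 1.0)]
        return render_spectrum({"ref": 5.0}, lib, cfg, np.random.default_rng(0))

    def test_shift_applied(self):
        s = self._singlet(0.012)
        out = reference_to_peak(s, SCHEMES["urine-600"])
        apex = out.ppm[np.argmax(out.intensity)]
        assert apex == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.ppm - s.ppm, out.ppm[0] - s.ppm[0])  # rigid

    def test_already_referenced_unchanged(self):
        s = self._singlet(1.33, fluid="serum")
        # place the apex exactly on a grid point at 1.33
        s.ppm = s.ppm - s.ppm[np.argmax(s.intensity)] + 1.33
        out = reference_to_peak(s, SCHEMES["serum-600"])
        assert np.array_equal(out.ppm, s.ppm)

    def test_flat_spectrum_rejected(self):
        with pytest.raises(ValueError, match="reference peak not found"):
            reference_to_peak(flat_spectrum(), SCHEMES["urine-600"])


class TestNormalization:
    def test_fractions(self):
        assert np.allclose(normalize_total_area([2.0, 3.0, 5.0]), [0.2, 0.3, 0.5])

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        v = normalize_total_area(rng.uniform(0, 10, 100))
        assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="total spectral area"):
            normalize_total_area([0.0, 0.0])


class TestAssemble:
    def _spectra(self, n=4, seed=0):
        from metabopls.cohort import build_library, simulate_cohort

        cfg = CohortConfig(
            fluid="urine", n_copd=n // 2, n_control=n - n // 2, points=8192, seed=seed
        )
        return simulate_cohort(cfg).spectra

    def test_row_order_and_permutation(self):
        spectra = self._spectra(4)
        b1 = assemble_matrix(spectra, "urine-600")
        order = [2, 0, 3, 1]
        b2 = assemble_matrix([spectra[i] for i in order], "urine-600")
        assert b1.normalized
        assert b2.sample_ids == [b1.sample_ids[i] for i in order]
        assert np.array_equal(b2.matrix, b1.matrix[order])

    def test_expected_shape(self):
        b = assemble_matrix(self._spectra(4), "urine-600")
        assert b.matrix.shape == (4, 1580)
        assert np.allclose(b.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty manifest"):
            assemble_matrix([], "urine-600")

    def test_mixed_fluids_rejected(self):
        spectra = self._spectra(4)
        spectra[0].fluid = "serum"
        with pytest.raises(ValueError, match="mixed fluid"):
            assemble_matrix(spectra, "urine-600")

    def test_corrupt_file_names_sample(self, tmp_path):
        spectra = self._spectra(4)
        rows = []
        for sp in spectra:
            p = tmp_path / f"{sp.sample_id}.tsv"
            mio.write_spectrum(sp, p)
            rows.append(
                {"sample_id": sp.sample_id, "group": sp.group, "fluid": sp.fluid,
                 "path": str(p)}
            )
        (tmp_path / f"{spectra[1].sample_id}.tsv").write_text("1.0\t2.0\t3.0\n")
        manifest = pd.DataFrame(rows)
        with pytest.raises(ValueError, match=spectra[1].sample_id):
            assemble_matrix(manifest, "urine-600")


class TestScaling:
    def test_mean_center(self):
        sm = scale_matrix(np.array([[1.0], [3.0]]), "mean_center")
        assert np.array_equal(sm.values, [[-1.0], [1.0]])

    def test_unit_variance_sds(self):
        rng = np.random.default_rng(1)
        sm = scale_matrix(rng.normal(2, 5, size=(30, 8)), "unit_variance")
        assert np.allclose(sm.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(sm.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_left_at_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        sm = scale_matrix(X, "unit_variance")
        assert np.all(sm.values[:, 1] == 0.0)
        assert sm.column_sds[1] == 0.0

    def test_back_transform_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 6))
        for method in ("mean_center", "unit_variance"):
            sm = scale_matrix(X, method)
            assert np.allclose(sm.inverse(sm.values), X, atol=1e-9)
            assert np.allclose(sm.transform(X), sm.values, atol=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown scaling"):
            scale_matrix(np.ones((3, 2)), "pareto")
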