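"""Group statistics, feature correlations, and the slide pipeline."""

import numpy as np
import pandas as pd
import pytest

from cslim.dry_mass import integrate_mass, phase_to_density
from cslim.errors import DegenerateDataError, SampleSizeError, ValidationError
from cslim.phantom import PhantomSpec, forward_interferograms, make_phantom, write_phantom_field
from cslim.reporting import compare_groups, correlate_features, quantify_slide
from cslim.stain_segmentation import filter_mask, myelin_mask, stain_features


class TestCompareGroups:
    def test_identical_samples_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(a, a)
        assert res.t_stat == 0 and res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(21)
        a = rng.normal(1.0, 0.1, 500)
        b = rng.normal(0.8, 0.1, 500)
        res = compare_groups(a, b)
        assert res.significant and res.p_value < 0.05
        assert res.mean_a > res.mean_b

    def test_order_invariance(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([3.0, 1.0, 2.0])
        r1 = compare_groups(a, b)
        r2 = compare_groups(a, b[::-1])
        assert r1.t_stat == r2.t_stat and r1.p_value == r2.p_value

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_groups([1.0, 1.0], [1.0, 1.0])

    def test_small_group_rejected(self):
        with pytest.raises(SampleSizeError):
            compare_groups([1.0], [1.0, 2.0])

    def test_matches_permutation_oracle(self):
        """Student-t p-value tracks a permutation p-value on small groups."""
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.7, 1.0, 8)
        res = compare_groups(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:8].mean() - perm[8:].mean()) >= obs:
                count += 1
        p_perm = count / n_perm
        assert res.p_value == pytest.approx(p_perm, abs=0.02)

    def test_welch_variant_available(self):
        rng = np.random.default_rng(2)
        res = compare_groups(rng.normal(0, 1, 10), rng.normal(0, 3, 30), variant="welch")
        assert res.variant == "welch"


class TestCorrelations:
    def test_perfect_linearity(self):
        dm = np.linspace(1, 10, 20)
        table = pd.DataFrame(
            {"dry_mass": dm, "mask_area": 2 * dm, "stain_intensity": np.random.default_rng(0).random(20)}
        )
        corr = correlate_features(table)
        assert corr.loc["dry_mass", "mask_area"] == pytest.approx(1.0)
        assert (np.diag(corr) == 1).all()
        assert (corr.values == corr.values.T).all()

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "dry_mass": rng.random(1000),
                "mask_area": rng.random(1000),
                "stain_intensity": rng.random(1000),
            }
        )
        corr = correlate_features(table)
        off = corr.values[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.1).all()

    def test_constant_column_rejected(self):
        table = pd.DataFrame(
            {"dry_mass": [1, 2, 3], "mask_area": [1, 1, 1], "stain_intensity": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(DegenerateDataError):
            correlate_features(table)

    def test_phantom_features_strongly_correlated(self):
        rows = []
        for n in range(5, 51, 9):
            truth = make_phantom(PhantomSpec(n_fibers=n, seed=3))
            mask = filter_mask(myelin_mask(truth.stain_rgb))
            feats = stain_features(truth.stain_rgb, mask)
            mass = integrate_mass(phase_to_density(truth.phase), mask.mask).total_mass_pg
            rows.append(
                {"dry_mass": mass, "mask_area": feats.mask_area_um2,
                 "stain_intensity": feats.mean_stain_intensity}
            )
        corr = correlate_features(pd.DataFrame(rows))
        off = corr.values[~np.eye(3, dtype=bool)]
        assert (off > 0.8).all()


@pytest.fixture(scope="module")
def phantom_slide(tmp_path_factory):
    """4-field slide: two fiber-rich fields, two without fibers."""
    root = tmp_path_factory.mktemp("slide")
    truths = []
    for i, nf in enumerate([14, 14, 0, 0]):
        spec = PhantomSpec(height_px=256, width_px=256, n_fibers=nf, n_cells=6,
                           seed=100 + i)
        truth = make_phantom(spec)
        stack = forward_interferograms(truth, noise_sigma=0.01, seed=100 + i)
        write_phantom_field(root / f"field_{i}", truth, stack)
        truths.append(truth)
    return root, truths


class TestQuantifySlide:
    def test_high_tiles_are_the_fiber_fields(self, phantom_slide):
        root, _ = phantom_slide
        report = quantify_slide(root)
        by_field = report.tiles.groupby("field_id")["label"].agg(lambda s: set(s))
        assert by_field["field_0"] == {"high"} and by_field["field_1"] == {"high"}
        assert by_field["field_2"] == {"low"} and by_field["field_3"] == {"low"}

    def test_high_density_exceeds_low(self, phantom_slide):
        root, _ = phantom_slide
        report = quantify_slide(root)
        assert (
            report.mass_high.mean_density_pg_per_um2
            > report.mass_low.mean_density_pg_per_um2
        )

    def test_rerun_is_deterministic(self, phantom_slide, tmp_path):
        root, _ = phantom_slide
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        quantify_slide(root, out_dir=out_a)
        quantify_slide(root, out_dir=out_b)
        assert (out_a / "tiles.csv").read_bytes() == (out_b / "tiles.csv").read_bytes()
        assert (out_a / "slide_report.json").read_bytes() == (
            out_b / "slide_report.json"
        ).read_bytes()

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            quantify_slide(tmp_path)

    def test_parameters_logged(self, phantom_slide):
        root, _ = phantom_slide
        report = quantify_slide(root)
        assert report.params["optics"]["wavelength_nm"] == 550.0
        assert report.params["weights"] == {"r": 0.1, "g": 0.6, "b": 0.3}
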