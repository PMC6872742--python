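"""Phantom generator: geometry, rendering windows, and label mechanism."""

import numpy as np
import pytest
from scipy import ndimage

from seg2surv.synthetic import (
    CohortDistribution,
    PhantomSpec,
    SurvivalGenerator,
    generate_cohort,
    generate_tumor_mask,
    labels_from_latents,
    render_ct,
    render_pet,
)


def brute_force_ellipsoid_count(shape, center, radii):
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                q = (
                    ((i - center[0]) / radii[0]) ** 2
                    + ((j - center[1]) / radii[1]) ** 2
                    + ((k - center[2]) / radii[2]) ** 2
                )
                count += q <= 1.0
    return count


class TestTumorMask:
    def test_zero_lobularity_is_exact_discrete_ellipsoid(self):
        spec = PhantomSpec(
            volume_shape=(48, 48, 24), tumor_radii=(8, 8, 4), lobularity=0.0, seed=1
        )
        mask = generate_tumor_mask(spec)
        expected = brute_force_ellipsoid_count((48, 48, 24), spec.tumor_center, (8, 8, 4))
        assert mask.voxel_count == expected

    def test_deterministic_under_seed(self, tiny_spec):
        m1 = generate_tumor_mask(tiny_spec)
        m2 = generate_tumor_mask(tiny_spec)
        assert np.array_equal(m1.data, m2.data)

    def test_ball_volume_matches_continuum(self):
        spec = PhantomSpec(
            volume_shape=(32, 32, 32), tumor_radii=(5, 5, 5), lobularity=0.0, seed=0
        )
        mask = generate_tumor_mask(spec)
        continuum = 4.0 / 3.0 * np.pi * 5**3  # ~524
        assert abs(mask.voxel_count - continuum) / continuum < 0.15

    def test_mask_nonempty_and_connected(self, tiny_phantom):
        mask = tiny_phantom["mask"]
        assert mask.voxel_count > 0
        _, n = ndimage.label(mask.data)
        assert n == 1

    def test_oversized_tumor_rejected(self):
        spec = PhantomSpec(volume_shape=(24, 24, 16), tumor_radii=(11, 11, 7), seed=0)
        with pytest.raises(ValueError, match="exceeds volume bounds"):
            generate_tumor_mask(spec)


class TestRendering:
    def test_ct_uniform_tumor_without_texture_or_noise(self):
        spec = PhantomSpec(
            volume_shape=(32, 32, 16), tumor_radii=(5, 5, 3),
            heterogeneity=0.0, noise_sd_ct=0.0, lobularity=0.0, seed=2,
        )
        mask = generate_tumor_mask(spec)
        ct = render_ct(mask, spec)
        assert np.unique(ct.data[mask.data]).size == 1

    def test_no_vessels_means_no_high_hu_outside_tumor(self):
        spec = PhantomSpec(
            volume_shape=(32, 32, 16), tumor_radii=(5, 5, 3),
            vessel_count=0, noise_sd_ct=0.0, seed=3,
        )
        mask = generate_tumor_mask(spec)
        ct = render_ct(mask, spec)
        assert (ct.data[~mask.data] < -500).all()

    def test_ct_values_plausible_over_seeds(self):
        hits, total = 0, 0
        for seed in range(10):
            spec = PhantomSpec(volume_shape=(32, 32, 16), tumor_radii=(5, 5, 3), seed=seed)
            ct = render_ct(generate_tumor_mask(spec), spec)
            hits += ((ct.data >= -1000) & (ct.data <= 400)).sum()
            total += ct.data.size
        assert hits / total >= 0.99

    def test_pet_nonnegative_and_hot_tumor(self, tiny_phantom):
        pet, mask = tiny_phantom["pet"], tiny_phantom["mask"]
        assert (pet.data >= 0).all()
        assert pet.data[mask.data].mean() > pet.data[~mask.data].mean()

    def test_pet_uniform_tumor_without_texture_or_noise(self):
        spec = PhantomSpec(
            volume_shape=(32, 32, 16), tumor_radii=(5, 5, 3),
            heterogeneity=0.0, noise_sd_pet=0.0, lobularity=0.0, seed=4,
        )
        mask = generate_tumor_mask(spec)
        pet = render_pet(mask, spec)
        assert np.unique(pet.data[mask.data]).size == 1

    def test_heterogeneity_raises_intratumoral_variance(self):
        variances = []
        for het in (0.0, 0.5, 1.0):
            spec = PhantomSpec(
                volume_shape=(32, 32, 16), tumor_radii=(6, 6, 4),
                heterogeneity=het, noise_sd_ct=0.0, lobularity=0.0, seed=7,
            )
            mask = generate_tumor_mask(spec)
            variances.append(render_ct(mask, spec).data[mask.data].var())
        assert variances[0] < variances[1] < variances[2]

    def test_modalities_share_geometry(self, tiny_phantom):
        # vessels land at the same voxels in CT and PET renderings
        spec = tiny_phantom["spec"]
        ct = render_ct(tiny_phantom["mask"], spec)
        pet = render_pet(tiny_phantom["mask"], spec)
        assert ct.data.shape == pet.data.shape


class TestCohort:
    def test_null_generator_gives_half_prevalence(self):
        gen = SurvivalGenerator(beta0=0.0, betas={"volume": 0.0}, seed=9)
        latents = [{"volume": float(v)} for v in np.random.default_rng(1).uniform(50, 500, 200)]
        labels, p = labels_from_latents(latents, gen)
        assert np.allclose(p, 0.5)
        # binomial 99.9% band at n=200, p=0.5
        assert abs(labels.mean() - 0.5) < 3.3 * 0.5 / np.sqrt(200)

    def test_negative_volume_effect_lowers_survival_of_large_tumors(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(2)
        latents = [{"volume": float(v)} for v in rng.uniform(50, 500, 200)]
        gen = SurvivalGenerator(beta0=0.0, betas={"volume": -3.0}, seed=3)
        labels, _ = labels_from_latents(latents, gen)
        rho = spearmanr([d["volume"] for d in latents], labels).statistic
        assert rho < -0.3

    def test_same_seed_reproduces_cohort_exactly(self):
        dist = CohortDistribution(volume_shape=(24, 24, 16))
        gen = SurvivalGenerator(seed=5)
        c1 = generate_cohort(3, dist, gen, seed=8)
        c2 = generate_cohort(3, dist, gen, seed=8)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.ct.data, b.ct.data)
            assert np.array_equal(a.pet.data, b.pet.data)
            assert np.array_equal(a.mask.data, b.mask.data)
            assert a.label == b.label and a.latents == b.latents

    def test_cohort_labels_track_generating_sigmoid(self, tiny_cohort):
        p = np.array([r.p_survival for r in tiny_cohort])
        labels = np.array([r.label for r in tiny_cohort])
        assert set(np.unique(labels)) <= {0, 1}
        assert (p > 0).all() and (p < 1).all()

    def test_degenerate_distribution_rules(self):
        dist = CohortDistribution(volume_shape=(24, 24, 16), heterogeneity_range=(0.5, 0.5))
        generate_cohort(2, dist, SurvivalGenerator(seed=0), seed=0)  # zero-width ok
        bad = CohortDistribution(volume_shape=(24, 24, 16), heterogeneity_range=(0.8, 0.2))
        with pytest.raises(ValueError, match="negative width"):
            generate_cohort(2, bad, SurvivalGenerator(seed=0), seed=0)

    def test_label_rates_track_generating_sigmoid_in_bins(self):
        # empirical survival rate per latent bin matches the sigmoid within
        # binomial error (labels drawn straight from latents; no images)
        rng = np.random.default_rng(7)
        latents = [{"volume": float(v)} for v in rng.normal(300, 80, 3000)]
        gen = SurvivalGenerator(beta0=0.3, betas={"volume": -1.5}, seed=11)
        labels, p = labels_from_latents(latents, gen)
        vols = np.array([d["volume"] for d in latents])
        z = (vols - vols.mean()) / vols.std()
        edges = np.quantile(z, np.linspace(0, 1, 7))
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (z >= lo) & (z <= hi)
            n = sel.sum()
            expected = p[sel].mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(labels[sel].mean() - expected) < 4 * se + 1e-9

    def test_save_cohort_writes_niftis_and_manifest(self, tmp_path):
        from seg2surv.io import read_volume

        dist = CohortDistribution(volume_shape=(24, 24, 16))
        cohort = generate_cohort(2, dist, SurvivalGenerator(seed=1), seed=2)
        from seg2surv.synthetic import save_cohort

        manifest = save_cohort(cohort, tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        back = read_volume(manifest["ct_path"][0])
        np.testing.assert_allclose(back.data, cohort[0].ct.data, rtol=1e-6)
        mask = read_volume(manifest["mask_path"][1])
        np.testing.assert_array_equal(mask.data, cohort[1].mask.data)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_cohort(1, CohortDistribution(), SurvivalGenerator(), seed=0)
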