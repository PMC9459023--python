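"""Generator tests: determinism, structure, class realization, effect knobs."""

import numpy as np
import pytest

import ramrad as rr
from ramrad.synthetic_cohort import (
    ISUP_FROM_GLEASON,
    ConfigurationError,
    Histology,
    SyntheticConfig,
    generate_cohort,
    null_config,
    simulate_mri_triplet,
)

TINY = dict(
    n_patients=4,
    n_sites_total=None,
    sites_per_patient_range=(2, 3),
    n_replicates_range=(3, 5),
    volume_extent_mm=48.0,
)


class TestConfigValidation:
    def test_bad_class_mix_rejected(self):
        with pytest.raises(ConfigurationError, match="class_mix"):
            SyntheticConfig(class_mix=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_fixed_axis_lengths_enforced(self):
        with pytest.raises(ConfigurationError, match="1801"):
            SyntheticConfig(fp_axis=(400.0, 1800.0, 1000))

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(cosmic_ray_rate=1.5)

    def test_histology_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Histology(4, 3, 2, 60.0)
        with pytest.raises(ValueError):
            Histology(0, 0, 0, 50.0)  # benign with HG defined
        assert ISUP_FROM_GLEASON[(4, 3)] == 3


class TestDeterminismAndStructure:
    def test_identical_seed_bitwise_identical(self):
        a = generate_cohort(SyntheticConfig(**TINY, seed=5))
        b = generate_cohort(SyntheticConfig(**TINY, seed=5))
        assert [s.site_id for s in a.sites] == [s.site_id for s in b.sites]
        for s1, s2 in zip(a.sites, b.sites):
            np.testing.assert_array_equal(s1.trus_coords_mm, s2.trus_coords_mm)
            assert s1.histology == s2.histology
        for key in a.acquisitions:
            np.testing.assert_array_equal(
                a.acquisitions[key].replicates, b.acquisitions[key].replicates
            )
        for pid in a.volumes:
            for m in a.volumes[pid]:
                np.testing.assert_array_equal(
                    a.volumes[pid][m].intensities, b.volumes[pid][m].intensities
                )

    def test_different_seed_differs(self):
        a = generate_cohort(SyntheticConfig(**TINY, seed=5))
        b = generate_cohort(SyntheticConfig(**TINY, seed=6))
        assert any(
            not np.array_equal(s1.trus_coords_mm, s2.trus_coords_mm)
            for s1, s2 in zip(a.sites, b.sites)
        )

    def test_default_cohort_realizes_study_counts(self):
        full = generate_cohort(SyntheticConfig(seed=3, n_replicates_range=(3, 4), volume_extent_mm=48.0))
        hist = full.histology_table()
        assert len(full.sites) == 47
        counts = hist["isup_gg"].value_counts().sort_index()
        assert counts.to_dict() == {0: 23, 1: 3, 2: 10, 3: 8, 4: 3}
        per_patient = hist.groupby("patient_id").size()
        assert per_patient.between(2, 5).all()
        assert len(per_patient) == 18

    def test_every_site_has_both_regions_and_mapped_coordinates(self, small_cohort):
        for site in small_cohort.sites:
            for region, n in (("FP", 1801), ("HW", 2801)):
                acq = small_cohort.acquisitions[(site.site_id, region)]
                assert acq.n_samples == n
                lo, hi = small_cohort.config.n_replicates_range
                assert lo <= acq.n_replicates <= hi
            reg = small_cohort.registrations[site.patient_id]
            mri_point = rr.map_trus_to_mri(site.trus_coords_mm, reg)
            for vol in small_cohort.volumes[site.patient_id].values():
                assert vol.contains(mri_point), (site.site_id, vol.modality)

    def test_tumor_sites_inside_lesion_benign_outside(self, small_cohort):
        for site in small_cohort.sites:
            reg = small_cohort.registrations[site.patient_id]
            mri_point = rr.map_trus_to_mri(site.trus_coords_mm, reg)
            center = small_cohort.lesion_centers_mm[site.patient_id]
            dist = np.linalg.norm(mri_point - center)
            if site.histology.is_tumor:
                assert dist <= small_cohort.config.lesion_radius_mm
            else:
                assert dist >= small_cohort.config.lesion_radius_mm


class TestAcquisitionSimulation:
    def test_noiseless_spikeless_replicates_identical(self):
        cfg = SyntheticConfig(**TINY, noise_sd=0.0, cosmic_ray_rate=0.0, seed=2)
        cohort = generate_cohort(cfg)
        acq = next(iter(cohort.acquisitions.values()))
        for row in acq.replicates[1:]:
            np.testing.assert_array_equal(row, acq.replicates[0])

    def test_rate_one_spikes_every_replicate(self):
        cfg = SyntheticConfig(
            **TINY, noise_sd=0.01, cosmic_ray_rate=1.0, cosmic_ray_amplitude=10.0, seed=3
        )
        clean_cfg = SyntheticConfig(**TINY, noise_sd=0.01, cosmic_ray_rate=0.0, seed=3)
        cohort = generate_cohort(cfg)
        clean = generate_cohort(clean_cfg)
        for key, acq in cohort.acquisitions.items():
            base = clean.acquisitions[key]
            excess = acq.replicates - base.replicates
            # every replicate carries at least one spike well above the noise
            assert (excess.max(axis=1) > 5 * 0.01).all()

    def test_benign_dominant_band_visible_in_processed_mean(self):
        # a band whose benign amplitude exceeds the tumor amplitude makes the
        # mean processed benign spectrum higher at that shift
        cfg = SyntheticConfig(n_patients=8, n_sites_total=None, sites_per_patient_range=(2, 4),
                              n_replicates_range=(5, 8), volume_extent_mm=48.0, seed=9)
        cohort = generate_cohort(cfg)
        table, hist = rr.extract_features(cohort)
        col = table.values.columns[np.argmin(np.abs(
            np.array([float(c[3:]) for c in table.values.columns[:1801]]) - 1007.0))]
        benign = hist.index[hist["isup_gg"] == 0]
        tumor = hist.index[hist["isup_gg"] >= 1]
        assert table.values.loc[benign, col].mean() > table.values.loc[tumor, col].mean()


class TestMriSimulation:
    def test_fixed_spacings(self):
        rng = np.random.default_rng(0)
        vols = simulate_mri_triplet("P", np.array([24.0, 24.0, 24.0]), SyntheticConfig(**TINY), rng)
        np.testing.assert_allclose(vols["T2"].spacing_mm, [1, 1, 1])
        np.testing.assert_allclose(vols["ADC"].spacing_mm, [1.8, 1.8, 4.0])
        np.testing.assert_allclose(vols["b2000"].spacing_mm, [2.6, 2.6, 5.0])

    def test_zero_contrast_leaves_lesion_mean_unbiased(self):
        # lesion-interior vs exterior mean ADC: difference < 2 SE over seeds
        cfg = null_config(SyntheticConfig(**TINY))
        center = np.array([24.0, 24.0, 24.0])
        diffs = []
        for seed in range(60):
            vols = simulate_mri_triplet("P", center, cfg, np.random.default_rng(seed))
            adc = vols["ADC"]
            idx = np.indices(adc.intensities.shape).astype(float)
            world = [adc.origin_mm[k] + idx[k] * adc.spacing_mm[k] for k in range(3)]
            lesion = sum((world[k] - center[k]) ** 2 for k in range(3)) <= cfg.lesion_radius_mm**2
            diffs.append(adc.intensities[lesion].mean() - adc.intensities[~lesion].mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-9

    def test_default_contrast_darkens_lesion_adc(self):
        cfg = SyntheticConfig(**TINY, seed=4)
        center = np.array([24.0, 24.0, 24.0])
        vols = simulate_mri_triplet("P", center, cfg, np.random.default_rng(1))
        adc = vols["ADC"]
        idx = np.indices(adc.intensities.shape).astype(float)
        world = [adc.origin_mm[k] + idx[k] * adc.spacing_mm[k] for k in range(3)]
        lesion = sum((world[k] - center[k]) ** 2 for k in range(3)) <= cfg.lesion_radius_mm**2
        assert adc.intensities[lesion].mean() < adc.intensities[~lesion].mean() - 200


class TestEffectSizeMonotonicity:
    def test_band_gap_raises_fp_only_auc(self):
        """Mean FP-only LOPOCV AUC increases across three band-gap levels."""
        from dataclasses import replace as drep

        def gapped(scale):
            bands = tuple(
                drep(b, amplitude_tumor=b.amplitude_benign
                     - scale * (b.amplitude_benign - b.amplitude_tumor))
                for b in rr.synthetic_cohort.DEFAULT_PEAK_BANDS
            )
            return bands

        mean_aucs = []
        for scale in (0.0, 0.5, 1.0):
            aucs = []
            for seed in range(10):
                cfg = SyntheticConfig(
                    n_patients=10, n_sites_total=24, sites_per_patient_range=(2, 4),
                    n_replicates_range=(4, 6), volume_extent_mm=48.0,
                    peak_bands=gapped(scale), seed=100 + seed,
                )
                cohort = generate_cohort(cfg)
                table, hist = rr.extract_features(cohort)
                y = rr.assign_labels(hist, "gg_gt1")
                cv = rr.lopocv(table.subset("FP"), y, max_nf=10)
                aucs.append(rr.roc_summary(cv.posteriors, cv.labels).auc)
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] < mean_aucs[1] < mean_aucs[2]
        assert mean_aucs[0] < 0.75  # gap 0: near-chance
        assert mean_aucs[2] > 0.8
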