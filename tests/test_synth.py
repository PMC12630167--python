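"""Synthetic generator: rendering, fluorescence, arrival streams, manual trap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import binary_erosion, laplace
from scipy.stats import chi2
from skimage.filters import threshold_otsu

import holopollen as hp
from holopollen.errors import InvalidParameterError


def silhouette_highpass_energy(img):
    """Std of the Laplacian inside the (eroded) particle silhouette."""
    mask = binary_erosion(img > threshold_otsu(img), iterations=2)
    return laplace(img)[mask].std()


class TestRenderHologram:
    def test_droplet_smoother_than_textured_pollen(self, profiles):
        smooth = profiles["droplet"]
        grassy = dataclasses.replace(
            profiles["Poaceae"], texture_amplitude=0.3
        )
        e_smooth = silhouette_highpass_energy(
            hp.render_particle_hologram(smooth, 50, 3, 64, 2.0)[0])
        e_grassy = silhouette_highpass_energy(
            hp.render_particle_hologram(grassy, 50, 3, 64, 2.0)[0])
        assert e_smooth < e_grassy

    def test_droplet_smoother_than_every_default_pollen(self, profiles):
        # matched diameter and seed across all profiles
        energies = {
            name: silhouette_highpass_energy(
                hp.render_particle_hologram(p, 40, 5, 64, 2.0)[0])
            for name, p in profiles.items()
        }
        droplet = energies.pop("droplet")
        assert all(droplet < e for e in energies.values())

    @pytest.mark.parametrize("diameter", [0.0, -5.0, 200.0])
    def test_bad_diameter_rejected(self, profiles, diameter):
        with pytest.raises(InvalidParameterError):
            hp.render_particle_hologram(profiles["Poaceae"], diameter,
                                        1, image_side=64, pixel_scale=1.0)

    def test_same_seed_bit_identical(self, profiles):
        a = hp.render_particle_hologram(profiles["Betula"], 23, 99, 64, 2.0)
        b = hp.render_particle_hologram(profiles["Betula"], 23, 99, 64, 2.0)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        # two planes of one event are distinct renders of the same particle
        assert not np.array_equal(a[0], a[1])


class TestSampleFluorescence:
    def test_always_missing(self, profiles):
        p = dataclasses.replace(profiles["Poaceae"], fluor_missing_prob=1.0)
        assert hp.sample_fluorescence(p, 0) is None

    def test_zero_spread_returns_means(self, profiles):
        p = dataclasses.replace(
            profiles["Poaceae"], fluor_sds=np.zeros(13), fluor_missing_prob=0.0
        )
        np.testing.assert_array_equal(hp.sample_fluorescence(p, 0), p.fluor_means)

    def test_truncated_normal_mean_recovered(self):
        # droplet-like channels: mean 0, sd sigma -> zero-truncated mean
        # is sigma/sqrt(2*pi) (half of E|N(0,sigma)|).
        sigma = 0.5
        p = hp.TaxonProfile(
            "d", 30, 5, fluor_means=np.zeros(13),
            fluor_sds=np.full(13, sigma), fluor_missing_prob=0.0,
            diameter_clip=(10, 100), is_droplet=True,
        )
        draws = np.array([hp.sample_fluorescence(p, s) for s in range(10_000)])
        target = sigma / np.sqrt(2 * np.pi)
        se = sigma / np.sqrt(2 * 10_000)  # conservative per-channel SE
        assert np.all(np.abs(draws.mean(axis=0) - target) < 3 * se)


class TestGenerateEvent:
    def test_record_shape_contract(self, profiles):
        ev = hp.generate_event(profiles["Poaceae"], "2024-06-01", "s", 5,
                               image_side=64, pixel_scale=2.0)
        assert len(ev.holograms) == 2
        assert ev.fluorescence is None or ev.fluorescence.shape == (13,)
        assert ev.true_label == "Poaceae"

    def test_droplet_missing_prob_one(self, profiles):
        p = dataclasses.replace(profiles["droplet"], fluor_missing_prob=1.0)
        ev = hp.generate_event(p, "2024-06-01", "s", 5, 64, 2.0)
        assert ev.fluorescence is None

    def test_seed_reproducibility(self, profiles):
        a = hp.generate_event(profiles["Betula"], "2024-06-01", "s", 5, 64, 2.0)
        b = hp.generate_event(profiles["Betula"], "2024-06-01", "s", 5, 64, 2.0)
        assert np.array_equal(a.holograms[0], b.holograms[0])
        assert (a.fluorescence is None and b.fluorescence is None) or \
            np.array_equal(a.fluorescence, b.fluorescence)


class TestEventStream:
    def test_zero_rates_empty_stream(self, profiles):
        sched = hp.EpisodeSchedule("2024-04-01", {"Poaceae": [0.0, 0.0]})
        events, manifest = hp.generate_event_stream(
            sched, profiles, "s", 1, image_side=32, pixel_scale=4.0)
        assert events == [] and manifest.records == []
        assert manifest.seed == 1

    def test_poisson_mean_over_replicates(self):
        # rate 10/h for 24 h -> 240 expected; mean over 200 seeds within
        # 3 * sqrt(240/200) of 240
        sched = hp.EpisodeSchedule("2024-04-01", {"Poaceae": [10.0]})
        counts = np.array([
            len(hp.sample_arrivals(sched, s)) for s in range(200)
        ])
        assert abs(counts.mean() - 240) < 3 * np.sqrt(240 / 200)

    def test_poisson_dispersion_chisquare(self):
        # Poisson GOF on the aggregate dispersion statistic:
        # sum((x - xbar)^2 / xbar) ~ chi2(n-1) under Poisson sampling.
        sched = hp.EpisodeSchedule("2024-04-01", {"Poaceae": [10.0]})
        counts = np.array([
            len(hp.sample_arrivals(sched, 1000 + s)) for s in range(200)
        ], dtype=float)
        stat = ((counts - counts.mean()) ** 2).sum() / counts.mean()
        lo, hi = chi2.ppf([0.005, 0.995], df=199)
        assert lo < stat < hi

    def test_fog_droplets_only_inside_episodes(self, profiles):
        fog = [hp.FogEpisode("2024-04-01T06:00", "2024-04-01T09:00", 5.0)]
        sched = hp.EpisodeSchedule("2024-04-01", {"Poaceae": [1.0]},
                                   fog_episodes=fog)
        arr = hp.sample_arrivals(sched, 3)
        droplets = arr[arr["taxon"] == "droplet"]
        assert len(droplets) > 0
        for t in droplets["timestamp"]:
            assert fog[0].start <= t < fog[0].end

    def test_timestamps_within_campaign(self):
        sched = hp.EpisodeSchedule("2024-04-01", {"Poaceae": [5.0, 5.0]})
        arr = hp.sample_arrivals(sched, 4)
        assert (arr["timestamp"] >= sched.start_date).all()
        assert (arr["timestamp"] < sched.end_date).all()


class TestManualEmulation:
    def _true_series(self, values):
        idx = pd.date_range("2024-04-01", periods=len(values), freq="D")
        return hp.ConcentrationSeries(
            "s", "Poaceae", "daily", pd.Series(values, index=idx), "true")

    def test_noiseless_limit_is_exact(self):
        true_s = self._true_series([0.0, 10.0, 55.5, 3.0])
        manual = hp.emulate_manual_series(true_s, 1.0, 0.0, 0)
        np.testing.assert_array_equal(manual.values, true_s.values)
        assert manual.source == "manual"

    def test_zero_series_stays_zero(self):
        manual = hp.emulate_manual_series(self._true_series([0.0] * 20),
                                          2.0, 0.5, 0)
        assert np.all(manual.values == 0)

    def test_efficiency_recovered_by_lln(self):
        rng_vals = np.random.default_rng(0).uniform(5, 50, 5000)
        true_s = self._true_series(rng_vals)
        manual = hp.emulate_manual_series(true_s, 2.0, 0.3, 1)
        ratio = manual.values.sum() / true_s.values.sum()
        assert abs(ratio - 2.0) < 0.05 * 2.0

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(InvalidParameterError):
            hp.emulate_manual_series(self._true_series([1.0] * 8), 0.0, 0.1, 0)


class TestProfileFamily:
    def test_betulaceae_morphologically_identical_spectrally_disjoint(
        self, profiles
    ):
        trio = [profiles[n] for n in ("Betula", "Alnus", "Corylus")]
        for a in trio:
            for b in trio:
                assert a.diameter_mean == b.diameter_mean
                assert a.texture_amplitude == b.texture_amplitude
                assert a.spike_count == b.spike_count
        pooled_sd = float(np.mean([p.fluor_sds.mean() for p in trio]))
        for i, a in enumerate(trio):
            for b in trio[i + 1:]:
                dist = np.linalg.norm(a.fluor_means - b.fluor_means)
                assert dist > 5 * pooled_sd
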