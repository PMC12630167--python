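"""Parametric synthetic generator for airflow-cytometry pollen events.

The generator emulates the statistical structure of operational
monitoring data: per-event hologram pairs and 13-channel fluorescence
vectors, Poisson arrival streams following per-taxon seasonal rate
curves, fog episodes injecting non-fluorescent water droplets, and a
noisy "manual trap" reference series derived from the true daily
concentrations.

The hologram appearance model is deliberately simple — a particle
silhouette with multiplicative surface texture and boundary protrusions
over a low-noise background — chosen so that the one morphological
contrast that matters operationally (smooth round water droplets versus
textured pollen grains) is present and classifiable, without modelling
holographic reconstruction physics.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import (
    DEFAULT_IMAGE_SIDE,
    NUM_FLUOR_CHANNELS,
    ConcentrationSeries,
    DatasetManifest,
    EpisodeSchedule,
    EventRecord,
    TaxonProfile,
)
from .errors import InvalidParameterError
from .utils import config_hash, derive_seed

# Rendering constants (relative units)
_SPIKE_HEIGHT = 0.14       # protrusion height as a fraction of the radius
_SPIKE_WIDTH = 0.10        # angular Gaussian width of a protrusion, radians
_EDGE_SOFT_PX = 1.0        # silhouette edge softening, pixels
_BACKGROUND_LEVEL = 0.06
_BACKGROUND_NOISE = 0.015
_TEXTURE_SCALE_PX = 1.5    # correlation length of the surface texture


def _render_plane(
    side: int,
    radius_px: float,
    center: Tuple[float, float],
    spike_phases: np.ndarray,
    texture_field: np.ndarray,
    texture_amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    boundary = np.full_like(r, radius_px)
    for phase in spike_phases:
        d = np.angle(np.exp(1j * (theta - phase)))
        boundary += radius_px * _SPIKE_HEIGHT * np.exp(
            -0.5 * (d / _SPIKE_WIDTH) ** 2
        )
    soft = np.clip((boundary - r) / _EDGE_SOFT_PX + 0.5, 0.0, 1.0)

    # Lens-like interior brightness: brighter at the centre of the grain.
    rel = np.clip(r / max(radius_px, 1e-9), 0.0, 1.0)
    dome = 0.55 + 0.25 * np.sqrt(np.clip(1.0 - rel**2, 0.0, 1.0))
    interior = dome * (1.0 + texture_amplitude * texture_field)

    background = _BACKGROUND_LEVEL + _BACKGROUND_NOISE * rng.standard_normal(
        (side, side)
    )
    img = background * (1.0 - soft) + interior * soft
    return np.clip(img, 0.0, 1.0)


def render_particle_hologram(
    profile: TaxonProfile,
    diameter: float,
    rng_seed: int,
    image_side: int = DEFAULT_IMAGE_SIDE,
    pixel_scale: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render the two greyscale hologram planes of one particle.

    Parameters
    ----------
    diameter : float
        Particle diameter in micrometres; must be > 0 and fit the frame.
    rng_seed : int
        Both planes are deterministic functions of this seed; the second
        plane re-renders the same particle with an independent small
        centre jitter and fresh background noise, emulating the two
        reconstruction planes of the instrument.
    """
    if diameter <= 0:
        raise InvalidParameterError(f"diameter must be > 0, got {diameter}")
    radius_px = diameter / (2.0 * pixel_scale)
    # The protrusions extend the silhouette beyond the nominal radius.
    if 2.0 * radius_px * (1.0 + _SPIKE_HEIGHT) >= image_side - 2:
        raise InvalidParameterError(
            f"particle of diameter {diameter} um does not fit a "
            f"{image_side} px frame at {pixel_scale} um/px"
        )
    rng = np.random.default_rng(rng_seed)
    # Particle-level randomness shared by both planes.
    base = image_side / 2.0
    center0 = (base + rng.uniform(-2, 2), base + rng.uniform(-2, 2))
    n_spikes = int(profile.spike_count)
    if n_spikes > 0:
        phase0 = rng.uniform(0, 2 * math.pi)
        spike_phases = phase0 + np.arange(n_spikes) * 2 * math.pi / n_spikes
        spike_phases = spike_phases + rng.normal(0, 0.05, n_spikes)
    else:
        spike_phases = np.empty(0)
    noise = rng.standard_normal((image_side, image_side))
    texture = gaussian_filter(noise, _TEXTURE_SCALE_PX, mode="wrap")
    texture /= max(texture.std(), 1e-12)

    img0 = _render_plane(
        image_side, radius_px, center0, spike_phases, texture,
        profile.texture_amplitude, rng,
    )
    jitter = rng.uniform(-1, 1, size=2)
    center1 = (center0[0] + jitter[0], center0[1] + jitter[1])
    img1 = _render_plane(
        image_side, radius_px, center1, spike_phases, texture,
        profile.texture_amplitude, rng,
    )
    return img0, img1


def sample_fluorescence(
    profile: TaxonProfile, rng_seed: int
) -> Optional[np.ndarray]:
    """Draw a 13-channel fluorescence vector, or ``None`` when missing.

    With probability ``profile.fluor_missing_prob`` the event carries no
    signal; otherwise each channel is a zero-truncated normal draw around
    the profile means.
    """
    rng = np.random.default_rng(rng_seed)
    if rng.uniform() < profile.fluor_missing_prob:
        return None
    draw = rng.normal(profile.fluor_means, profile.fluor_sds)
    return np.maximum(draw, 0.0)


def sample_diameter(profile: TaxonProfile, rng: np.random.Generator) -> float:
    d = rng.normal(profile.diameter_mean, profile.diameter_sd)
    if profile.diameter_clip is not None:
        lo, hi = profile.diameter_clip
        d = float(np.clip(d, lo, hi))
    return max(d, 0.5)


def generate_event(
    profile: TaxonProfile,
    timestamp,
    site: str,
    rng_seed: int,
    image_side: int = DEFAULT_IMAGE_SIDE,
    pixel_scale: float = 1.0,
    event_id: Optional[str] = None,
) -> EventRecord:
    """Generate one fully populated event for the given taxon profile."""
    rng = np.random.default_rng(rng_seed)
    diameter = sample_diameter(profile, rng)
    holograms = render_particle_hologram(
        profile, diameter, derive_seed(rng_seed, "holo"),
        image_side=image_side, pixel_scale=pixel_scale,
    )
    fluor = sample_fluorescence(profile, derive_seed(rng_seed, "fluor"))
    if event_id is None:
        event_id = f"{site}-{profile.name}-{rng_seed}"
    return EventRecord(
        event_id=event_id,
        timestamp=timestamp,
        site=site,
        holograms=holograms,
        fluorescence=fluor,
        true_label=profile.name,
        pixel_scale=pixel_scale,
    )


def sample_arrivals(
    schedule: EpisodeSchedule,
    rng_seed: int,
    droplet_taxon: str = "droplet",
) -> pd.DataFrame:
    """Sample event arrival times without rendering images.

    Returns a DataFrame with columns ``timestamp`` (UTC) and ``taxon``,
    sorted by time.  Per taxon and hour the event count is
    Poisson(rate x 1 h); fog episodes add droplet arrivals only inside
    their intervals.
    """
    rng = np.random.default_rng(rng_seed)
    rows: List[tuple] = []
    hour = pd.Timedelta(hours=1)
    for taxon, daily_rates in schedule.rates.items():
        for day_i, rate in enumerate(daily_rates):
            if rate == 0:
                continue
            day_start = schedule.start_date + pd.Timedelta(days=day_i)
            counts = rng.poisson(rate, size=24)
            for h in range(24):
                if counts[h] == 0:
                    continue
                offs = rng.uniform(0, 1, counts[h])
                for o in np.sort(offs):
                    rows.append((day_start + (h + o) * hour, taxon))
    for ep in schedule.fog_episodes:
        start = max(ep.start, schedule.start_date)
        end = min(ep.end, schedule.end_date)
        if end <= start or ep.droplet_rate == 0:
            continue
        hours = (end - start) / hour
        n = rng.poisson(ep.droplet_rate * hours)
        offs = rng.uniform(0, hours, n)
        for o in np.sort(offs):
            rows.append((start + o * hour, droplet_taxon))
    df = pd.DataFrame(rows, columns=["timestamp", "taxon"])
    if len(df):
        df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return df


def generate_event_stream(
    schedule: EpisodeSchedule,
    profiles: Dict[str, TaxonProfile],
    site: str,
    rng_seed: int,
    image_side: int = DEFAULT_IMAGE_SIDE,
    pixel_scale: float = 1.0,
    droplet_taxon: str = "droplet",
) -> Tuple[List[EventRecord], DatasetManifest]:
    """Generate a full rendered event stream for one site campaign."""
    arrivals = sample_arrivals(schedule, rng_seed, droplet_taxon=droplet_taxon)
    missing = set(arrivals["taxon"]) - set(profiles)
    if missing:
        raise InvalidParameterError(
            f"schedule references taxa without profiles: {sorted(missing)}"
        )
    events = []
    records = []
    for i, row in enumerate(arrivals.itertuples(index=False)):
        ev = generate_event(
            profiles[row.taxon],
            row.timestamp,
            site,
            derive_seed(rng_seed, "event", i),
            image_side=image_side,
            pixel_scale=pixel_scale,
            event_id=f"{site}-{i:06d}",
        )
        events.append(ev)
        records.append({"event_id": ev.event_id, "label": ev.true_label})
    cfg = {
        "site": site,
        "image_side": image_side,
        "pixel_scale": pixel_scale,
        "n_days": schedule.n_days,
        "taxa": sorted(schedule.rates),
        "profiles": {
            name: {
                "diameter_mean": p.diameter_mean,
                "diameter_sd": p.diameter_sd,
                "texture_amplitude": p.texture_amplitude,
                "spike_count": p.spike_count,
                "fluor_missing_prob": p.fluor_missing_prob,
            }
            for name, p in profiles.items()
        },
    }
    manifest = DatasetManifest(
        records=records, seed=rng_seed, config_hash=config_hash(cfg)
    )
    return events, manifest


def expected_daily_concentration(
    schedule: EpisodeSchedule,
    taxon: str,
    sample_flow: float,
    site: str = "synthetic",
) -> ConcentrationSeries:
    """Noise-free daily concentration implied by the schedule.

    Daily concentration = expected events/day divided by the sampled air
    volume per day (``sample_flow`` m^3/h x 24 h).  Fog-episode arrivals
    contribute to the droplet taxon only.
    """
    if sample_flow <= 0:
        raise InvalidParameterError("sample_flow must be > 0")
    rates = schedule.rates.get(taxon)
    expected = (
        np.asarray(rates, dtype=float) * 24.0
        if rates is not None
        else np.zeros(schedule.n_days)
    )
    if taxon == "droplet":
        hour = pd.Timedelta(hours=1)
        for ep in schedule.fog_episodes:
            for day_i in range(schedule.n_days):
                d0 = schedule.start_date + pd.Timedelta(days=day_i)
                d1 = d0 + pd.Timedelta(days=1)
                overlap = (min(ep.end, d1) - max(ep.start, d0)) / hour
                if overlap > 0:
                    expected[day_i] += ep.droplet_rate * overlap
    conc = expected / (sample_flow * 24.0)
    return ConcentrationSeries(
        site=site,
        taxon=taxon,
        resolution="daily",
        series=pd.Series(conc, index=schedule.day_index()),
        source="true",
    )


def emulate_manual_series(
    true_daily_conc: ConcentrationSeries,
    efficiency: float,
    noise_dispersion: float,
    rng_seed: int,
    sample_volume: float = 10.0,
) -> ConcentrationSeries:
    """Emulate a Hirst-type manual trap from true daily concentrations.

    Each manual value is drawn around ``efficiency x true`` with
    negative-binomial-like counting noise on an equivalent sampled volume
    of ``sample_volume`` m^3/day: a gamma multiplier of unit mean and
    variance ``noise_dispersion`` modulates the Poisson intensity.  With
    ``noise_dispersion = 0`` the series is exactly ``efficiency x true``
    (degenerate noiseless limit).
    """
    if efficiency <= 0:
        raise InvalidParameterError("efficiency must be > 0")
    if noise_dispersion < 0:
        raise InvalidParameterError("noise_dispersion must be >= 0")
    true_vals = true_daily_conc.values
    if noise_dispersion == 0:
        manual = efficiency * true_vals
    else:
        rng = np.random.default_rng(rng_seed)
        lam = efficiency * true_vals * sample_volume
        g = rng.gamma(1.0 / noise_dispersion, noise_dispersion, size=lam.shape)
        counts = rng.poisson(lam * g)
        manual = counts / sample_volume
    return ConcentrationSeries(
        site=true_daily_conc.site,
        taxon=true_daily_conc.taxon,
        resolution="daily",
        series=pd.Series(manual, index=true_daily_conc.timestamps),
        source="manual",
    )


def _spectrum(peaks: Dict[int, float], base: float = 0.2) -> np.ndarray:
    v = np.full(NUM_FLUOR_CHANNELS, base)
    for ch, val in peaks.items():
        v[ch] = val
    return v


def default_profiles() -> Dict[str, TaxonProfile]:
    """Default profiles for the main Swiss allergenic taxa plus droplets.

    Grain sizes follow the usual palynological ranges.  The Betulaceae
    triplet (Betula, Alnus, Corylus) is morphologically near-identical by
    construction — same diameter and texture ranges — but carries
    well-separated fluorescence spectra, so holography alone cannot split
    it while fluorescence can.  Water droplets are smooth, non-fluorescent
    and confined to 10-100 um.
    """
    sds = np.full(NUM_FLUOR_CHANNELS, 0.25)
    betulaceae = dict(
        diameter_mean=23.0, diameter_sd=2.5,
        texture_amplitude=0.15, spike_count=3,
        fluor_sds=sds, fluor_missing_prob=0.1,
    )
    return {
        # Grass grains are smooth and round with a single pore — the very
        # reason fog droplets get confused with them under holography.
        "Poaceae": TaxonProfile(
            name="Poaceae", diameter_mean=35.0, diameter_sd=4.0,
            texture_amplitude=0.12, spike_count=1,
            fluor_means=_spectrum({1: 2.5, 6: 1.5}), fluor_sds=sds,
            fluor_missing_prob=0.1,
        ),
        "Betula": TaxonProfile(
            name="Betula", fluor_means=_spectrum({0: 2.8, 2: 1.8}),
            **betulaceae,
        ),
        "Alnus": TaxonProfile(
            name="Alnus", fluor_means=_spectrum({5: 2.8, 7: 1.8}),
            **betulaceae,
        ),
        "Corylus": TaxonProfile(
            name="Corylus", fluor_means=_spectrum({10: 2.8, 12: 1.8}),
            **betulaceae,
        ),
        "Fraxinus": TaxonProfile(
            name="Fraxinus", diameter_mean=26.0, diameter_sd=3.0,
            texture_amplitude=0.22, spike_count=4,
            fluor_means=_spectrum({3: 2.2, 8: 2.2}), fluor_sds=sds,
            fluor_missing_prob=0.1,
        ),
        "Quercus": TaxonProfile(
            name="Quercus", diameter_mean=30.0, diameter_sd=3.5,
            texture_amplitude=0.35, spike_count=6,
            fluor_means=_spectrum({4: 2.0, 11: 1.6}), fluor_sds=sds,
            fluor_missing_prob=0.1,
        ),
        "Fagus": TaxonProfile(
            name="Fagus", diameter_mean=42.0, diameter_sd=4.0,
            texture_amplitude=0.25, spike_count=8,
            fluor_means=_spectrum({2: 1.2, 9: 2.4}), fluor_sds=sds,
            fluor_missing_prob=0.1,
        ),
        "droplet": TaxonProfile(
            name="droplet", diameter_mean=30.0, diameter_sd=15.0,
            texture_amplitude=0.0, spike_count=0,
            fluor_means=np.zeros(NUM_FLUOR_CHANNELS),
            fluor_sds=np.full(NUM_FLUOR_CHANNELS, 0.02),
            fluor_missing_prob=0.6,
            diameter_clip=(10.0, 100.0), is_droplet=True,
        ),
    }
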