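"""Core domain types for airflow-cytometry pollen monitoring data.

One detected particle (an *event*) carries two greyscale hologram
reconstructions and, when the fluorescence module fired, a 13-channel
induced-fluorescence intensity vector.  Daily or hourly particle
concentrations per site/taxon form :class:`ConcentrationSeries`; the
synthetic generator is parameterised by :class:`TaxonProfile` and
:class:`EpisodeSchedule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError

#: Number of induced-fluorescence channels measured per event.
NUM_FLUOR_CHANNELS = 13

#: Default hologram side length in pixels.
DEFAULT_IMAGE_SIDE = 200

#: Allowed provenance tags for a concentration series.
SERIES_SOURCES = ("manual", "automatic", "true")

#: Allowed temporal resolutions and their bin widths.
RESOLUTIONS = {"daily": pd.Timedelta(days=1), "hourly": pd.Timedelta(hours=1)}


def _as_utc(ts) -> pd.Timestamp:
    t = pd.Timestamp(ts)
    if t.tzinfo is None:
        return t.tz_localize("UTC")
    return t.tz_convert("UTC")


@dataclass
class EventRecord:
    """A single detected particle.

    Parameters
    ----------
    event_id : str
        Opaque unique identifier.
    timestamp : pandas.Timestamp
        Detection instant; coerced to UTC.
    site : str
        Monitoring-site name.
    holograms : tuple of two ndarray
        Two square greyscale images, identical shape, intensities in [0, 1].
    fluorescence : ndarray of shape (13,), optional
        Non-negative channel intensities; ``None`` when the event carries
        no fluorescence signal.
    true_label : str, optional
        Ground-truth class for synthetic or curated events.
    pixel_scale : float
        Micrometres per pixel, > 0.
    """

    event_id: str
    timestamp: pd.Timestamp
    site: str
    holograms: tuple
    fluorescence: Optional[np.ndarray] = None
    true_label: Optional[str] = None
    pixel_scale: float = 1.0

    def __post_init__(self):
        self.timestamp = _as_utc(self.timestamp)
        if len(self.holograms) != 2:
            raise DataError(
                f"event {self.event_id}: expected exactly 2 holograms, "
                f"got {len(self.holograms)}"
            )
        h0, h1 = (np.asarray(h, dtype=np.float64) for h in self.holograms)
        if h0.shape != h1.shape or h0.ndim != 2 or h0.shape[0] != h0.shape[1]:
            raise DataError(
                f"event {self.event_id}: holograms must be square and of "
                f"identical shape, got {h0.shape} and {h1.shape}"
            )
        for i, h in enumerate((h0, h1)):
            if h.min() < 0.0 or h.max() > 1.0:
                raise DataError(
                    f"event {self.event_id}: hologram {i} intensities "
                    "outside [0, 1]"
                )
        self.holograms = (h0, h1)
        if self.fluorescence is not None:
            f = np.asarray(self.fluorescence, dtype=np.float64)
            if f.shape != (NUM_FLUOR_CHANNELS,):
                raise DataError(
                    f"event {self.event_id}: fluorescence must have "
                    f"{NUM_FLUOR_CHANNELS} entries, got shape {f.shape}"
                )
            if np.any(f < 0) or not np.all(np.isfinite(f)):
                raise DataError(
                    f"event {self.event_id}: fluorescence entries must be "
                    "finite and >= 0"
                )
            self.fluorescence = f
        if not self.pixel_scale > 0:
            raise DataError(
                f"event {self.event_id}: pixel_scale must be > 0"
            )

    @property
    def image_side(self) -> int:
        return self.holograms[0].shape[0]

    @property
    def has_fluorescence(self) -> bool:
        return self.fluorescence is not None


@dataclass
class TaxonProfile:
    """Generative parameters of one particle class.

    ``texture_amplitude`` is the relative amplitude of the multiplicative
    surface texture (0 = perfectly smooth, as for a water droplet) and
    ``spike_count`` the number of boundary protrusions (pores/spikes).
    ``diameter_clip``, when set, truncates the sampled diameter to a hard
    support interval in micrometres.
    """

    name: str
    diameter_mean: float
    diameter_sd: float
    texture_amplitude: float = 0.0
    spike_count: int = 0
    fluor_means: np.ndarray = field(
        default_factory=lambda: np.zeros(NUM_FLUOR_CHANNELS)
    )
    fluor_sds: np.ndarray = field(
        default_factory=lambda: np.zeros(NUM_FLUOR_CHANNELS)
    )
    fluor_missing_prob: float = 0.0
    diameter_clip: Optional[tuple] = None
    is_droplet: bool = False

    def __post_init__(self):
        self.fluor_means = np.asarray(self.fluor_means, dtype=np.float64)
        self.fluor_sds = np.asarray(self.fluor_sds, dtype=np.float64)
        if self.diameter_mean <= 0:
            raise InvalidParameterError(
                f"profile {self.name}: diameter_mean must be > 0"
            )
        if self.diameter_sd < 0:
            raise InvalidParameterError(
                f"profile {self.name}: diameter_sd must be >= 0"
            )
        if self.texture_amplitude < 0:
            raise InvalidParameterError(
                f"profile {self.name}: texture_amplitude must be >= 0"
            )
        if self.spike_count < 0 or int(self.spike_count) != self.spike_count:
            raise InvalidParameterError(
                f"profile {self.name}: spike_count must be a non-negative "
                "integer"
            )
        for arrname in ("fluor_means", "fluor_sds"):
            arr = getattr(self, arrname)
            if arr.shape != (NUM_FLUOR_CHANNELS,):
                raise InvalidParameterError(
                    f"profile {self.name}: {arrname} must have "
                    f"{NUM_FLUOR_CHANNELS} entries"
                )
            if np.any(arr < 0):
                raise InvalidParameterError(
                    f"profile {self.name}: {arrname} must be non-negative"
                )
        if not 0.0 <= self.fluor_missing_prob <= 1.0:
            raise InvalidParameterError(
                f"profile {self.name}: fluor_missing_prob must be in [0, 1]"
            )
        if self.diameter_clip is not None:
            lo, hi = self.diameter_clip
            if not 0 < lo < hi:
                raise InvalidParameterError(
                    f"profile {self.name}: invalid diameter_clip {self.diameter_clip}"
                )
        if self.is_droplet:
            # Water droplets are smooth, featureless and non-fluorescent,
            # with sizes confined to 10-100 um.
            if self.texture_amplitude != 0 or self.spike_count != 0:
                raise InvalidParameterError(
                    f"droplet profile {self.name}: must be smooth "
                    "(texture_amplitude = 0, spike_count = 0)"
                )
            if np.any(self.fluor_means > 1e-6):
                raise InvalidParameterError(
                    f"droplet profile {self.name}: fluor_means must be ~0"
                )
            if self.diameter_clip is None or not (
                self.diameter_clip[0] >= 10.0 and self.diameter_clip[1] <= 100.0
            ):
                raise InvalidParameterError(
                    f"droplet profile {self.name}: diameter support must lie "
                    "within [10, 100] um"
                )


@dataclass
class FogEpisode:
    """A saturated-atmosphere interval injecting water-droplet events."""

    start: pd.Timestamp
    end: pd.Timestamp
    droplet_rate: float  # events/hour

    def __post_init__(self):
        self.start = _as_utc(self.start)
        self.end = _as_utc(self.end)
        if self.end <= self.start:
            raise InvalidParameterError("fog episode must have start < end")
        if self.droplet_rate < 0:
            raise InvalidParameterError("fog droplet_rate must be >= 0")


@dataclass
class EpisodeSchedule:
    """Per-taxon daily arrival-rate curves plus fog episodes.

    ``rates[taxon]`` holds one arrival rate (events/hour, constant within
    the day) per campaign day, starting at ``start_date`` 00:00 UTC.
    Fog episodes inject only droplet-class events, inside their intervals.
    """

    start_date: pd.Timestamp
    rates: dict  # taxon -> ndarray of shape (n_days,)
    fog_episodes: Sequence[FogEpisode] = field(default_factory=tuple)

    def __post_init__(self):
        self.start_date = _as_utc(self.start_date).normalize()
        lengths = set()
        clean = {}
        for taxon, r in self.rates.items():
            arr = np.asarray(r, dtype=np.float64)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise InvalidParameterError(
                    f"schedule: rates for {taxon} must be finite and >= 0"
                )
            clean[taxon] = arr
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise InvalidParameterError(
                "schedule: all taxa must cover the same number of days"
            )
        self.rates = clean
        self.fog_episodes = tuple(self.fog_episodes)

    @property
    def n_days(self) -> int:
        return next(iter(self.rates.values())).shape[0] if self.rates else 0

    @property
    def end_date(self) -> pd.Timestamp:
        return self.start_date + pd.Timedelta(days=self.n_days)

    def day_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


@dataclass
class ConcentrationSeries:
    """Daily or hourly particle concentrations for one site/taxon/source.

    Values are particles per cubic metre, finite and non-negative, on a
    strictly increasing, equally spaced UTC time grid.
    """

    site: str
    taxon: str
    resolution: str
    series: pd.Series  # DatetimeIndex (UTC) -> particles/m^3
    source: str

    def __post_init__(self):
        if self.resolution not in RESOLUTIONS:
            raise InvalidParameterError(
                f"resolution must be one of {sorted(RESOLUTIONS)}, "
                f"got {self.resolution!r}"
            )
        if self.source not in SERIES_SOURCES:
            raise InvalidParameterError(
                f"source must be one of {SERIES_SOURCES}, got {self.source!r}"
            )
        s = self.series
        if not isinstance(s, pd.Series):
            s = pd.Series(s)
        idx = pd.DatetimeIndex(s.index)
        if idx.tz is None:
            idx = idx.tz_localize("UTC")
        else:
            idx = idx.tz_convert("UTC")
        s = pd.Series(np.asarray(s.values, dtype=np.float64), index=idx)
        if len(s) == 0:
            self.series = s
            return
        vals = s.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise DataError(
                f"series {self.site}/{self.taxon}: values must be finite "
                "and >= 0"
            )
        step = RESOLUTIONS[self.resolution]
        diffs = np.diff(idx.asi8)
        if len(diffs) and not np.all(diffs == step.value):
            raise DataError(
                f"series {self.site}/{self.taxon}: timestamps must be "
                f"strictly increasing and equally spaced at {self.resolution} "
                "resolution"
            )
        self.series = s

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.series.index)

    def __len__(self) -> int:
        return len(self.series)


@dataclass
class DatasetManifest:
    """Links event files to labels and records generation provenance."""

    records: list  # dicts: event_id, meta (relative), images (relative paths), label
    seed: int
    config_hash: str

    def __post_init__(self):
        if self.seed is None:
            raise DataError("manifest must record the generator seed")
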