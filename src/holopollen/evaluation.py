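"""Season-aware evaluation of automatic pollen counts against a manual trap.

Implements the three network-evaluation statistics — Kendall's tau-b
between manual and automatic daily series, the scaling factor S (ratio
of manual to automatic totals; lower is better sampling), and the
off-season noise ratio R (mean automatic concentration outside the
pollen season over the mean within it) — together with the data-driven
out-of-season rule: a day is off-season when it lies in any sliding
window of W = 7 consecutive days in which at least k = 4 days stay
below T = 20 particles/m^3 in the manual series.  All metrics are
computed on daily series and swept over the classifier confidence
threshold; per-site curves combine into cross-site min/mean/max
envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .classifier import Prediction, apply_confidence_threshold
from .datatypes import RESOLUTIONS, ConcentrationSeries
from .errors import (
    DataError,
    InvalidParameterError,
    UNCLASSIFIED,
    UNDEFINED_METRIC,
)


@dataclass
class SeasonMask:
    """Per-day off-season flags derived from a manual series."""

    index: pd.DatetimeIndex
    off_season: np.ndarray  # bool per day
    T: float = 20.0
    W: int = 7
    k: int = 4
    reference: str = ""

    def __post_init__(self):
        self.off_season = np.asarray(self.off_season, dtype=bool)
        if len(self.off_season) != len(self.index):
            raise DataError("mask must define a flag for every day")
        if self.T <= 0 or self.W <= 0 or self.k <= 0:
            raise InvalidParameterError("mask parameters must be positive")
        if self.k > self.W:
            raise InvalidParameterError("k must be <= W")


def detect_off_season(
    manual_daily: ConcentrationSeries,
    T: float = 20.0,
    W: int = 7,
    k: int = 4,
) -> SeasonMask:
    """Flag off-season days of a daily manual series.

    A day is off-season iff it belongs to at least one contiguous
    W-day window (never crossing the series boundaries) in which at
    least k days have concentration strictly below T.
    """
    if manual_daily.resolution != "daily":
        raise DataError("off-season detection requires a daily series")
    n = len(manual_daily)
    if n < W:
        raise DataError(f"series of length {n} is shorter than the window W={W}")
    vals = manual_daily.values
    low = (vals < T).astype(int)
    window_low = np.convolve(low, np.ones(W, dtype=int), mode="valid")
    qualifies = window_low >= k  # indexed by window start, length n-W+1
    off = np.zeros(n, dtype=bool)
    for d in range(n):
        s0 = max(0, d - W + 1)
        s1 = min(d, n - W)
        if s1 >= s0 and qualifies[s0:s1 + 1].any():
            off[d] = True
    return SeasonMask(
        index=manual_daily.timestamps, off_season=off, T=T, W=W, k=k,
        reference=f"{manual_daily.site}/{manual_daily.taxon}",
    )


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall rank correlation between paired series.

    Returns the undefined-metric sentinel when either vector is
    completely tied (tau-b denominator zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("kendall_tau_b requires two equal-length vectors")
    if len(x) < 2:
        raise DataError("kendall_tau_b requires length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return UNDEFINED_METRIC
    tau = kendalltau(x, y, variant="b").statistic
    return float(tau) if np.isfinite(tau) else UNDEFINED_METRIC


def _align(a: ConcentrationSeries, b: ConcentrationSeries):
    common = a.timestamps.intersection(b.timestamps)
    if len(common) == 0:
        raise DataError("series have no overlapping period")
    return a.series.loc[common].to_numpy(), b.series.loc[common].to_numpy()


def scaling_factor(
    manual: ConcentrationSeries, automatic: ConcentrationSeries
) -> float:
    """Ratio of manual to automatic totals over the common period."""
    m, a = _align(manual, automatic)
    total_a = a.sum()
    if total_a == 0:
        return UNDEFINED_METRIC
    return float(m.sum() / total_a)


def off_season_noise_ratio(
    automatic_daily: ConcentrationSeries, mask: SeasonMask
) -> float:
    """Mean automatic concentration off-season over mean in-season."""
    sel = mask.index.get_indexer(automatic_daily.timestamps)
    if np.any(sel < 0):
        raise DataError("season mask does not cover the automatic series")
    off = mask.off_season[sel]
    vals = automatic_daily.values
    if not off.any() or off.all():
        return UNDEFINED_METRIC
    in_mean = vals[~off].mean()
    if in_mean == 0:
        return UNDEFINED_METRIC
    return float(vals[off].mean() / in_mean)


def aggregate_counts(
    labelled: pd.DataFrame,
    resolution: str,
    taxon: str,
    span: Optional[Tuple[pd.Timestamp, pd.Timestamp]] = None,
) -> pd.Series:
    """Integer event counts per calendar bin (UTC) for one taxon.

    ``labelled`` must have columns ``timestamp`` and ``label``; labels
    must be resolved (no missing values — abstentions carry the
    UNCLASSIFIED label and are excluded from every taxon's counts).
    ``span`` extends the binning range so empty bins appear as zeros.
    """
    if resolution not in RESOLUTIONS:
        raise InvalidParameterError(f"unknown resolution {resolution!r}")
    if len(labelled) and labelled["label"].isna().any():
        raise DataError("every event must carry a threshold-resolved label")
    freq = "D" if resolution == "daily" else "h"
    ts = pd.DatetimeIndex(labelled["timestamp"]) if len(labelled) else pd.DatetimeIndex([], tz="UTC")
    if span is None:
        if len(ts) == 0:
            raise DataError("cannot infer binning span from an empty table")
        span = (ts.min(), ts.max())
    start = pd.Timestamp(span[0]).floor(freq)
    end = pd.Timestamp(span[1]).ceil(freq)
    if end <= start:
        end = start + RESOLUTIONS[resolution]
    bins = pd.date_range(start, end, freq=freq, inclusive="left")
    match = labelled[labelled["label"] == taxon]
    counts = pd.Series(0, index=bins, dtype=np.int64)
    if len(match):
        binned = pd.DatetimeIndex(match["timestamp"]).floor(freq)
        vc = binned.value_counts()
        counts.loc[vc.index] = vc.to_numpy()
    return counts


def counts_to_concentration(
    counts: pd.Series,
    sample_flow: float,
    site: str = "",
    taxon: str = "",
    resolution: str = "daily",
) -> ConcentrationSeries:
    """Convert binned counts to particles/m^3 given the instrument flow."""
    if sample_flow <= 0:
        raise InvalidParameterError("sample_flow must be > 0")
    hours = RESOLUTIONS[resolution] / pd.Timedelta(hours=1)
    values = counts.to_numpy(dtype=float) / (sample_flow * hours)
    return ConcentrationSeries(
        site=site, taxon=taxon, resolution=resolution,
        series=pd.Series(values, index=counts.index), source="automatic",
    )


@dataclass
class ThresholdMetrics:
    tau: float
    scaling: float
    noise_ratio: float
    n_classified: int


def labelled_frame(
    predictions: Sequence[Prediction],
    events,
    c: float,
) -> pd.DataFrame:
    """Threshold-resolved (timestamp, label) table for aggregation.

    ``events`` may be EventRecords or anything with ``timestamp``;
    predictions must cover events one-to-one, in order.
    """
    if len(predictions) != len(events):
        raise DataError("predictions must cover the events one-to-one")
    rows = {
        "timestamp": [ev.timestamp for ev in events],
        "label": [apply_confidence_threshold(p, c) for p in predictions],
    }
    return pd.DataFrame(rows)


DEFAULT_SAMPLE_FLOW = 2.4  # m^3/hour


def evaluate_at_threshold(
    predictions: Sequence[Prediction],
    events,
    manual_daily: ConcentrationSeries,
    c: float,
    sample_flow: float = DEFAULT_SAMPLE_FLOW,
    taxon: Optional[str] = None,
    mask: Optional[SeasonMask] = None,
) -> ThresholdMetrics:
    """Compute (tau, S, R) for one confidence threshold.

    Applies the threshold, aggregates daily automatic concentrations
    over the manual series' period, and evaluates the three metrics
    using the off-season mask derived from the manual series.
    """
    taxon = taxon if taxon is not None else manual_daily.taxon
    table = labelled_frame(predictions, events, c)
    span = (manual_daily.timestamps[0],
            manual_daily.timestamps[-1] + RESOLUTIONS["daily"])
    counts = aggregate_counts(table, "daily", taxon, span=span)
    automatic = counts_to_concentration(
        counts, sample_flow, site=manual_daily.site, taxon=taxon,
    )
    if mask is None:
        mask = detect_off_season(manual_daily)
    m, a = _align(manual_daily, automatic)
    tau = kendall_tau_b(m, a) if len(m) >= 2 else UNDEFINED_METRIC
    s = scaling_factor(manual_daily, automatic)
    r = off_season_noise_ratio(automatic, mask)
    n_classified = int((table["label"] != UNCLASSIFIED).sum())
    return ThresholdMetrics(tau=tau, scaling=s, noise_ratio=r,
                            n_classified=n_classified)


@dataclass
class MetricCurve:
    """The three metrics as functions of the confidence threshold."""

    thresholds: np.ndarray
    tau: np.ndarray
    scaling: np.ndarray
    noise_ratio: np.ndarray
    counts_retained: np.ndarray
    site: str = ""
    taxon: str = ""

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        for name in ("tau", "scaling", "noise_ratio", "counts_retained"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.thresholds.shape:
                raise DataError(f"{name} length must match thresholds")
            setattr(self, name, arr)
        if np.any(np.diff(self.counts_retained) > 0):
            raise DataError("counts_retained must be non-increasing in c")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "tau": self.tau,
            "scaling": self.scaling,
            "noise_ratio": self.noise_ratio,
            "counts_retained": self.counts_retained,
            "site": self.site,
            "taxon": self.taxon,
        })


def threshold_sweep(
    predictions: Sequence[Prediction],
    events,
    manual_daily: ConcentrationSeries,
    thresholds: Sequence[float],
    sample_flow: float = DEFAULT_SAMPLE_FLOW,
    taxon: Optional[str] = None,
) -> MetricCurve:
    """Evaluate the three metrics across an ascending threshold grid."""
    thr = np.asarray(thresholds, dtype=float)
    if np.any(thr < 0) or np.any(thr > 1) or np.any(np.diff(thr) < 0):
        raise InvalidParameterError("thresholds must be ascending in [0, 1]")
    mask = detect_off_season(manual_daily)
    rows = [
        evaluate_at_threshold(
            predictions, events, manual_daily, c,
            sample_flow=sample_flow, taxon=taxon, mask=mask,
        )
        for c in thr
    ]
    return MetricCurve(
        thresholds=thr,
        tau=[r.tau for r in rows],
        scaling=[r.scaling for r in rows],
        noise_ratio=[r.noise_ratio for r in rows],
        counts_retained=[r.n_classified for r in rows],
        site=manual_daily.site,
        taxon=taxon if taxon is not None else manual_daily.taxon,
    )


@dataclass
class SiteEnvelope:
    """Pointwise mean/min/max of each metric across sites.

    Undefined sentinels are excluded from the statistics; ``n_sites``
    reports, per threshold and metric, how many sites contributed.
    """

    thresholds: np.ndarray
    mean: dict = field(default_factory=dict)
    min: dict = field(default_factory=dict)
    max: dict = field(default_factory=dict)
    n_sites: dict = field(default_factory=dict)
    taxon: str = ""


METRIC_NAMES = ("tau", "scaling", "noise_ratio")


def cross_site_envelope(curves: Sequence[MetricCurve]) -> SiteEnvelope:
    """Combine per-site metric curves into a min/mean/max envelope."""
    if not curves:
        raise DataError("at least one curve is required")
    thr = curves[0].thresholds
    for c in curves[1:]:
        if c.thresholds.shape != thr.shape or np.any(c.thresholds != thr):
            raise DataError("all curves must share the same threshold grid")
    env = SiteEnvelope(thresholds=thr, taxon=curves[0].taxon)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        for name in METRIC_NAMES:
            stack = np.vstack([getattr(c, name) for c in curves])
            defined = np.isfinite(stack)
            env.n_sites[name] = defined.sum(axis=0)
            masked = np.where(defined, stack, np.nan)
            any_def = defined.any(axis=0)
            env.mean[name] = np.where(any_def, np.nanmean(masked, axis=0), np.nan)
            env.min[name] = np.where(any_def, np.nanmin(masked, axis=0), np.nan)
            env.max[name] = np.where(any_def, np.nanmax(masked, axis=0), np.nan)
    return env


def plot_metric_curves(envelope: SiteEnvelope, path) -> None:
    """Three metric lines with cross-site min/max shading."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"tau": "tab:red", "scaling": "tab:green",
              "noise_ratio": "tab:orange"}
    labels = {"tau": "Kendall's tau", "scaling": "scaling factor S",
              "noise_ratio": "off-season noise ratio R"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in METRIC_NAMES:
        ax.plot(envelope.thresholds, envelope.mean[name],
                color=colors[name], label=labels[name])
        ax.fill_between(envelope.thresholds, envelope.min[name],
                        envelope.max[name], color=colors[name], alpha=0.2)
    ax.set_xlabel("confidence threshold c")
    ax.set_ylabel("metric value")
    if envelope.taxon:
        ax.set_title(envelope.taxon)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
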