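"""Readers and writers for events and concentration series.

Events live in a directory: ``events.jsonl`` (one JSON object per line),
``images/`` with two 16-bit greyscale PNGs per event, and
``manifest.json`` recording seed and config hash.  Concentration series
are CSV with the fixed header ``site,taxon,resolution,timestamp,value,
source`` and ISO-8601 UTC timestamps.  All round-trips are lossless up
to the 16-bit image quantisation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import ConcentrationSeries, DatasetManifest, EventRecord
from .errors import DataError, ManifestIntegrityError, ParseError

_SERIES_COLUMNS = ["site", "taxon", "resolution", "timestamp", "value", "source"]
_QUANT = 65535  # 16-bit greyscale


def _save_png(path: Path, img: np.ndarray) -> None:
    arr = np.round(np.clip(img, 0.0, 1.0) * _QUANT).astype(np.uint16)
    Image.fromarray(arr).save(path)


def _load_png(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.float64)
    return arr / _QUANT


def write_events(
    path: Union[str, Path],
    records: Sequence[EventRecord],
    manifest: Optional[DatasetManifest] = None,
) -> None:
    """Write an event stream (possibly empty) to a dataset directory."""
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    lines = []
    man_records = []
    for ev in records:
        images = [f"images/{ev.event_id}_0.png", f"images/{ev.event_id}_1.png"]
        for rel, img in zip(images, ev.holograms):
            _save_png(root / rel, img)
        lines.append(json.dumps({
            "event_id": ev.event_id,
            "timestamp": ev.timestamp.isoformat(),
            "site": ev.site,
            "images": images,
            "fluorescence": None if ev.fluorescence is None
            else [float(v) for v in ev.fluorescence],
            "true_label": ev.true_label,
            "pixel_scale": ev.pixel_scale,
        }))
        man_records.append({"event_id": ev.event_id, "label": ev.true_label})
    (root / "events.jsonl").write_text("\n".join(lines) + ("\n" if lines else ""))
    if manifest is None:
        manifest = DatasetManifest(records=man_records, seed=0, config_hash="")
    (root / "manifest.json").write_text(json.dumps({
        "records": manifest.records,
        "seed": manifest.seed,
        "config_hash": manifest.config_hash,
    }, indent=1))


def read_events(path: Union[str, Path]) -> List[EventRecord]:
    """Read an event dataset directory written by :func:`write_events`."""
    root = Path(path)
    meta_path = root / "events.jsonl"
    if not meta_path.exists():
        raise ParseError(f"no events.jsonl under {root}")
    events = []
    for lineno, line in enumerate(meta_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"{meta_path}:{lineno}: malformed JSON ({exc.msg})"
            ) from exc
        for key in ("event_id", "timestamp", "site", "images", "pixel_scale"):
            if key not in obj:
                raise ParseError(f"{meta_path}:{lineno}: missing field {key!r}")
        imgs = []
        for rel in obj["images"]:
            p = root / rel
            if not p.exists():
                raise ManifestIntegrityError(
                    f"{meta_path}:{lineno}: referenced image {rel} missing"
                )
            imgs.append(_load_png(p))
        try:
            events.append(EventRecord(
                event_id=obj["event_id"],
                timestamp=pd.Timestamp(obj["timestamp"]),
                site=obj["site"],
                holograms=tuple(imgs),
                fluorescence=None if obj.get("fluorescence") is None
                else np.asarray(obj["fluorescence"], dtype=np.float64),
                true_label=obj.get("true_label"),
                pixel_scale=obj["pixel_scale"],
            ))
        except DataError as exc:
            raise ParseError(f"{meta_path}:{lineno}: {exc}") from exc
    return events


def read_manifest(path: Union[str, Path]) -> DatasetManifest:
    root = Path(path)
    obj = json.loads((root / "manifest.json").read_text())
    man = DatasetManifest(
        records=obj["records"], seed=obj["seed"], config_hash=obj["config_hash"]
    )
    meta = {json.loads(l)["event_id"]
            for l in (root / "events.jsonl").read_text().splitlines() if l.strip()}
    referenced = {r["event_id"] for r in man.records}
    if not referenced <= meta:
        raise ManifestIntegrityError(
            f"manifest references unknown events: {sorted(referenced - meta)[:5]}"
        )
    return man


def write_series(
    path: Union[str, Path],
    series: Union[ConcentrationSeries, Sequence[ConcentrationSeries]],
) -> None:
    """Write one or several concentration series to a CSV file."""
    if isinstance(series, ConcentrationSeries):
        series = [series]
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "site": s.site,
            "taxon": s.taxon,
            "resolution": s.resolution,
            "timestamp": [t.isoformat() for t in s.timestamps],
            "value": s.values,
            "source": s.source,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_SERIES_COLUMNS))
    df.to_csv(path, index=False, columns=_SERIES_COLUMNS)


def read_series(path: Union[str, Path]) -> List[ConcentrationSeries]:
    """Read every concentration series from a CSV file.

    Series are grouped by (site, taxon, resolution, source); rows with
    negative or non-numeric values raise :class:`ParseError` naming the
    offending line.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = set(_SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(values) | (values < 0))
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError(
            f"{path}:{bad[0] + 2}: field 'value' must be a finite "
            f"non-negative number, got {df['value'].iloc[bad[0]]!r}"
        )
    df["value"] = values
    out = []
    for (site, taxon, res, source), grp in df.groupby(
        ["site", "taxon", "resolution", "source"], sort=True
    ):
        ts = pd.DatetimeIndex([pd.Timestamp(t) for t in grp["timestamp"]])
        try:
            out.append(ConcentrationSeries(
                site=site, taxon=taxon, resolution=res,
                series=pd.Series(grp["value"].to_numpy(), index=ts),
                source=source,
            ))
        except (DataError, ValueError) as exc:
            raise ParseError(f"{path}: series {site}/{taxon}: {exc}") from exc
    return out
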