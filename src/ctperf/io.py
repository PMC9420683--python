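"""Curve CSV files and study configuration loading.

Curve files are plain UTF-8 CSV with the exact header ``time_s,hu`` and one
row per frame; times must be strictly increasing. Values are written with
12 significant digits so a write/read round trip preserves them well beyond
the precision that matters for HU data.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from .curve_fitting import TimeEnhancementCurve
from .gamma_model import GammaVariateParams
from .synthetic import OrganSpec, StudyConfig

__all__ = ["read_curve", "write_curve", "load_study_config", "CURVE_HEADER"]

CURVE_HEADER = ("time_s", "hu")


class CurveParseError(ValueError):
    """A curve CSV that cannot be parsed; the message carries the line number."""


def read_curve(path: str | Path) -> TimeEnhancementCurve:
    """Read a time-enhancement curve from a ``time_s,hu`` CSV file."""
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CurveParseError(f"{path}: empty file") from None
        if [c.strip() for c in header] != list(CURVE_HEADER):
            raise CurveParseError(
                f"{path}:1: expected header 'time_s,hu', got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise CurveParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(row)}"
                )
            try:
                t, v = float(row[0]), float(row[1])
            except ValueError:
                raise CurveParseError(
                    f"{path}:{lineno}: non-numeric cell in {row!r}"
                ) from None
            if times and t <= times[-1]:
                raise CurveParseError(
                    f"{path}:{lineno}: times must be strictly increasing "
                    f"({t} after {times[-1]})"
                )
            times.append(t)
            values.append(v)
    if len(times) < 2:
        raise CurveParseError(f"{path}: need at least 2 data rows, got {len(times)}")
    return TimeEnhancementCurve(np.asarray(times), np.asarray(values))


def write_curve(curve: TimeEnhancementCurve, path: str | Path) -> None:
    """Write a curve as a ``time_s,hu`` CSV with 12 significant digits."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CURVE_HEADER)
        for t, v in zip(curve.times, curve.values):
            writer.writerow([f"{t:.12g}", f"{v:.12g}"])


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a :class:`~ctperf.synthetic.StudyConfig` from YAML or JSON.

    Recognised keys mirror the dataclass fields; ``aorta`` is a mapping with
    ``y_max``/``t_max``/``alpha`` (plus optional ``baseline_hu``), and
    ``organs`` maps organ names to ``perfusion``/``t_max``/``baseline_hu``.
    Missing keys fall back to the defaults.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: study config must be a mapping")

    kwargs: dict = {}
    for key in ("n_frames", "frame_interval", "noise_sd", "roi_voxels", "seed", "delay_s", "k_mode"):
        if key in raw:
            kwargs[key] = raw[key]
    if "aorta" in raw:
        a = dict(raw["aorta"])
        if "baseline_hu" in a:
            kwargs["aorta_baseline_hu"] = float(a.pop("baseline_hu"))
        kwargs["aorta"] = GammaVariateParams(**a)
    if "aorta_baseline_hu" in raw:
        kwargs["aorta_baseline_hu"] = float(raw["aorta_baseline_hu"])
    if "organs" in raw:
        kwargs["organs"] = {
            name: OrganSpec(**spec) for name, spec in raw["organs"].items()
        }
    return StudyConfig(**kwargs)
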