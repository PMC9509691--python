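"""Readers and writers for recordings, calibrations, cohort tables and pH maps.

All text artifacts carry a provenance header (tool version, seed, config
hash) in ``#``-prefixed comment lines; CSV bodies use comma separators,
UTF-8, a mandatory header row and ``.`` decimals.  Floats are written with
17 significant digits so write/read round-trips are exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import Calibration
from .photophysics import ChannelRecording

__all__ = [
    "ParseError",
    "write_recording",
    "read_recording",
    "write_calibration",
    "read_calibration",
    "write_table",
    "read_table",
    "write_ph_image",
    "COHORT_SURFACE_COLUMNS",
    "COHORT_SUBJECT_COLUMNS",
    "READING_COLUMNS",
]

COHORT_SURFACE_COLUMNS = [
    "subject_id", "group", "surface_id", "rank",
    "rest_ph", "rest_sd", "rest_n", "drop_ph", "drop_sd", "drop_n",
]
COHORT_SUBJECT_COLUMNS = ["subject_id", "group", "saliva_ph"]
READING_COLUMNS = ["subject_id", "group", "surface_id", "rank", "phase", "replicate", "ph"]


class ParseError(ValueError):
    """A file did not conform to the expected format."""


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance_lines(seed=None, extra: dict | None = None) -> list[str]:
    items = {"tool": f"oph {__version__}", "seed": seed}
    if extra:
        items.update(extra)
    return [f"# {k}={v}" for k, v in items.items() if v is not None] or ["# tool=oph"]


def write_recording(path, rec: ChannelRecording, f_mod: float, seed=None) -> None:
    """Write one channel recording as columnar CSV with a metadata header."""
    path = Path(path)
    lines = _provenance_lines(seed)
    lines += [f"# fs={rec.fs:.17g}", f"# f_mod={f_mod:.17g}", f"# channel_id={rec.channel_id}"]
    t = np.arange(rec.samples.size) / rec.fs
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        fh.write("time_s,volts\n")
        for ti, vi in zip(t, rec.samples):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


def read_recording(path) -> tuple[ChannelRecording, dict]:
    """Read a channel recording; returns the recording and its header metadata."""
    path = Path(path)
    meta: dict = {}
    data_lines = []
    header = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                for col in ("time_s", "volts"):
                    if col not in header:
                        raise ParseError(f"{path}:{lineno}: missing column '{col}'")
                continue
            data_lines.append(line)
    if header is None or not data_lines:
        raise ParseError(f"{path}: no data rows")
    for key in ("fs", "f_mod", "channel_id"):
        if key not in meta:
            raise ParseError(f"{path}: missing header field '{key}'")
    volts_idx = header.index("volts")
    try:
        samples = np.array([float(l.split(",")[volts_idx]) for l in data_lines])
        fs = float(meta["fs"])
        channel_id = int(meta["channel_id"])
        meta["fs"] = fs
        meta["f_mod"] = float(meta["f_mod"])
        meta["channel_id"] = channel_id
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed data ({exc})") from exc
    return ChannelRecording(samples=samples, fs=fs, channel_id=channel_id), meta


def write_calibration(path, cal: Calibration, seed=None, provenance: dict | None = None) -> None:
    payload = asdict(cal)
    doc = {
        "calibration": payload,
        "provenance": {
            "tool": f"oph {__version__}",
            "seed": seed,
            "config_hash": _config_hash(payload),
            **(provenance or {}),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_calibration(path) -> Calibration:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    payload = doc.get("calibration", doc)
    try:
        return Calibration(**{k: v for k, v in payload.items()})
    except TypeError as exc:
        raise ParseError(f"{path}: unexpected calibration fields ({exc})") from exc


def write_table(path, df: pd.DataFrame, required_columns=None, seed=None) -> None:
    """Write a cohort/results table as CSV with a provenance comment header."""
    path = Path(path)
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\n".join(_provenance_lines(seed)) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path, required_columns=None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse CSV ({exc})") from exc
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_ph_image(path_tiff, ph_image, path_png=None, title="pH map") -> None:
    """Export a pH map as 32-bit float TIFF and optionally a PNG heatmap."""
    import tifffile

    data = np.where(ph_image.valid, ph_image.ph, np.nan).astype(np.float32)
    tifffile.imwrite(str(path_tiff), data)
    if path_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(data, cmap="viridis")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="pH")
        fig.savefig(path_png, dpi=120, bbox_inches="tight")
        plt.close(fig)
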