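"""Reading and writing recordings, cohort tables, and configuration files.

Recordings travel as EDF (read through :mod:`mne` when installed) or as a
simple delimited-text format: comment headers carrying the sampling rate and
channel labels, then one tab-separated row of samples per channel.  Tables
are TSV via pandas; configuration is declarative YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectral import Recording

__all__ = [
    "read_recording",
    "write_recording_text",
    "read_table",
    "write_table",
    "load_config",
    "save_config",
]

_MAGIC = "# megnpt-recording v1"


def write_recording_text(rec: Recording, path: str | Path) -> Path:
    """Write a recording as delimited text (one row per channel)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# channels={','.join(rec.channel_ids)}\n")
        if rec.excluded:
            fh.write(f"# excluded={rec.exclusion_reason or 'unspecified'}\n")
        np.savetxt(fh, rec.samples, delimiter="\t", fmt="%.10g")
    return path


def _read_recording_text(path: Path) -> Recording:
    fs = None
    channels = None
    excluded = False
    reason = ""
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("channels="):
                channels = body[len("channels=") :].split(",")
            elif body.startswith("excluded="):
                excluded = True
                reason = body[len("excluded=") :]
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header")
    samples = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    return Recording(
        samples=samples,
        fs=fs,
        channel_ids=channels,
        excluded=excluded,
        exclusion_reason=reason,
    )


def _read_recording_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
    )


def read_recording(path: str | Path) -> Recording:
    """Read a recording from ``.edf`` or the delimited-text format."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_recording_edf(path)
    return _read_recording_text(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
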