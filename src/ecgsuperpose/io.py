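"""CSV recording I/O and YAML experiment configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .synth import (
    LOCATION_AMPLITUDES_UV,
    ChannelSpec,
    CleanRecording,
    MultiChannelRecording,
    generate_clean_recording,
    generate_template,
    make_multichannel,
)

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "load_config",
    "recording_from_config",
]


def write_recording_csv(rec: MultiChannelRecording, path: str | Path) -> None:
    """Write a recording as CSV: t_seconds column plus ch1..chK."""
    t = np.arange(rec.n_samples) / rec.fs
    cols = {"t_seconds": t}
    for i in range(rec.n_channels):
        cols[f"ch{i + 1}"] = rec.data[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_recording_csv(path: str | Path, fs: float | None = None) -> MultiChannelRecording:
    """Read a recording written by :func:`write_recording_csv`.

    The sample rate is inferred from the ``t_seconds`` column when present;
    otherwise ``fs`` must be given.
    """
    df = pd.read_csv(path)
    ch_cols = [c for c in df.columns if c.lower().startswith("ch")]
    if not ch_cols:
        raise ValueError("no channel columns (ch1..chK) found")
    if "t_seconds" in df.columns:
        dt = np.diff(df["t_seconds"].to_numpy())
        if dt.size and np.all(dt > 0):
            fs = 1.0 / float(np.median(dt))
    if fs is None:
        raise ValueError("fs not inferable from file; pass fs explicitly")
    data = df[ch_cols].to_numpy(dtype=float).T
    return MultiChannelRecording(fs, data)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def recording_from_config(
    cfg: Mapping[str, Any],
) -> tuple[CleanRecording, MultiChannelRecording]:
    """Build a (clean, multichannel) pair from a configuration mapping.

    Recognised keys: samples_per_cycle, fs, n_cycles, r_amplitude_uv,
    location_preset (chest | mastoid | upper_arm), rr_jitter, seed, and
    channels: a list of {noise_sigma_uv, phase_offset_samples, gain_scale}.
    """
    spc = int(cfg.get("samples_per_cycle", 180))
    fs = float(cfg.get("fs", 250.0))
    n_cycles = int(cfg.get("n_cycles", 4))
    preset = cfg.get("location_preset")
    if preset is not None:
        if preset not in LOCATION_AMPLITUDES_UV:
            raise ValueError(f"unknown location_preset {preset!r}")
        r_amp = LOCATION_AMPLITUDES_UV[preset]
    else:
        r_amp = float(cfg.get("r_amplitude_uv", 1000.0))
    rr_jitter = float(cfg.get("rr_jitter", 0.0))
    seed = cfg.get("seed")
    if seed is None:
        raise ValueError("config must contain a seed")
    seed = int(seed)

    template = generate_template(spc, r_amp)
    clean = generate_clean_recording(template, n_cycles, fs, rr_jitter, seed)
    chans = cfg.get("channels") or [{}]
    specs = [
        ChannelSpec(
            noise_sigma=float(c.get("noise_sigma_uv", 0.0)),
            phase_offset=int(c.get("phase_offset_samples", 0)),
            gain_scale=float(c.get("gain_scale", 1.0)),
        )
        for c in chans
    ]
    rec = make_multichannel(clean, specs, seed=seed + 1)
    return clean, rec
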