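"""File formats and configuration.

Covers the three interchange formats the pipeline touches:

* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``) — written in the
  BINARY / MULTIPLEXED / IEEE_FLOAT_32 dialect, read through MNE (which
  additionally handles INT_16 with per-channel resolutions);
* plain-CSV marker tables (onset_s, marker_code, ...);
* YAML pipeline configuration with schema validation and defaults.

Also hosts the montage presets (32/16/15/7-channel layouts with 2-D scalp
positions, nose up).  The protocol fixes only the *sizes* of the reduced
montages, not their exact channel identities, so the 16/15/7-channel
presets here are documented stand-ins and are overridable.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stimgen import BLOCK_END_MARKER, BLOCK_START_MARKER, CODE_TO_CONDITION

__all__ = [
    "MONTAGES",
    "CHANNEL_POSITIONS",
    "montage_positions",
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "read_marker_csv",
    "write_marker_csv",
    "read_brainvision",
    "write_brainvision",
    "BrainVisionError",
    "MarkerDataMismatchError",
]

# ---------------------------------------------------------------------------
# montages

#: approximate 2-D scalp positions (10-20 layout, nose up, unit head radius)
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.28), "FC1": (-0.25, 0.25), "FCz": (0.0, 0.25),
    "FC2": (0.25, 0.25), "FC6": (0.69, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.69, -0.28), "CP1": (-0.25, -0.25), "CPz": (0.0, -0.25),
    "CP2": (0.25, -0.25), "CP6": (0.69, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO7": (-0.55, -0.78), "PO8": (0.55, -0.78),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

MONTAGES: dict[str, list[str]] = {
    "acticap32": list(CHANNEL_POSITIONS),
    # portable 16-channel set-up used with the first patients (stand-in)
    "vamp16": [
        "Fz", "FCz", "Cz", "Pz", "Oz", "F3", "F4", "C3", "C4",
        "P3", "P4", "T7", "T8", "P7", "P8", "CPz",
    ],
    # 15-channel subset common to all set-ups, used for offline re-analysis
    "offline15": [
        "Fz", "FCz", "Cz", "Pz", "Oz", "F3", "F4", "C3", "C4",
        "P3", "P4", "T7", "T8", "P7", "P8",
    ],
    "minimal7": ["Fz", "FCz", "Cz", "Pz", "C3", "C4", "Oz"],
}


def montage_positions(channels: list[str] | str) -> np.ndarray:
    """2-D positions (n_channels, 2) for a montage name or channel list."""
    if isinstance(channels, str):
        channels = MONTAGES[channels]
    try:
        return np.array([CHANNEL_POSITIONS[ch] for ch in channels], float)
    except KeyError as exc:
        raise KeyError(f"unknown channel {exc} (no registered position)") from exc


# ---------------------------------------------------------------------------
# pipeline configuration


class ConfigError(ValueError):
    """Schema violation in a pipeline configuration."""


#: per-kind epoch windows in seconds, by population preset
EPOCH_WINDOWS = {
    "healthy": {"STANDARD": 0.500, "DEVIANT": 0.750},
    "patient": {"STANDARD": 0.800, "DEVIANT": 1.000},
}


@dataclass
class PipelineConfig:
    """Decoding/analysis parameters with the online defaults."""

    montage: str = "acticap32"
    population: str = "healthy"
    band_low: float = 0.5
    band_high: float = 20.0
    window_std_s: float | None = None  # default from population
    window_dev_s: float | None = None
    n_xdawn_filters: int | str = "auto"  # "auto" = LOO-CV over 1..5
    max_auto_filters: int = 5
    decim: int = 10
    rejection_fraction: float = 0.15
    shrinkage: float | str = "lw"  # Ledoit-Wolf by default
    n_permutations: int = 10000
    alpha: float = 0.01
    alpha_ica: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.population not in EPOCH_WINDOWS:
            raise ConfigError(f"population: unknown preset {self.population!r}")
        if self.window_std_s is None:
            self.window_std_s = EPOCH_WINDOWS[self.population]["STANDARD"]
        if self.window_dev_s is None:
            self.window_dev_s = EPOCH_WINDOWS[self.population]["DEVIANT"]
        if not (0 < self.band_low < self.band_high):
            raise ConfigError(
                f"band edges: need 0 < low < high, got ({self.band_low}, {self.band_high})"
            )
        if not (0 <= self.rejection_fraction < 1):
            raise ConfigError("rejection_fraction: must be in [0, 1)")
        if isinstance(self.montage, str) and self.montage not in MONTAGES:
            raise ConfigError(f"montage: unknown preset {self.montage!r}")
        n_ch = len(self.channels)
        if self.n_xdawn_filters != "auto":
            if not isinstance(self.n_xdawn_filters, int) or not (
                1 <= self.n_xdawn_filters <= n_ch
            ):
                raise ConfigError(
                    f"n_xdawn_filters: must be 'auto' or in 1..{n_ch}"
                )
        if self.decim < 1:
            raise ConfigError("decim: must be >= 1")
        for name in ("alpha", "alpha_ica"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ConfigError(f"{name}: must be in (0, 1)")

    @property
    def channels(self) -> list[str]:
        if isinstance(self.montage, str):
            return MONTAGES[self.montage]
        return list(self.montage)

    @property
    def windows(self) -> dict[str, float]:
        return {"STANDARD": self.window_std_s, "DEVIANT": self.window_dev_s}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; missing keys get defaults, unknown keys raise."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# marker tables

_KNOWN_CODES = set(CODE_TO_CONDITION) | {BLOCK_START_MARKER, BLOCK_END_MARKER}


def write_marker_csv(table: pd.DataFrame, path: str | Path) -> None:
    _validate_marker_table(table)
    table.to_csv(path, index=False)


def read_marker_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _validate_marker_table(table)
    return table


def _validate_marker_table(table: pd.DataFrame) -> None:
    for col in ("onset_s", "marker_code"):
        if col not in table.columns:
            raise ValueError(f"marker table missing column {col!r}")
    onsets = table["onset_s"].to_numpy(float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("marker onsets must be non-decreasing")
    bad = set(table["marker_code"].astype(int)) - _KNOWN_CODES
    if bad:
        raise ValueError(f"unregistered marker codes: {sorted(bad)}")


# ---------------------------------------------------------------------------
# BrainVision triplet


class BrainVisionError(ValueError):
    """Malformed or unsupported BrainVision files."""


class MarkerDataMismatchError(BrainVisionError):
    """Markers reference samples beyond the data length."""


def write_brainvision(recording, path: str | Path) -> tuple[Path, Path, Path]:
    """Write a Recording as ``path.vhdr``/``path.vmrk``/``path.eeg``.

    Dialect: BINARY, MULTIPLEXED, IEEE_FLOAT_32, resolution 1 µV.  Marker
    positions are 1-based data-point indices as the format prescribes.
    """
    path = Path(path)
    stem = path.name.removesuffix(".vhdr")
    base = path.parent / stem
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch, n_samp = recording.signal.shape
    if n_ch != len(recording.channels):
        raise BrainVisionError("channel count does not match montage")
    interval_us = 1e6 / recording.fs

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    header += [
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(recording.channels)
    ]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for i, (sample, code) in enumerate(recording.events, start=2):
        if not (0 <= sample < n_samp):
            raise MarkerDataMismatchError(
                f"event at sample {sample} outside data of length {n_samp}"
            )
        markers.append(f"Mk{i}=Stimulus,S{int(code):>3},{int(sample) + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    recording.signal.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


_VHDR_KEYS = re.compile(r"^(NumberOfChannels|BinaryFormat|DataOrientation)=(.*)$", re.M)


def _precheck_triplet(vhdr: Path) -> None:
    """Cheap structural validation before handing the triplet to MNE."""
    text = vhdr.read_text(encoding="utf-8", errors="replace")
    info = dict(_VHDR_KEYS.findall(text))
    if "NumberOfChannels" not in info:
        raise BrainVisionError(f"{vhdr}: malformed header (no NumberOfChannels)")
    n_ch = int(info["NumberOfChannels"])
    fmt = info.get("BinaryFormat", "IEEE_FLOAT_32").strip()
    bytes_per = {"IEEE_FLOAT_32": 4, "INT_16": 2}.get(fmt)
    if bytes_per is None:
        raise BrainVisionError(f"{vhdr}: unsupported binary dialect {fmt!r}")
    m = re.search(r"^DataFile=(.*)$", text, re.M)
    eeg = vhdr.parent / (m.group(1).strip() if m else vhdr.stem + ".eeg")
    if not eeg.exists():
        raise BrainVisionError(f"{vhdr}: data file {eeg.name} not found")
    size = eeg.stat().st_size
    if size % (bytes_per * n_ch):
        raise BrainVisionError(f"{eeg}: size not a whole number of frames")
    n_samp = size // (bytes_per * n_ch)
    vmrk = vhdr.with_suffix(".vmrk")
    if vmrk.exists():
        positions = [
            int(mm.group(1))
            for mm in re.finditer(
                r"^Mk\d+=Stimulus,[^,]*,(\d+),", vmrk.read_text(), re.M
            )
        ]
        if positions and max(positions) > n_samp:
            raise MarkerDataMismatchError(
                f"{vmrk}: marker at data point {max(positions)} "
                f"but data has only {n_samp} samples"
            )


def read_brainvision(path: str | Path):
    """Read a BrainVision triplet into a Recording (signal in µV)."""
    import mne

    from .synthdata import Recording

    vhdr = Path(path)
    if vhdr.suffix != ".vhdr":
        vhdr = vhdr.with_suffix(".vhdr")
    if not vhdr.exists():
        raise FileNotFoundError(vhdr)
    _precheck_triplet(vhdr)
    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    signal = raw.get_data() * 1e6  # V -> µV
    events = []
    for annot in raw.annotations:
        m = re.match(r"Stimulus/S\s*(\d+)", annot["description"])
        if m:
            events.append((int(round(annot["onset"] * fs)), int(m.group(1))))
    events.sort()
    return Recording(
        signal=signal,
        fs=fs,
        channels=list(raw.ch_names),
        events=events,
    )
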