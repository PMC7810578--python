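"""Reading and writing recordings, annotations and profiles.

WAV files are mono RIFF/WAVE at 250 kHz by default, 32-bit float or 16-bit
PCM. Click annotations use the tab-separated label format common to audio
annotation tools (onset<TAB>offset<TAB>label, one event per line); duty-cycle
profiles are CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.io import wavfile

from .click_analysis import DutyCycleProfile
from .tymbal_model import ClickEvent, Recording

__all__ = ["write_wav", "read_wav", "write_labels", "read_labels", "write_profile_csv"]


def write_wav(path, rec: Recording, subtype: str = "float32") -> None:
    """Write a recording as mono WAV (``float32`` or ``pcm16``)."""
    path = Path(path)
    if subtype == "float32":
        wavfile.write(path, int(rec.sample_rate), rec.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(rec.samples, -1.0, 1.0)
        wavfile.write(path, int(rec.sample_rate), (clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}; use 'float32' or 'pcm16'")


def read_wav(path) -> Recording:
    """Read a mono WAV into a Recording with samples scaled to [-1, 1]."""
    rate, data = wavfile.read(Path(path))
    if data.ndim > 1:
        raise ValueError("only mono recordings are supported")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    else:
        samples = data.astype(np.float64)
    return Recording(samples, float(rate))


def write_labels(path, clicks: Iterable[ClickEvent], label: str = "click") -> None:
    """Write click events as a tab-separated label file (onset, offset, label)."""
    with open(path, "w", newline="") as fh:
        for c in clicks:
            fh.write(f"{c.onset:.6f}\t{c.offset:.6f}\t{label}\n")


def read_labels(path) -> list[ClickEvent]:
    """Read a tab-separated label file back into click events."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            onset, offset, _label = line.rstrip("\n").split("\t")
            out.append(ClickEvent(float(onset), float(offset) - float(onset)))
    return out


def write_profile_csv(path, profile: DutyCycleProfile) -> None:
    """Write a duty-cycle profile as CSV (window_start_s, click_count, dc_percent)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["window_start_s", "click_count", "dc_percent"])
        for t, n, dc in zip(profile.window_starts, profile.click_counts, profile.dc_values):
            writer.writerow([f"{t:.6f}", int(n), f"{dc:.6f}"])
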