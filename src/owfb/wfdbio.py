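"""Minimal reader/writer for PhysioNet WFDB (MIT) records.

Supports the subset of the MIT signal-file specification needed for
multi-channel Holter ECG ingest: single-segment records, one ``.dat`` file
shared by all signals, sample-interleaved storage, formats 16 (little-
endian 16-bit two's complement) and 80 (8-bit offset binary, as used by
low-resolution Holter archives).  Digital values are converted to physical
units as ``(adc - baseline) / gain``.

Only the header fields this package consumes are parsed; unknown trailing
header content is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ECGRecord

__all__ = ["read_wfdb", "write_wfdb"]

_SUPPORTED_FORMATS = (16, 80)


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str


def _parse_signal_line(line: str, index: int) -> _SignalSpec:
    parts = line.split()
    file_name = parts[0]
    fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
    gain_field = parts[2] if len(parts) > 2 else "200"
    units = ""
    if "/" in gain_field:
        gain_field, units = gain_field.split("/", 1)
    if "(" in gain_field:
        gain_str, baseline_str = gain_field.rstrip(")").split("(")
        gain = float(gain_str)
        baseline = int(baseline_str)
    else:
        gain = float(gain_field)
        baseline = int(parts[4]) if len(parts) > 4 else 0  # ADC zero
    if gain == 0:
        gain = 200.0  # WFDB convention for unspecified gain
    description = " ".join(parts[8:]) if len(parts) > 8 else f"CH{index + 1}"
    return _SignalSpec(file_name, fmt, gain, baseline, description)


def read_wfdb(path: str | Path) -> ECGRecord:
    """Load a WFDB record given the path to its ``.hea`` header.

    ``path`` may omit the ``.hea`` suffix.  Channel names are taken from
    the per-signal description field (header order preserved).
    """
    header = Path(path)
    if header.suffix != ".hea":
        header = header.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(f"WFDB header not found: {header}")
    lines = [
        ln.strip()
        for ln in header.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header: {header}")
    rec_fields = lines[0].split()
    if len(rec_fields) < 2:
        raise ValueError(f"malformed WFDB record line in {header}")
    nsig = int(rec_fields[1])
    if nsig < 1:
        raise ValueError(f"record {header} declares no signals")
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0

    specs = [_parse_signal_line(lines[1 + i], i) for i in range(nsig)]
    dat_names = {s.file_name for s in specs}
    if len(dat_names) != 1:
        raise ValueError("only single-.dat records are supported")
    fmts = {s.fmt for s in specs}
    if not fmts.issubset(set(_SUPPORTED_FORMATS)):
        raise ValueError(
            f"unsupported WFDB format(s) {sorted(fmts)}; "
            f"supported: {_SUPPORTED_FORMATS}"
        )
    fmt = specs[0].fmt
    dat = header.parent / specs[0].file_name
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = dat.read_bytes()
    if fmt == 16:
        digital = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    else:  # 80: offset binary bytes
        digital = np.frombuffer(raw, dtype=np.uint8).astype(np.int64) - 128
    usable = (len(digital) // nsig) * nsig
    digital = digital[:usable].reshape(-1, nsig)
    if nsamp and len(digital) > nsamp:
        digital = digital[:nsamp]

    channels = {}
    for i, s in enumerate(specs):
        channels[s.description] = (digital[:, i] - s.baseline) / s.gain
    return ECGRecord(channels=channels, fs=fs, subject_id=header.stem)


def write_wfdb(
    record: ECGRecord,
    directory: str | Path,
    name: str | None = None,
    fmt: int = 16,
    gain: float = 200.0,
) -> Path:
    """Write a record as a WFDB header + interleaved ``.dat`` pair.

    Physical values are quantized to ``round(x * gain)`` digital units
    (baseline 0) and clipped to the format's range, so the round trip is
    exact to ``1 / (2 * gain)``.  Returns the header path.
    """
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(f"format {fmt} not supported; use one of {_SUPPORTED_FORMATS}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or (record.subject_id or "record")
    names = list(record.channels)
    sigs = np.stack([record.channels[c] for c in names], axis=1)
    digital = np.round(sigs * gain).astype(np.int64)
    if fmt == 16:
        lo, hi = -32768, 32767
        encoded = np.clip(digital, lo, hi).astype("<i2").tobytes()
    else:
        lo, hi = -128, 127
        encoded = (np.clip(digital, lo, hi) + 128).astype(np.uint8).tobytes()
    dat_name = f"{name}.dat"
    (directory / dat_name).write_bytes(encoded)

    nsamp, nsig = sigs.shape
    lines = [f"{name} {nsig} {record.fs:g} {nsamp}"]
    for i, cname in enumerate(names):
        first = int(np.clip(digital[0, i], lo, hi))
        checksum = int(np.clip(digital[:, i], lo, hi).sum() % 65536)
        bits = 16 if fmt == 16 else 8
        lines.append(
            f"{dat_name} {fmt} {gain:g}(0)/mV {bits} 0 {first} {checksum} 0 {cname}"
        )
    header = directory / f"{name}.hea"
    header.write_text("\n".join(lines) + "\n")
    return header
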