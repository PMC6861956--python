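"""Per-sub-band log-energy and signal-fractal-dimension features.

Each 5-minute epoch yields twelve numbers: the log energy (LOGE) and the
signal fractal dimension (SFD) of each of the six sub-bands.

LOGE is ``log(sum |r(n)|^2)`` over the band's coefficients (natural log by
default; base 10 available -- the choice only rescales the downstream
linear index).

SFD estimates the box-counting dimension of the *graph* of the band: the
sample index is mapped affinely to [0, 1] and the amplitude range to
[0, 1], the unit square is tiled with boxes of side 2^-k for dyadic scales
k, the occupied boxes P_k are counted, and the least-squares slope of
log P_k versus log 2^k is returned.  A smooth curve has dimension 1, a
space-filling trace approaches 2; fractional-Brownian-like graphs with
Hurst exponent H have dimension 2 - H.  Katz's and Higuchi's estimators
are available as alternates since published feature magnitudes alone do
not pin the estimator down.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .design import WaveletFilterBank
from .dwt import decompose
from .preprocess import Epoch

logger = logging.getLogger(__name__)

__all__ = ["loge", "sfd", "feature_table", "FEATURE_COLUMNS"]

BAND_NAMES = tuple(f"SB{i}" for i in range(1, 7))
FEATURE_COLUMNS = tuple(f"LOGE_{b}" for b in BAND_NAMES) + tuple(
    f"SFD_{b}" for b in BAND_NAMES
)


def loge(band: np.ndarray, base: str = "natural") -> float:
    """Log of the band's summed squared amplitudes.

    ``base`` is ``"natural"`` or ``"ten"``.
    """
    x = np.asarray(band, dtype=float)
    if x.size == 0:
        raise ValueError("band is empty")
    energy = float(np.sum(x**2))
    if energy <= 0.0:
        raise ValueError("all-zero band: log energy undefined")
    if base == "natural":
        return math.log(energy)
    if base == "ten":
        return math.log10(energy)
    raise ValueError(f"unknown log base {base!r}; use 'natural' or 'ten'")


def _boxcount_dimension(x: np.ndarray, scales: range) -> float:
    """Least-squares box-counting slope on the graph of ``x``.

    Boxes are counted in the continuous (variation) form: within each
    column of width ``s = 2^-k`` the graph is connected, so it occupies
    ``max(span / s, 1)`` boxes, where ``span`` is the column's amplitude
    range.  Counting fractional boxes removes the integer-rounding bias
    that otherwise drags the slope of rough traces toward 1 at the sample
    sizes used here; smooth and constant curves still measure exactly 1.
    """
    n = len(x)
    t = np.arange(n) / (n - 1)
    lo, hi = float(x.min()), float(x.max())
    y = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    log_inv_s = []
    log_P = []
    for k in scales:
        nb = 1 << k
        col = np.minimum((t * nb).astype(np.int64), nb - 1)
        order = np.argsort(col, kind="stable")
        ys = y[order]
        bounds = np.flatnonzero(np.diff(col[order])) + 1
        count = 0.0
        for seg in np.split(ys, bounds):
            count += max((float(seg.max()) - float(seg.min())) * nb, 1.0)
        log_inv_s.append(k * math.log(2.0))
        log_P.append(math.log(count))
    slope = float(np.polyfit(log_inv_s, log_P, 1)[0])
    return slope


def _katz_dimension(x: np.ndarray) -> float:
    diffs = np.diff(x)
    L = float(np.sum(np.hypot(1.0, diffs)))
    d = float(np.max(np.hypot(np.arange(1, len(x)), x[1:] - x[0])))
    n = len(x) - 1
    if d == 0 or L == 0:
        return 1.0
    return math.log10(n) / (math.log10(n) + math.log10(d / L))

def _higuchi_dimension(x: np.ndarray, kmax: int = 8) -> float:
    n = len(x)
    ks, Ls = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            lk = np.abs(np.diff(x[idx])).sum() * (n - 1) / (len(idx) - 1) / k
            lm.append(lk / k)
        if lm:
            ks.append(math.log(1.0 / k))
            Ls.append(math.log(np.mean(lm)))
    return float(np.polyfit(ks, Ls, 1)[0])


def sfd(
    band: np.ndarray,
    scales: range | None = None,
    method: str = "boxcount",
) -> float:
    """Signal fractal dimension of a band, clamped to [1, 2].

    ``scales`` (box-counting only) is the range of dyadic exponents k;
    the default is 3..9 restricted to boxes no finer than half the sample
    count.  At least three scales are required.
    """
    x = np.asarray(band, dtype=float)
    if len(x) < 64:
        raise ValueError(f"band too short for SFD: {len(x)} < 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("band contains non-finite samples")
    if method == "boxcount":
        if scales is None:
            kmax = min(9, int(math.floor(math.log2(len(x) / 2))))
            scales = range(3, kmax + 1)
        if len(scales) < 3:
            raise ValueError(
                f"fewer than 3 usable dyadic scales for length {len(x)}"
            )
        dim = _boxcount_dimension(x, scales)
    elif method == "katz":
        dim = _katz_dimension(x)
    elif method == "higuchi":
        dim = _higuchi_dimension(x)
    else:
        raise ValueError(f"unknown SFD method {method!r}")
    if dim < 1.0 or dim > 2.0:
        warnings.warn(
            f"SFD estimate {dim:.3f} outside [1, 2]; clamping", stacklevel=2
        )
        dim = min(2.0, max(1.0, dim))
    return dim


def feature_table(
    epochs: list[Epoch],
    fb: WaveletFilterBank,
    log_base: str = "natural",
    sfd_method: str = "boxcount",
    levels: int = 5,
) -> pd.DataFrame:
    """LOGE and SFD of every sub-band of every epoch.

    One row per epoch keyed by (subject_id, epoch_index, channel) with the
    class label and twelve feature columns.  Epochs whose decomposition or
    feature computation fails are skipped with a logged warning; the skip
    count is reported at the end.
    """
    rows = []
    skipped = 0
    for ep in epochs:
        try:
            sbs = decompose(ep.samples, fb, levels=levels, fs=ep.fs,
                            epoch_id=ep.epoch_id)
            row: dict[str, object] = {
                "subject_id": ep.subject_id,
                "epoch_index": ep.epoch_index,
                "channel": ep.channel,
                "class_label": ep.class_label,
            }
            for name in sbs.names:
                row[f"LOGE_{name}"] = loge(sbs.bands[name], base=log_base)
                row[f"SFD_{name}"] = sfd(sbs.bands[name], method=sfd_method)
            rows.append(row)
        except (ValueError, FloatingPointError) as exc:
            skipped += 1
            logger.warning("skipping epoch %s: %s", ep.epoch_id, exc)
    if skipped:
        logger.warning("feature extraction skipped %d epoch(s)", skipped)
    columns = ["subject_id", "epoch_index", "channel", "class_label"]
    n_bands = levels + 1
    columns += [f"LOGE_SB{i}" for i in range(1, n_bands + 1)]
    columns += [f"SFD_SB{i}" for i in range(1, n_bands + 1)]
    return pd.DataFrame(rows, columns=columns)
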