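"""Raw scan -> 66x66x1 fingerprint pipeline.

Steps, in order: exposure normalization, removal of nonspectral
columns, wavelength trimming, contiguous bin averaging, per-channel
[0, 1] normalization, and zero-padding + reshape to a 66 x 66 x 1
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hsfkit.device import (
    EMISSION_MAX_NM,
    EMISSION_MIN_NM,
    N_EMISSION_PIXELS,
    N_LEDS,
    RawScan,
)

HSF_SIDE = 66
HSF_CELLS = HSF_SIDE * HSF_SIDE  # 4356

DEFAULT_TRIM_WINDOW = (250.0, 655.0)
DEFAULT_N_BINS = 360


@dataclass(frozen=True)
class PreprocessParams:
    trim_window: tuple[float, float] = DEFAULT_TRIM_WINDOW
    n_bins: int = DEFAULT_N_BINS


@dataclass(frozen=True)
class ChannelMatrix:
    """12 x B grid of exposure-normalized, binned channel intensities."""

    values: np.ndarray
    bin_centers: np.ndarray
    channel_led_index: tuple[int, ...] = tuple(range(N_LEDS))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        if v.ndim != 2 or v.shape[0] != N_LEDS:
            raise ValueError(f"expected {N_LEDS} channel rows, got shape {v.shape}")
        if v.shape[1] != len(self.bin_centers):
            raise ValueError("values/bin_centers length mismatch")


@dataclass(frozen=True)
class HSFMatrix:
    """The 66 x 66 x 1 fingerprint; values in [0, 1], trailing cells zero."""

    values: np.ndarray
    pad_count: int
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (HSF_SIDE, HSF_SIDE, 1):
            raise ValueError(f"fingerprint must be {HSF_SIDE}x{HSF_SIDE}x1, got {v.shape}")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("fingerprint values must lie in [0, 1]")
        if not 0 <= self.pad_count <= HSF_CELLS:
            raise ValueError("pad_count out of range")
        flat = v.ravel()
        if self.pad_count and np.any(flat[HSF_CELLS - self.pad_count:] != 0):
            raise ValueError("trailing pad cells must be exactly zero")

    def to_channels(self, n_bins: int) -> np.ndarray:
        """Inverse of pad_reshape: recover the 12 x B channel matrix."""
        if N_LEDS * n_bins + self.pad_count != HSF_CELLS:
            raise ValueError("n_bins inconsistent with pad_count")
        return self.values.ravel()[: N_LEDS * n_bins].reshape(N_LEDS, n_bins)


def normalize_exposure(scan: RawScan) -> RawScan:
    """Divide intensities by (integration_time x brightness) per row."""
    for led, _nm, _counts, t, b in scan.iter_blocks():
        if t <= 0:
            raise ValueError(f"block led_index={led}: non-positive integration_time {t}")
        if b <= 0:
            raise ValueError(f"block led_index={led}: non-positive brightness {b}")
    scaled = np.asarray(scan.intensity, dtype=float) / (
        np.asarray(scan.integration_time, dtype=float) * np.asarray(scan.brightness, dtype=float)
    )
    return RawScan(scan.led_index, scan.emission_nm, scaled,
                   scan.integration_time, scan.brightness, dict(scan.metadata))


def strip_nonspectral(scan: RawScan) -> tuple[np.ndarray, np.ndarray]:
    """Exposure-normalize, then keep only per-channel intensity curves.

    Returns ``(values, wavelengths)`` where ``values`` is 12 x 1516 and
    ``wavelengths`` is the shared emission axis; wavelength, time and
    brightness columns are dropped.
    """
    normed = normalize_exposure(scan)
    present = sorted(set(int(i) for i in np.unique(normed.led_index)))
    missing = sorted(set(range(N_LEDS)) - set(present))
    if missing:
        raise ValueError(f"scan is missing LED channels: {missing}")
    values = np.empty((N_LEDS, N_EMISSION_PIXELS), dtype=float)
    wavelengths = None
    for led, nm, counts, _t, _b in normed.iter_blocks():
        values[led] = counts
        if wavelengths is None:
            wavelengths = np.asarray(nm, dtype=float)
        elif not np.array_equal(wavelengths, nm):
            raise ValueError(f"block led_index={led}: emission axis differs between blocks")
    return values, wavelengths


def trim(values: np.ndarray, bin_centers: np.ndarray,
         window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Keep pixels with wavelength inside the closed window, all channels."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError(f"invalid trim window [{lo}, {hi}]")
    if lo < EMISSION_MIN_NM or hi > EMISSION_MAX_NM:
        raise ValueError(f"trim window must lie within [{EMISSION_MIN_NM}, {EMISSION_MAX_NM}]")
    centers = np.asarray(bin_centers, dtype=float)
    mask = (centers >= lo) & (centers <= hi)
    if not mask.any():
        raise ValueError("trim window contains no pixels")
    return np.asarray(values, dtype=float)[:, mask], centers[mask]


def bin_average(values: np.ndarray, bin_centers: np.ndarray, n_bins: int) -> ChannelMatrix:
    """Average contiguous pixel windows down to ``n_bins`` bins per channel.

    Bin b covers pixels [floor(b*P/n), floor((b+1)*P/n)); when P is not a
    multiple of n_bins the leftover pixels are spread over the leading
    bins, so the final (shorter) windows average over their actual
    members. Bin centers are the mean wavelength of each window.
    """
    values = np.asarray(values, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    n_pixels = values.shape[1]
    if n_bins <= 0:
        raise ValueError(f"n_bins must be positive, got {n_bins}")
    if n_bins > n_pixels:
        raise ValueError(f"n_bins ({n_bins}) exceeds pixels per channel ({n_pixels})")
    edges = (np.arange(n_bins + 1) * n_pixels) // n_bins
    out = np.empty((values.shape[0], n_bins), dtype=float)
    out_centers = np.empty(n_bins, dtype=float)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        out[:, b] = values[:, lo:hi].mean(axis=1)
        out_centers[b] = centers[lo:hi].mean()
    return ChannelMatrix(values=out, bin_centers=out_centers)


def normalize_channels(matrix: ChannelMatrix) -> ChannelMatrix:
    """Min-max map each channel row to [0, 1]; constant rows become zeros."""
    v = matrix.values
    if not np.all(np.isfinite(v)):
        raise ValueError("channel matrix contains non-finite values")
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(v)
    nonconst = span.ravel() > 0
    out[nonconst] = (v[nonconst] - lo[nonconst]) / span[nonconst]
    return ChannelMatrix(values=out, bin_centers=matrix.bin_centers,
                         channel_led_index=matrix.channel_led_index)


def pad_reshape(matrix: ChannelMatrix, provenance: str = "") -> HSFMatrix:
    """Row-major flatten, zero-pad to 4356 cells, reshape to 66 x 66 x 1."""
    v = matrix.values
    n = v.size
    if n > HSF_CELLS:
        raise ValueError(
            f"{N_LEDS} x {v.shape[1]} = {n} values exceed {HSF_CELLS}; "
            f"use a bin count of at most {HSF_CELLS // N_LEDS}"
        )
    pad_count = HSF_CELLS - n
    flat = np.concatenate([v.ravel(), np.zeros(pad_count)])
    return HSFMatrix(values=flat.reshape(HSF_SIDE, HSF_SIDE, 1),
                     pad_count=pad_count, provenance=provenance)


def preprocess_scan(scan: RawScan, params: PreprocessParams | None = None) -> HSFMatrix:
    """Full deterministic pipeline from a raw scan to the fingerprint."""
    params = params or PreprocessParams()
    values, wavelengths = strip_nonspectral(scan)
    values, wavelengths = trim(values, wavelengths, params.trim_window)
    matrix = bin_average(values, wavelengths, params.n_bins)
    matrix = normalize_channels(matrix)
    provenance = str(scan.metadata.get("sample_id", ""))
    return pad_reshape(matrix, provenance=provenance)
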