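"""Fragment-length distribution and FFT-based nucleosome periodicity estimate.

The length histogram of a good ATAC-seq library shows a sub-nucleosomal
mode plus modes at integer multiples of the inter-nucleosome spacing; the
spacing is recovered as the dominant period of the detrended histogram's
discrete power spectrum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_MAX_LENGTH = 1000
DEFAULT_SEARCH_BAND = (100, 400)
# The detrend moving average acts as a high-pass filter; its width must sit
# well above the search-band maximum or it suppresses the very periods being
# searched (a 51-bp window retains only ~12% of a 190-bp component).
DEFAULT_DETREND_WINDOW = 401

#: FFT length is the next power of two >= this multiple of the histogram
#: length; heavy zero-padding keeps the period grid fine (< 4 bp near 200 bp).
_PAD_FACTOR = 16


@dataclass
class LengthHistogram:
    """Fragment counts per 1-bp length bin; ``counts[L]`` is the count at length L."""

    max_length: int
    counts: np.ndarray  # shape (max_length + 1,); index 0 unused

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for L in range(1, self.max_length + 1):
                fh.write(f"{L}\t{int(self.counts[L])}\n")


@dataclass
class PeriodEstimate:
    """Dominant period of the fragment-length distribution."""

    period: float
    search_band: tuple
    power_spectrum: np.ndarray  # rows of (frequency 1/bp, power)
    has_signal: bool

    def band_spectrum(self) -> np.ndarray:
        """(period_bp, power) rows restricted to the search band."""
        f = self.power_spectrum[:, 0]
        mask = f > 0
        periods = np.zeros_like(f)
        periods[mask] = 1.0 / f[mask]
        sel = mask & (periods >= self.search_band[0]) & (periods <= self.search_band[1])
        return np.column_stack([periods[sel], self.power_spectrum[sel, 1]])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "period_bp": self.period,
            "search_band": list(self.search_band),
            "has_signal": self.has_signal,
        }, indent=2) + "\n")

    def spectrum_tsv(self, path) -> None:
        band = self.band_spectrum()
        with open(path, "w") as fh:
            fh.write("period_bp\tpower\n")
            for p, pw in band:
                fh.write(f"{p:.4f}\t{pw:.6g}\n")


def length_histogram(fragments, max_length: int = DEFAULT_MAX_LENGTH) -> LengthHistogram:
    """Bin fragment lengths at 1 bp; lengths beyond ``max_length`` are dropped."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    counts = np.zeros(max_length + 1, dtype=np.int64)
    n_over = 0
    for f in fragments:
        L = f.length if hasattr(f, "length") else int(f)
        if L > max_length:
            n_over += 1
        elif L >= 1:
            counts[L] += 1
    if n_over:
        warnings.warn(f"{n_over} fragments longer than {max_length} bp excluded")
    if counts.sum() == 0:
        warnings.warn("empty fragment-length histogram")
    return LengthHistogram(max_length=max_length, counts=counts)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def estimate_period_fft(hist: LengthHistogram,
                        search_band=DEFAULT_SEARCH_BAND,
                        detrend_window: int = DEFAULT_DETREND_WINDOW) -> PeriodEstimate:
    """Estimate the dominant period of the length histogram.

    The counts are detrended by subtracting a centered moving average of
    width ``detrend_window``, zero-padded, and Fourier transformed; the
    period is 1/f* where f* maximizes band power, refined by parabolic
    interpolation across the three bins around the maximum. ``has_signal``
    is false when the maximal band power is below 4x the median band power.
    """
    lo, hi = search_band
    if not (2 < lo < hi):
        raise ValueError("search band must satisfy 2 < min < max")
    if hi > hist.max_length:
        raise ValueError("histogram shorter than search band maximum")
    if detrend_window < 3 or detrend_window % 2 == 0:
        raise ValueError("detrend_window must be odd and >= 3")

    counts = hist.counts[1:].astype(float)  # series over lengths 1..max_length
    detrended = counts - _moving_average(counts, detrend_window)
    detrended -= detrended.mean()

    nfft = 1 << int(np.ceil(np.log2(max(_PAD_FACTOR * len(detrended), 64))))
    power = np.abs(np.fft.rfft(detrended, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0)
    spectrum = np.column_stack([freqs, power])

    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    band = np.nonzero((periods >= lo) & (periods <= hi))[0]
    band_power = power[band]
    if band_power.max() <= 0:
        return PeriodEstimate(float("nan"), (lo, hi), spectrum, False)

    k = band[np.argmax(band_power)]
    # parabolic refinement on the power spectrum around the peak bin
    f_star = freqs[k]
    if 0 < k < len(power) - 1:
        y0, y1, y2 = power[k - 1], power[k], power[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            f_star = freqs[k] + delta * (freqs[1] - freqs[0])
    period = 1.0 / f_star

    med = float(np.median(band_power))
    has_signal = band_power.max() >= 4.0 * med if med > 0 else True
    if not np.isfinite(period) or not (lo <= period <= hi):
        period = float(np.clip(period, lo, hi))
    return PeriodEstimate(float(period), (lo, hi), spectrum, bool(has_signal))


def plot_histogram(hist: LengthHistogram, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(np.arange(1, hist.max_length + 1), hist.counts[1:], lw=0.8)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(est: PeriodEstimate, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    band = est.band_spectrum()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if len(band):
        order = np.argsort(band[:, 0])
        ax.plot(band[order, 0], band[order, 1], lw=0.8)
    if np.isfinite(est.period):
        ax.axvline(est.period, color="r", ls="--", lw=0.8,
                   label=f"period {est.period:.1f} bp")
        ax.legend()
    ax.set_xlabel("period (bp)")
    ax.set_ylabel("power")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
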