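"""Cross-spectral estimation and magnitude-squared coherence.

Welch-style estimation: each epoch is cut into tapered, 50%-overlapping
segments; per-segment FFT cross-products are averaged over all segments
pooled across the trials supplied (one estimate per subject x condition),
and coherence per frequency bin is

    C_xy(f) = |W_xy(f)|^2 / (W_x(f) W_y(f)),

with W the averaged (cross-)spectra. Band coherence is the unweighted
mean of per-bin coherence over the bins in [f_lo, f_hi) -- closed on the
left, open on the right, so the default alpha (8-13 Hz) and beta
(13-30 Hz) bands are disjoint at 13 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .synthetic import EpochedSourceSeries

DEFAULT_BANDS = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass(frozen=True)
class SpectralConfig:
    """Segmentation and band layout for coherence estimation.

    The 1 s default segment (250 samples at 250 Hz) gives 1 Hz bins --
    enough to resolve the 5 Hz wide alpha band -- and five segments per
    3 s epoch at 50% overlap.
    """

    segment_samples: int = 250
    overlap_fraction: float = 0.5
    taper: str = "hann"                 # "hann" | "tukey10"
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    sample_rate: float = 250.0

    def __post_init__(self):
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.segment_samples < 2:
            raise ValueError("segment_samples must be >= 2")
        nyq = self.sample_rate / 2.0
        for name, (lo, hi) in self.bands.items():
            if not (0.0 < lo < hi <= nyq):
                raise ValueError(f"band {name!r} edges {lo, hi} outside (0, {nyq}]")
        if self.taper not in ("hann", "tukey10"):
            raise ValueError(f"unknown taper {self.taper!r}")

    @property
    def step(self) -> int:
        return max(1, int(round(self.segment_samples
                                * (1.0 - self.overlap_fraction))))

    def window(self) -> np.ndarray:
        if self.taper == "hann":
            return _sig.windows.hann(self.segment_samples, sym=False)
        # 10% cosine-tapered (Tukey) alternative reading of the taper spec
        return _sig.windows.tukey(self.segment_samples, alpha=0.2, sym=False)

    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.segment_samples, d=1.0 / self.sample_rate)


@dataclass
class CrossSpectralMatrix:
    """Averaged cross-spectral density: one Hermitian matrix per bin."""

    freqs: np.ndarray                   # (n_freq,)
    W: np.ndarray                       # (n_freq, n_roi, n_roi) complex
    n_segments: int
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    @property
    def n_roi(self) -> int:
        return self.W.shape[1]


@dataclass
class CoherenceMatrix:
    """Band-averaged magnitude-squared coherence; symmetric, unit diagonal."""

    band: str
    C: np.ndarray                       # (n_roi, n_roi) in [0, 1]
    n_segments: int

    @property
    def n_roi(self) -> int:
        return self.C.shape[0]


def _segments(data: np.ndarray, seg: int, step: int) -> np.ndarray:
    """(n_seg, n_roi, seg) view of an (n_roi, n_samples) epoch."""
    n = data.shape[1]
    if n < seg:
        raise ValueError(f"epoch of {n} samples shorter than one "
                         f"{seg}-sample segment")
    starts = range(0, n - seg + 1, step)
    return np.stack([data[:, s:s + seg] for s in starts])


def compute_cross_spectra(epochs: list[EpochedSourceSeries],
                          config: SpectralConfig) -> CrossSpectralMatrix:
    """Average tapered-periodogram cross-products over all segments of all
    epochs supplied (trial pooling).

    Segments are mean-removed and tapered before the FFT; the scaling is
    the standard Welch density normalization (it cancels in coherence).
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    n_roi = epochs[0].data.shape[0]
    fs = epochs[0].sample_rate
    for e in epochs:
        if e.data.shape[0] != n_roi:
            raise ValueError("mismatched channel counts across epochs")
        if e.sample_rate != fs:
            raise ValueError("mismatched sample rates across epochs")
    if fs != config.sample_rate:
        raise ValueError("config.sample_rate does not match the epochs")

    win = config.window()
    scale = 1.0 / (fs * np.sum(win ** 2))
    n_freq = config.segment_samples // 2 + 1
    acc = np.zeros((n_freq, n_roi, n_roi), dtype=complex)
    n_segments = 0
    for e in epochs:
        segs = _segments(e.data, config.segment_samples, config.step)
        segs = segs - segs.mean(axis=2, keepdims=True)
        spec = np.fft.rfft(segs * win, axis=2)      # (n_seg, n_roi, n_freq)
        acc += np.einsum("aif,ajf->fij", spec, np.conj(spec))
        n_segments += segs.shape[0]
    w = acc * (scale / n_segments)
    # one-sided density doubling (all bins except DC and Nyquist)
    w[1:-1] *= 2.0 if config.segment_samples % 2 == 0 else 1.0
    if config.segment_samples % 2 != 0:
        w[1:] *= 2.0
    return CrossSpectralMatrix(config.freqs(), w, n_segments,
                               bands=dict(config.bands))


def coherence_per_bin(csd: CrossSpectralMatrix) -> np.ndarray:
    """Per-bin coherence matrices (n_freq, n_roi, n_roi).

    Bins with zero power in either signal yield coherence 0 (with a
    warning); the diagonal is set to 1. A single-segment estimate is
    flagged: its off-diagonal coherence is identically 1 and carries no
    information.
    """
    if csd.n_segments < 2:
        warnings.warn("coherence from a single segment is identically 1",
                      stacklevel=2)
    power = np.real(np.einsum("fii->fi", csd.W))       # (n_freq, n_roi)
    denom = power[:, :, None] * power[:, None, :]
    num = np.abs(csd.W) ** 2
    zero = denom <= 0
    if np.any(zero & ~np.eye(csd.n_roi, dtype=bool)[None]):
        warnings.warn("zero-power bins encountered; their coherence is 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(zero, 0.0, num / np.where(zero, 1.0, denom))
    c = np.clip(np.real(c), 0.0, 1.0)
    idx = np.arange(csd.n_roi)
    c[:, idx, idx] = 1.0
    return c


def band_coherence_matrix(csd: CrossSpectralMatrix,
                          band: str | tuple[float, float]) -> CoherenceMatrix:
    """Mean per-bin coherence over the bins with f_lo <= f < f_hi."""
    if isinstance(band, str):
        if band not in csd.bands:
            raise KeyError(f"band {band!r} not defined")
        lo, hi = csd.bands[band]
        name = band
    else:
        lo, hi = band
        name = f"{lo}-{hi}Hz"
    mask = (csd.freqs >= lo) & (csd.freqs < hi)
    if not np.any(mask):
        raise ValueError(f"no frequency bins fall in band [{lo}, {hi})")
    c = coherence_per_bin(csd)[mask].mean(axis=0)
    c = 0.5 * (c + c.T)                 # exact symmetry against rounding
    np.fill_diagonal(c, 1.0)
    return CoherenceMatrix(name, c, csd.n_segments)


def coherence_matrices(epochs: list[EpochedSourceSeries],
                       config: SpectralConfig) -> dict[str, CoherenceMatrix]:
    """All configured band-coherence matrices for one pooled set of epochs."""
    csd = compute_cross_spectra(epochs, config)
    return {name: band_coherence_matrix(csd, name) for name in config.bands}
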