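"""Per-second amplitude spectra and spectral-peak significance criteria.

Each 300-s epoch is analysed with 2-s Hann windows advanced by 1 s (50%
overlap), giving one spectrum per second on a 0.5 Hz grid.  A frequency bin
between 1 and 25 Hz counts as a significant oscillation in a given second
when, simultaneously,

(a) its amplitude is at least 5% of the maximum amplitude of that same
    frequency over the surrounding 4 s (windows starting within +/-2 s),
(b) its amplitude is at least 50% of the largest amplitude in that window's
    1-25 Hz spectrum, and
(c) it strictly exceeds its four neighbouring bins (+/-0.5 and +/-1.0 Hz).

All three criteria are relative, so the detected peak set of a channel is
invariant under rescaling of that channel.  An optional absolute amplitude
floor (in microvolt-equivalent sinusoid amplitude) can be enabled for data
where the noise floor would otherwise produce spurious relative peaks; it is
off by default.

Amplitudes are normalised to equivalent-sinusoid microvolts: a pure,
bin-centred sinusoid of amplitude A microvolts reads A at its bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import get_window

WINDOW_SECONDS = 2.0
STEP_SECONDS = 1.0
#: analysed band (inclusive) and the margin kept so edge bins have neighbours
FMIN, FMAX = 1.0, 25.0
GRID_MAX = 26.0  # spectra carry 0..26 Hz so 1 and 25 Hz have four neighbours
BIN_HZ = 0.5


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the peak-significance criteria.

    local_frac
        criterion (a): fraction of the temporal-neighbourhood maximum.
    global_frac
        criterion (b): fraction of the window's 1-25 Hz maximum.
    neighbourhood_s
        half-width (s) of the temporal neighbourhood in criterion (a).
    floor_uv
        optional absolute amplitude floor (equivalent-sinusoid uV); None
        disables it and leaves the criteria purely relative.
    """

    local_frac: float = 0.05
    global_frac: float = 0.50
    neighbourhood_s: float = 2.0
    floor_uv: float | None = None


@dataclass
class EpochSpectra:
    """Amplitude spectra of one epoch: (window, channel, frequency bin)."""

    amplitudes: np.ndarray  # (n_windows, n_channels, n_bins), uV
    bins: np.ndarray  # Hz, 0.5 Hz spacing, 0 .. 26 Hz
    window_times: np.ndarray  # window start times within the epoch, s

    @property
    def n_windows(self) -> int:
        return self.amplitudes.shape[0]


@dataclass
class PeakSet:
    """Per-second, per-channel significant frequencies within 1-25 Hz.

    ``mask[t, c, k]`` is True when bin ``freqs[k]`` is significant for
    channel ``c`` in the window starting at second ``t``.
    """

    mask: np.ndarray  # (n_windows, n_channels, n_freqs) bool
    freqs: np.ndarray  # Hz, 1.0 .. 25.0 in 0.5 steps

    def sets(self, window: int) -> list[frozenset[float]]:
        """Frozen frequency sets of every channel for one second."""
        return [
            frozenset(self.freqs[self.mask[window, c]])
            for c in range(self.mask.shape[1])
        ]


def windowed_spectra(data: np.ndarray, sfreq: float = 256.0) -> EpochSpectra:
    """Sliding Hann-window amplitude spectra, one window per second.

    ``data`` is (n_channels, n_samples) in microvolts.  A 300-s epoch yields
    299 windows.  Raises ``ValueError`` for segments shorter than one window.
    """
    data = np.asarray(data, dtype=float)
    nwin = int(round(WINDOW_SECONDS * sfreq))
    step = int(round(STEP_SECONDS * sfreq))
    n_samples = data.shape[-1]
    if n_samples < nwin:
        raise ValueError("input shorter than one 2-s analysis window")
    n_windows = (n_samples - nwin) // step + 1

    window = get_window("hann", nwin, fftbins=True)
    idx = np.arange(nwin)[None, :] + step * np.arange(n_windows)[:, None]
    segments = data[:, idx] * window  # (n_channels, n_windows, nwin)

    n_keep = int(GRID_MAX / BIN_HZ) + 1  # 0 .. 26 Hz inclusive
    coeffs = np.fft.rfft(segments, axis=-1)[..., :n_keep]
    # equivalent sinusoid amplitude: peak of a bin-centred tone of amplitude
    # A is A * sum(window) / 2
    amps = np.abs(coeffs) / (window.sum() / 2.0)
    amps = np.moveaxis(amps, 0, 1)  # (n_windows, n_channels, n_bins)

    bins = np.arange(n_keep) * BIN_HZ
    times = STEP_SECONDS * np.arange(n_windows)
    return EpochSpectra(amplitudes=amps, bins=bins, window_times=times)


def significant_frequencies(
    spectra: EpochSpectra, cfg: CriteriaConfig | None = None
) -> PeakSet:
    """Apply criteria (a)-(c) to windowed spectra.

    Returns the per-second, per-channel sets of significant bins on the
    1-25 Hz grid.  An empty set is a valid outcome (criterion (c) fails on
    ties, so an all-zero channel yields no peaks).
    """
    cfg = cfg or CriteriaConfig()
    amp = spectra.amplitudes
    lo = int(round(FMIN / BIN_HZ))
    hi = int(round(FMAX / BIN_HZ))
    if amp.shape[-1] < hi + 3:
        raise ValueError("spectra lack the 0.5 Hz margin beyond 25 Hz")

    # (a) temporal neighbourhood: windows starting within +/-neighbourhood_s,
    # truncated at the epoch edges (amplitudes are non-negative, so padding
    # with zeros realises the truncated maximum)
    n_nb = 2 * int(round(cfg.neighbourhood_s / STEP_SECONDS)) + 1
    local_max = maximum_filter1d(amp, size=n_nb, axis=0, mode="constant", cval=0.0)
    cond_a = amp >= cfg.local_frac * local_max

    # (b) fraction of the window's maximum over the analysed 1-25 Hz band
    band_max = amp[:, :, lo : hi + 1].max(axis=2, keepdims=True)
    cond_b = amp >= cfg.global_frac * band_max

    # (c) strictly larger than the four neighbouring coefficients
    center = amp[:, :, lo : hi + 1]
    cond_c = (
        (center > amp[:, :, lo - 1 : hi])
        & (center > amp[:, :, lo + 1 : hi + 2])
        & (center > amp[:, :, lo - 2 : hi - 1])
        & (center > amp[:, :, lo + 2 : hi + 3])
    )

    mask = cond_a[:, :, lo : hi + 1] & cond_b[:, :, lo : hi + 1] & cond_c
    if cfg.floor_uv is not None:
        mask &= center >= cfg.floor_uv
    freqs = spectra.bins[lo : hi + 1]
    return PeakSet(mask=mask, freqs=freqs)
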