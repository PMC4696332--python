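"""Welch power spectra and the collapsed (channel-averaged) spectrum.

One Hann-windowed periodogram per artifact-free epoch, averaged over kept
epochs — Welch's method with the 2-s epochs themselves as segments and no
overlap.  Density scaling divides by fs times the window's summed square
(i.e. the window mean-square normalisation), so broadband noise levels
are unbiased.  With 2-s epochs the frequency grid has the 0.5 Hz spacing
all band arithmetic assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .channels import MACROAREAS, resolve_subset
from .preprocess import EpochSet


@dataclass
class PowerSpectrum:
    """Per-channel power spectral density on a uniform frequency grid."""

    freqs: np.ndarray          # Hz, 0 .. Nyquist
    power: np.ndarray          # channels x bins, µV²/Hz
    channels: list[str]
    n_epochs_used: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != self.freqs.size:
            raise ValueError("power must be channels x len(freqs)")
        if (self.power < 0).any():
            raise ValueError("power density must be nonnegative")

    @property
    def df(self) -> float:
        """Grid spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class CollapsedSpectrum:
    """Channel-averaged ('global field') power spectrum."""

    freqs: np.ndarray
    power: np.ndarray          # single vector, µV²/Hz
    channel_set: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != self.freqs.shape:
            raise ValueError("power must match freqs")
        if (self.power < 0).any():
            raise ValueError("power density must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(ep: EpochSet) -> PowerSpectrum:
    """Average Hann-windowed per-epoch periodograms over kept epochs.

    Grid spacing is 1/epoch_length Hz (0.5 Hz for 2-s epochs).  Only
    epochs with ``kept_mask`` true contribute.
    """
    kept = ep.kept_epochs()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs; cannot estimate a spectrum")
    freqs, pxx = signal.periodogram(
        kept, fs=ep.fs, window="hann", detrend=False, scaling="density", axis=-1
    )
    return PowerSpectrum(
        freqs=freqs,
        power=pxx.mean(axis=0),
        channels=list(ep.source_channels),
        n_epochs_used=kept.shape[0],
    )


def collapse_spectrum(
    ps: PowerSpectrum, channel_subset: Sequence[str] | None = None
) -> CollapsedSpectrum:
    """Unweighted arithmetic mean of the selected channels' power vectors.

    ``channel_subset=None`` averages all channels (the global field
    spectrum).  Unknown labels raise.
    """
    if channel_subset is None:
        labels = list(ps.channels)
        idx = np.arange(len(labels))
    else:
        if len(channel_subset) == 0:
            raise ValueError("channel subset must be non-empty")
        labels = resolve_subset(channel_subset, ps.channels)
        pos = {lab: i for i, lab in enumerate(ps.channels)}
        idx = np.array([pos[lab] for lab in labels])
    return CollapsedSpectrum(
        freqs=ps.freqs.copy(),
        power=ps.power[idx].mean(axis=0),
        channel_set=labels,
    )


def band_power(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Integrated power over the half-open band [lo, hi): sum of bins x Δf."""
    freqs = np.asarray(freqs, float)
    mask = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) contains no frequency bins")
    df = float(freqs[1] - freqs[0])
    return float(np.sum(power[..., mask], axis=-1) * df)


def macroarea_alpha_correlation(
    spectra: Sequence[PowerSpectrum],
    area: str,
    band: tuple[float, float],
    macroareas: dict[str, Sequence[str]] | None = None,
) -> tuple[float, float]:
    """Pearson r, across subjects, between global and macroarea band power.

    For each subject the band power of the all-channel collapsed spectrum
    is paired with the band power of the spectrum collapsed over the
    named macroarea ('frontotemporal' or 'parietoccipital' by default).
    This is the consistency check that the collapsed global spectrum
    tracks regional alpha content.  Requires >= 3 subjects and nonzero
    variance in both vectors.
    """
    areas = {**MACROAREAS, **(macroareas or {})}
    if area not in areas:
        raise KeyError(f"unknown macroarea {area!r}; have {sorted(areas)}")
    if len(spectra) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    lo, hi = band
    glob, macro = [], []
    for ps in spectra:
        g = collapse_spectrum(ps)
        m = collapse_spectrum(ps, areas[area])
        glob.append(band_power(g.freqs, g.power, lo, hi))
        macro.append(band_power(m.freqs, m.power, lo, hi))
    glob_a, macro_a = np.asarray(glob), np.asarray(macro)
    if np.ptp(glob_a) == 0 or np.ptp(macro_a) == 0:
        raise ValueError("zero variance in band-power vector")
    r, p = stats.pearsonr(glob_a, macro_a)
    return float(r), float(p)


def spectrum_to_tsv(ps: PowerSpectrum, path) -> None:
    """Export a per-channel spectrum as TSV (freq column + one per channel)."""
    import pandas as pd

    out = pd.DataFrame({"freq_hz": ps.freqs})
    for i, lab in enumerate(ps.channels):
        out[lab] = ps.power[i]
    out.to_csv(path, sep="\t", index=False)
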