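"""Synthetic EEG and cohort generation with analytically known structure.

EEG model: every channel mixes a scalp-wide shared component and an
independent local component, both realisations of the same source
process — 1/f^a colored background plus narrowband oscillators with
Gaussian spectral profile: a theta oscillator below the theta/alpha
transition, a low-alpha oscillator just under the individual alpha peak
and a high-alpha oscillator at the peak itself — scaled by a per-channel
gain, plus independent white sensor noise:

    x_c(t) = g_c * [ sqrt(rho) s0(t) + sqrt(1-rho) v_c(t) ] + n_c(t)

Synthesis happens in the frequency domain (Gaussian random spectrum
shaped by the target PSD), so the expected power spectral density of
every recording — before or after common-average re-referencing, raw or
as seen through the Hann-windowed Welch estimator — is available in
closed form and serves as the oracle for anchor-recovery tests.

Cohorts: per-outcome-group multivariate-normal draws of markers and
covariates with configurable means, SDs and correlation structure,
truncated to plausible clinical ranges.  Markers can instead be
re-derived by running the signal pipeline on generated recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import CANONICAL_19
from .config import PipelineConfig
from .io import CohortTable, Recording

# ---------------------------------------------------------------------------
# subject-level EEG


@dataclass
class SubjectSpec:
    """Ground-truth spectral parameters for one synthetic subject.

    Oscillator amplitudes are RMS µV of the source process: ``amp_theta``
    below TF (default centre TF − 1.5 Hz), ``amp_alpha_low`` just below
    the alpha peak (default IAF − 1.5 Hz, feeding the alpha2 band) and
    ``amp_alpha_high`` at the IAF itself (the spectral maximum, feeding
    alpha3).  ``onef_amplitude`` is the 1/f^a background level at 1 Hz;
    ``noise_sd`` is per-channel white sensor noise; ``shared_fraction``
    is the variance fraction of the source common to all channels (the
    rest is channel-local, so a common-average reference does not cancel
    the signal).
    """

    iaf_true: float = 10.0
    tf_true: float = 6.5
    amp_theta: float = 4.0
    amp_alpha_low: float = 4.0
    amp_alpha_high: float = 5.0
    theta_freq: float | None = None        # default tf_true - 1.5
    alpha_low_offset: float = 1.5          # Hz below IAF
    osc_bandwidth: float = 1.5             # FWHM, Hz
    onef_exponent: float = 1.4
    onef_amplitude: float = 12.0           # µV²/Hz at 1 Hz
    noise_sd: float = 2.0                  # µV per channel
    shared_fraction: float = 0.3
    gains: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 5.0 <= self.iaf_true <= 14.0:
            raise ValueError("iaf_true must lie in [5, 14] Hz")
        if self.tf_true >= self.iaf_true:
            raise ValueError("tf_true must be below iaf_true")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        for name in ("amp_theta", "amp_alpha_low", "amp_alpha_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def theta_center(self) -> float:
        return self.tf_true - 1.5 if self.theta_freq is None else self.theta_freq

    def gain_vector(self, channels: Sequence[str] = CANONICAL_19) -> np.ndarray:
        return np.array([self.gains.get(ch, 1.0) for ch in channels])


def _gauss_profile(freqs: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-integral Gaussian spectral profile (one-sided)."""
    sigma = fwhm / 2.355
    prof = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    return prof / (sigma * np.sqrt(2 * np.pi))


def source_psd(spec: SubjectSpec, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD (µV²/Hz) of the source process (gain 1, no sensor noise)."""
    freqs = np.asarray(freqs, float)
    f_safe = np.maximum(freqs, 0.5)
    psd = spec.onef_amplitude / f_safe**spec.onef_exponent
    bw = spec.osc_bandwidth
    psd = psd + spec.amp_theta**2 * _gauss_profile(freqs, spec.theta_center, bw)
    psd = psd + spec.amp_alpha_low**2 * _gauss_profile(
        freqs, spec.iaf_true - spec.alpha_low_offset, bw
    )
    psd = psd + spec.amp_alpha_high**2 * _gauss_profile(freqs, spec.iaf_true, bw)
    return psd


def analytic_collapsed_psd(
    spec: SubjectSpec,
    freqs: np.ndarray,
    fs: float = 250.0,
    channels: Sequence[str] = CANONICAL_19,
    reference: str = "common-average",
) -> np.ndarray:
    """Expected collapsed (channel-averaged) PSD of a generated recording.

    ``reference='as-recorded'`` gives mean_c g_c² S + 2 sigma²/fs.  After
    common-average re-referencing the shared source component survives
    only through gain differences while the channel-local component is
    attenuated by (1 - 1/C)-type factors; both are closed form.
    """
    S = source_psd(spec, freqs)
    g = spec.gain_vector(channels)
    C = g.size
    noise_floor = 2.0 * spec.noise_sd**2 / fs
    rho = spec.shared_fraction
    if reference == "as-recorded":
        return float(np.mean(g**2)) * S + noise_floor
    if reference != "common-average":
        raise ValueError(f"unknown reference {reference!r}")
    gbar = g.mean()
    G2 = float(np.sum(g**2))
    shared_term = float(np.mean((g - gbar) ** 2))
    local_term = float(
        np.mean((g * (1 - 1 / C)) ** 2 + (G2 - g**2) / C**2)
    )
    sig = rho * shared_term + (1 - rho) * local_term
    return sig * S + (1 - 1 / C) * noise_floor


def hann_power_kernel(
    fs: float, epoch_length: float, oversample: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Squared-magnitude spectral kernel of the Hann window, unit integral.

    Returns (offsets_hz, kernel) on a grid of spacing
    1/(epoch_length*oversample); convolving a PSD with this kernel gives
    the expected Hann-windowed periodogram.
    """
    n = int(round(epoch_length * fs))
    w = np.hanning(n)
    m = n * oversample
    W = np.fft.fft(w, m)
    k = np.abs(W) ** 2
    k = np.fft.fftshift(k)
    offsets = (np.arange(m) - m // 2) * (fs / m)
    df = fs / m
    k /= k.sum() * df
    keep = np.abs(offsets) <= 5.0  # kernel mass beyond +-5 Hz is negligible
    return offsets[keep], k[keep]


def expected_welch_psd(
    spec: SubjectSpec,
    freqs: np.ndarray,
    fs: float = 250.0,
    epoch_length: float = 2.0,
    channels: Sequence[str] = CANONICAL_19,
    reference: str = "common-average",
) -> np.ndarray:
    """Expected value of the collapsed Welch estimate on the given bins.

    The process PSD convolved with the Hann window's power kernel —
    i.e. exactly what the pipeline's spectral estimator converges to.
    """
    offsets, kernel = hann_power_kernel(fs, epoch_length)
    dfine = offsets[1] - offsets[0]
    fine = np.arange(0.0, fs / 2 + dfine, dfine)
    psd_fine = analytic_collapsed_psd(spec, fine, fs, channels, reference)
    smeared = np.convolve(psd_fine, kernel, mode="same") * dfine
    return np.interp(np.asarray(freqs, float), fine, smeared)


def _synthesize(psd: np.ndarray, n: int, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian series with expected one-sided PSD ``psd``
    (sampled on the rfft grid for length n)."""
    scale = np.sqrt(psd * fs * n / 2.0)
    z = rng.normal(size=psd.size) + 1j * rng.normal(size=psd.size)
    z *= scale / np.sqrt(2.0)
    z[0] = 0.0  # zero-mean signal
    if n % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2.0)
    return np.fft.irfft(z, n=n)


def generate_eeg(
    spec: SubjectSpec,
    duration: float = 300.0,
    fs: float = 250.0,
    channels: Sequence[str] = CANONICAL_19,
) -> Recording:
    """Generate a multichannel resting-state recording from a SubjectSpec.

    Deterministic given ``spec.seed``.  Duration must be at least 4 s so
    at least two 2-s epochs exist.
    """
    if duration < 4.0:
        raise ValueError("duration must be at least 4 s")
    n = int(round(duration * fs))
    rng = np.random.default_rng(spec.seed)
    psd = source_psd(spec, np.fft.rfftfreq(n, 1 / fs))
    rho = spec.shared_fraction
    shared = _synthesize(psd, n, fs, rng) if rho > 0 else 0.0
    g = spec.gain_vector(channels)
    data = np.empty((len(channels), n))
    for c in range(len(channels)):
        local = _synthesize(psd, n, fs, rng) if rho < 1 else 0.0
        src = np.sqrt(rho) * shared + np.sqrt(1 - rho) * local
        data[c] = g[c] * src
    data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return Recording(samples=data, fs=fs, channels=list(channels))


def inject_spikes(
    rec: Recording,
    times_s: Sequence[float],
    amplitude_uv: float = 500.0,
    channel: int = 0,
    width_s: float = 0.05,
) -> Recording:
    """Return a copy with square artifact spikes added (for rejection tests)."""
    data = rec.samples.copy()
    half = max(1, int(width_s * rec.fs / 2))
    for t in times_s:
        i = int(round(t * rec.fs))
        lo, hi = max(0, i - half), min(rec.n_samples, i + half)
        data[channel, lo:hi] += amplitude_uv
    return Recording(samples=data, fs=rec.fs, channels=list(rec.channels),
                     reference=rec.reference)


def subject_preset(name: str, seed: int = 0) -> SubjectSpec:
    """Named presets whose expected-spectrum alpha3/alpha2 ratios sit near
    the low- and high-risk group means (~0.90 and ~1.29)."""
    if name == "low-risk":
        return SubjectSpec(
            iaf_true=10.0, tf_true=6.5,
            amp_theta=4.0, amp_alpha_low=4.4, amp_alpha_high=5.5,
            seed=seed,
        )
    if name == "high-risk":
        return SubjectSpec(
            iaf_true=10.0, tf_true=6.5,
            amp_theta=4.0, amp_alpha_low=2.9, amp_alpha_high=5.95,
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}")


def analytic_markers(
    spec: SubjectSpec,
    config: PipelineConfig | None = None,
    fs: float = 250.0,
    estimator_view: bool = True,
):
    """Noiseless-pipeline markers from the expected spectrum (the oracle).

    Evaluates the expected collapsed PSD on the 0.5 Hz grid — as seen
    through the Welch estimator when ``estimator_view`` (the default),
    else the raw process PSD — and runs the anchor/band/ratio stages on
    it; no time-domain simulation involved.  Returns (markers, anchors).
    """
    from .banding import (
        AnchorFrequencies, SubjectMarkers, band_powers, classify_risk,
        compute_ratios, define_bands, detect_iaf, detect_tf,
    )
    from .spectral import CollapsedSpectrum

    cfg = config or PipelineConfig()
    freqs = np.arange(0.0, fs / 2 + 1e-9, 0.5)
    if estimator_view:
        psd = expected_welch_psd(spec, freqs, fs, cfg.epoch_length_s)
    else:
        psd = analytic_collapsed_psd(spec, freqs, fs)
    cs = CollapsedSpectrum(freqs=freqs, power=psd, channel_set=list(CANONICAL_19))
    iaf, f1 = detect_iaf(cs, cfg.iaf_search_hz)
    tf, f2 = detect_tf(cs, iaf, floor=cfg.tf_floor_hz,
                       iaf_offset=cfg.tf_iaf_offset_hz)
    anchors = AnchorFrequencies(tf=tf, iaf=iaf, flags=f1 | f2)
    scheme = define_bands(anchors, cfg)
    powers = band_powers(cs, scheme, cfg.total_range_hz)
    a3a2, thg = compute_ratios(powers)
    markers = SubjectMarkers(
        rel_power=powers, a3_a2_ratio=a3a2, theta_gamma_ratio=thg,
        risk_group=classify_risk(a3a2, "fixed-cutoff"),
    )
    return markers, anchors


# ---------------------------------------------------------------------------
# cohort-level tables


@dataclass
class GroupSpec:
    """Means and SDs for one outcome group's markers and covariates."""

    n: int
    a3_a2: tuple[float, float]
    theta_gamma: tuple[float, float]
    age: tuple[float, float]
    education: tuple[float, float]
    mmse: tuple[float, float]
    hippo_left: tuple[float, float] = (2500.0, 400.0)
    hippo_right: tuple[float, float] = (2500.0, 450.0)
    female_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("a3_a2", "theta_gamma", "age", "education", "mmse",
                     "hippo_left", "hippo_right"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be nonnegative")


_MVN_COLUMNS = ("a3_a2_ratio", "theta_gamma_ratio", "age", "education",
                "mmse", "hippo_left_mm3", "hippo_right_mm3")


def default_correlation() -> np.ndarray:
    """Mild marker-covariate structure: higher a3/a2 with smaller left
    hippocampus, theta/gamma weakly tracking a3/a2; otherwise independent."""
    c = np.eye(len(_MVN_COLUMNS))
    idx = {name: i for i, name in enumerate(_MVN_COLUMNS)}

    def set_r(a, b, r):
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r

    set_r("a3_a2_ratio", "hippo_left_mm3", -0.3)
    set_r("a3_a2_ratio", "theta_gamma_ratio", 0.2)
    set_r("hippo_left_mm3", "hippo_right_mm3", 0.6)
    return c


@dataclass
class CohortSpec:
    """Group-structured cohort recipe (defaults: the follow-up cohort).

    Group sizes 42/18/14 (non-converters / AD converters / non-AD
    converters) with a3/a2 1.14±0.3 / 1.26±0.5 / 1.03±0.7 and the
    matching demographic profiles.  theta/gamma group values are not
    tabulated for the follow-up cohort; defaults encode the reported
    direction (higher in both converter groups) at plausible magnitude.
    """

    groups: dict[str, GroupSpec] = field(default_factory=lambda: {
        "non-converter": GroupSpec(
            n=42, a3_a2=(1.14, 0.3), theta_gamma=(3.6, 1.0),
            age=(69.4, 4.1), education=(7.3, 2.5), mmse=(27.2, 1.4),
            hippo_left=(2600, 360), hippo_right=(2580, 470),
            female_fraction=30 / 42,
        ),
        "AD-converter": GroupSpec(
            n=18, a3_a2=(1.26, 0.5), theta_gamma=(4.4, 1.2),
            age=(71.8, 5.7), education=(8.4, 3.1), mmse=(25.7, 1.5),
            hippo_left=(2070, 410), hippo_right=(2300, 500),
            female_fraction=10 / 18,
        ),
        "nonAD-converter": GroupSpec(
            n=14, a3_a2=(1.03, 0.7), theta_gamma=(4.5, 1.3),
            age=(70.1, 3.9), education=(8.8, 4.6), mmse=(26.8, 1.8),
            hippo_left=(2400, 400), hippo_right=(2450, 480),
            female_fraction=7 / 14,
        ),
    })
    correlation: np.ndarray = field(default_factory=default_correlation)
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.correlation, float)
        if c.shape != (len(_MVN_COLUMNS),) * 2:
            raise ValueError(
                f"correlation must be {len(_MVN_COLUMNS)}x{len(_MVN_COLUMNS)} "
                f"over {_MVN_COLUMNS}"
            )
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-9:
            raise ValueError("correlation matrix is not positive semidefinite")
        self.correlation = c


def _truncate(df: pd.DataFrame) -> pd.DataFrame:
    df["mmse"] = df["mmse"].clip(upper=30.0, lower=0.0)
    df["age"] = df["age"].clip(lower=40.0, upper=100.0)
    df["education"] = df["education"].clip(lower=0.0)
    for col in ("a3_a2_ratio", "theta_gamma_ratio"):
        df[col] = df[col].clip(lower=0.05)
    for col in ("hippo_left_mm3", "hippo_right_mm3"):
        df[col] = df[col].clip(lower=500.0)
    return df


def generate_cohort(
    spec: CohortSpec | None = None,
    mode: str = "draw",
    seed: int | None = None,
    recording_duration: float = 60.0,
    config: PipelineConfig | None = None,
) -> CohortTable:
    """Generate a cohort table with outcome-group structure.

    mode='draw': markers and covariates drawn from the group-wise
    multivariate normal (fast; exercises the statistics layer alone).
    mode='rederive': marker columns are replaced by running the signal
    pipeline on per-subject generated recordings whose upper-alpha
    content scales with the group's a3/a2 mean (slow; end-to-end).
    """
    spec = spec or CohortSpec()
    if mode not in ("draw", "rederive"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    sid = 0
    for outcome, g in spec.groups.items():
        means = np.array([
            g.a3_a2[0], g.theta_gamma[0], g.age[0], g.education[0],
            g.mmse[0], g.hippo_left[0], g.hippo_right[0],
        ])
        sds = np.array([
            g.a3_a2[1], g.theta_gamma[1], g.age[1], g.education[1],
            g.mmse[1], g.hippo_left[1], g.hippo_right[1],
        ])
        cov = spec.correlation * np.outer(sds, sds)
        draws = rng.multivariate_normal(means, cov, size=g.n, method="eigh")
        df = pd.DataFrame(draws, columns=list(_MVN_COLUMNS))
        df.insert(0, "id", [f"S{sid + i:04d}" for i in range(g.n)])
        sid += g.n
        df["sex"] = np.where(rng.random(g.n) < g.female_fraction, "F", "M")
        df["outcome"] = outcome
        frames.append(df)
    table = _truncate(pd.concat(frames, ignore_index=True))
    if mode == "rederive":
        table = _rederive_markers(table, rng, recording_duration, config)
    from .banding import classify_risk

    table["risk_group"] = [classify_risk(r) for r in table["a3_a2_ratio"]]
    return CohortTable(table)


def _rederive_markers(table, rng, duration, config):
    from .banding import subject_pipeline

    cfg = config or PipelineConfig()
    lo, hi = subject_preset("low-risk"), subject_preset("high-risk")
    a3a2, thg, tfv, iafv = [], [], [], []
    for _, row in table.iterrows():
        # interpolate oscillator amplitudes between the presets so the
        # drawn a3/a2 target orders subjects; exact marker values come
        # from the pipeline, not the draw
        t = float(np.clip((row["a3_a2_ratio"] - 0.9) / (1.29 - 0.9), 0.0, 1.5))
        sspec = SubjectSpec(
            iaf_true=float(rng.choice(np.arange(8.0, 12.5, 0.5))),
            tf_true=6.5,
            amp_alpha_low=lo.amp_alpha_low + t * (hi.amp_alpha_low - lo.amp_alpha_low),
            amp_alpha_high=lo.amp_alpha_high
            + t * (hi.amp_alpha_high - lo.amp_alpha_high),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = generate_eeg(sspec, duration=duration)
        res = subject_pipeline(rec, cfg)
        a3a2.append(res.markers.a3_a2_ratio)
        thg.append(res.markers.theta_gamma_ratio)
        tfv.append(res.anchors.tf)
        iafv.append(res.anchors.iaf)
    table = table.copy()
    table["a3_a2_ratio"] = a3a2
    table["theta_gamma_ratio"] = thg
    table["tf_hz"] = tfv
    table["iaf_hz"] = iafv
    return table
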