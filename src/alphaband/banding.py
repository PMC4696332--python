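"""Individualized frequency-band anchoring and the alpha3/alpha2 biomarker.

Two anchor frequencies are read off the collapsed spectrum: the
individual alpha frequency (IAF), the maximum-power peak in the extended
alpha range 5–14 Hz, and the theta/alpha transition frequency (TF), the
power minimum between the theta and alpha bulges.  Band edges are then
subject-specific:

    delta  [TF-4, TF-2)   theta  [TF-2, TF)
    alpha1 [TF, mid)      alpha2 [mid, IAF)     alpha3 [IAF, IAF+2)

with mid the midpoint of the TF-IAF range.  Relative powers are band
sums over the 2-45 Hz total; the alpha3/alpha2 ratio stratifies subjects
into low / middle / high AD-conversion risk groups (cut-offs 1.0 and
1.17), and theta/gamma is the second prognostic ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .io import Recording
from .preprocess import (
    rereference_common_average,
    segment_epochs,
    reject_artifact_epochs,
)
from .spectral import CollapsedSpectrum, PowerSpectrum, collapse_spectrum, welch_psd

GRID_HZ = 0.5

#: Fixed-cutoff risk boundaries on the alpha3/alpha2 ratio.  The printed
#: tertile cut-offs leave a gap between 1.16 and 1.17; it is closed by
#: assigning [1.0, 1.17) to the middle group, consistent with the high
#: group's reported range starting at 1.17.
RISK_CUTOFF_LOW = 1.0
RISK_CUTOFF_HIGH = 1.17

INDIVIDUAL_BANDS = ("delta", "theta", "alpha1", "alpha2", "alpha3")


@dataclass
class AnchorFrequencies:
    """Subject-specific anchors: TF and IAF, with detection quality flags.

    Flags: 'no-alpha-peak' (no local maximum in the search range; global
    max used), 'double-peak' (a second near-equal local maximum),
    'tf-at-boundary' (the power minimum sat at an end of the TF window).
    """

    tf: float
    iaf: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 < self.tf < self.iaf):
            raise ValueError(f"need 0 < tf < iaf, got tf={self.tf}, iaf={self.iaf}")
        self.flags = frozenset(self.flags)


@dataclass
class BandScheme:
    """Ordered band edges in Hz; individual bands are contiguous."""

    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        last = None
        for name, (lo, hi) in self.bands.items():
            if hi <= lo:
                raise ValueError(f"band {name} has non-increasing edges [{lo}, {hi})")
            if last is not None and lo < last - 1e-9:
                raise ValueError("bands overlap or are out of order")
            last = hi
        # the five individual bands must be contiguous
        ind = [self.bands[n] for n in INDIVIDUAL_BANDS if n in self.bands]
        for (lo1, hi1), (lo2, hi2) in zip(ind, ind[1:]):
            if abs(hi1 - lo2) > 1e-9:
                raise ValueError("individual bands must be contiguous")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def __iter__(self):
        return iter(self.bands.items())


@dataclass
class SubjectMarkers:
    """Relative band powers, the two prognostic ratios and the risk label."""

    rel_power: dict[str, float]
    a3_a2_ratio: float
    theta_gamma_ratio: float
    risk_group: str


@dataclass
class SubjectResult:
    """End-to-end output for one subject, intermediates retained for audit."""

    markers: SubjectMarkers
    anchors: AnchorFrequencies
    scheme: BandScheme
    spectrum: PowerSpectrum
    spectrum_source: CollapsedSpectrum
    n_epochs_total: int
    n_epochs_kept: int


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


# ---------------------------------------------------------------------------
# anchor detection


def _grid_index(freqs: np.ndarray, value: float, side: str) -> int:
    if side == "left":
        return int(np.searchsorted(freqs, value - 1e-9, side="left"))
    return int(np.searchsorted(freqs, value + 1e-9, side="right")) - 1


def detect_iaf(
    cs: CollapsedSpectrum,
    search: tuple[float, float] = (5.0, 14.0),
    prominence_frac: float = 0.25,
) -> tuple[float, frozenset[str]]:
    """Individual alpha frequency: maximum-power local peak in ``search``.

    Endpoints are inclusive.  Candidate peaks are local maxima whose
    prominence reaches ``prominence_frac`` of the maximum power in the
    range — estimator noise produces shallow local maxima on any finite
    spectrum, so bare local maxima are not evidence of an alpha peak.
    Ties between candidates break toward the higher frequency.  If no
    candidate exists (e.g. a monotone spectrum), the global maximum in
    range is returned with the 'no-alpha-peak' flag.  A second candidate
    at least 1 Hz away and within 5 % of the winner's power raises the
    'double-peak' flag.
    """
    lo, hi = search
    f = cs.freqs
    if lo < f[0] - 1e-9 or hi > f[-1] + 1e-9:
        raise ValueError(f"search range [{lo}, {hi}] outside spectrum grid")
    i0 = _grid_index(f, lo, "left")
    i1 = _grid_index(f, hi, "right")
    if i1 < i0:
        raise ValueError("empty IAF search range")
    p = cs.power
    pmax = float(p[i0 : i1 + 1].max())
    from scipy.signal import find_peaks

    all_peaks, props = find_peaks(p, prominence=prominence_frac * pmax)
    peaks = [i for i in all_peaks if i0 <= i <= i1]
    flags: set[str] = set()
    if peaks:
        best = max(peaks, key=lambda i: (p[i], f[i]))  # ties -> higher freq
        others = [i for i in peaks if abs(f[i] - f[best]) >= 1.0]
        if any(p[i] >= 0.95 * p[best] for i in others):
            flags.add("double-peak")
        return float(f[best]), frozenset(flags)
    flags.add("no-alpha-peak")
    rel = p[i0 : i1 + 1]
    best = i0 + int(np.flatnonzero(rel == rel.max())[-1])  # ties -> higher freq
    return float(f[best]), frozenset(flags)


def detect_tf(
    cs: CollapsedSpectrum,
    iaf: float,
    search_low: float | None = None,
    floor: float = 4.0,
    iaf_offset: float = 6.0,
) -> tuple[float, frozenset[str]]:
    """Theta/alpha transition frequency: power minimum below the IAF peak.

    The window is [search_low, IAF - 0.5] with
    ``search_low = max(floor, IAF - iaf_offset)`` by default; ties break
    toward the lower frequency.  A minimum at either window end raises
    the 'tf-at-boundary' flag.
    """
    if search_low is None:
        search_low = max(floor, iaf - iaf_offset)
    hi = iaf - GRID_HZ
    if not search_low < iaf - GRID_HZ + 1e-9:
        raise ValueError(
            f"TF search window empty: [{search_low}, {hi}] below iaf={iaf}"
        )
    f = cs.freqs
    i0 = _grid_index(f, search_low, "left")
    i1 = _grid_index(f, hi, "right")
    if i1 < i0:
        raise ValueError("TF search window contains no bins")
    seg = cs.power[i0 : i1 + 1]
    j = int(np.argmin(seg))  # first minimum -> lower frequency on ties
    flags: set[str] = set()
    if j == 0 or j == seg.size - 1:
        flags.add("tf-at-boundary")
    return float(f[i0 + j]), frozenset(flags)


# ---------------------------------------------------------------------------
# band construction and powers


def _on_grid(x: float) -> bool:
    return abs(x * 2 - round(x * 2)) < 1e-9


def define_bands(
    anchors: AnchorFrequencies, config: PipelineConfig | None = None
) -> BandScheme:
    """Build the subject-specific band scheme from the TF/IAF anchors.

    The alpha1/alpha2 boundary is the TF-IAF midpoint.  When both anchors
    sit on the 0.5 Hz measurement grid the midpoint can fall halfway
    between bins; it is then snapped to the grid by rounding half up.
    Anchors given off-grid (e.g. cohort means) keep the exact midpoint.
    Fixed high bands (beta1/beta2/gamma) come from ``config``.
    """
    cfg = config or PipelineConfig()
    tf, iaf = anchors.tf, anchors.iaf
    if tf < 4.0:
        raise ValueError(f"tf={tf} < 4 Hz would push the delta band below 0 Hz")
    if iaf <= tf:
        raise ValueError(f"need iaf > tf, got tf={tf}, iaf={iaf}")
    if _on_grid(tf) and _on_grid(iaf):
        # half-units of the 0.5 Hz grid; round half up
        mid = ((round(tf * 2) + round(iaf * 2) + 1) // 2) / 2.0
    else:
        mid = (tf + iaf) / 2.0
    bands: dict[str, tuple[float, float]] = {
        "delta": (tf - 4.0, tf - 2.0),
        "theta": (tf - 2.0, tf),
        "alpha1": (tf, mid),
        "alpha2": (mid, iaf),
        "alpha3": (iaf, iaf + 2.0),
    }
    b1lo, b1hi = cfg.beta1_offset_hz
    bands["beta1"] = (iaf + b1lo, iaf + b1hi)
    bands["beta2"] = (iaf + b1hi, cfg.beta2_upper_hz)
    bands["gamma"] = tuple(cfg.gamma_hz)  # type: ignore[assignment]
    return BandScheme(bands=bands)


def relative_band_power(
    cs: CollapsedSpectrum,
    band: tuple[float, float],
    total: tuple[float, float] = (2.0, 45.0),
    clip: bool = False,
) -> float:
    """Band power as a fraction of total power over ``total``.

    Bins are assigned half-open [lo, hi) for band and total alike, so
    contiguous bands never double-count a bin and partition additively.
    With ``clip=True`` a band reaching past the normalisation range is
    intersected with it (power outside the range is never counted)
    instead of raising; needed when a low TF pushes the delta band below
    the 2 Hz floor.
    """
    lo, hi = band
    tlo, thi = total
    if clip:
        lo, hi = max(lo, tlo), min(hi, thi)
    if lo < tlo - 1e-9 or hi > thi + 1e-9:
        raise ValueError(f"band [{lo}, {hi}) not within total [{tlo}, {thi}]")
    f = cs.freqs
    band_mask = (f >= lo - 1e-9) & (f < hi - 1e-9)
    total_mask = (f >= tlo - 1e-9) & (f < thi - 1e-9)
    denom = float(cs.power[total_mask].sum())
    if denom <= 0:
        raise ValueError("zero total power over the normalisation range")
    return float(cs.power[band_mask].sum()) / denom


def band_powers(
    cs: CollapsedSpectrum,
    scheme: BandScheme,
    total: tuple[float, float] = (2.0, 45.0),
) -> dict[str, float]:
    """Relative power for every band in the scheme.

    Bands are clipped to the normalisation range (a TF below 6 Hz puts
    part of the delta band under the 2 Hz floor; that power is simply
    not counted).
    """
    return {
        name: relative_band_power(cs, (lo, hi), total, clip=True)
        for name, (lo, hi) in scheme
    }


def compute_ratios(powers: Mapping[str, float]) -> tuple[float, float]:
    """alpha3/alpha2 and theta/gamma ratios from band powers.

    The normalisation denominator cancels, so absolute and relative
    powers give identical ratios.  Zero denominators raise.
    """
    for denom in ("alpha2", "gamma"):
        if powers.get(denom, 0.0) <= 0.0:
            raise ValueError(f"zero or missing {denom} band power in ratio")
    return (
        powers["alpha3"] / powers["alpha2"],
        powers["theta"] / powers["gamma"],
    )


def classify_risk(
    ratio: float,
    rule: str = "fixed-cutoff",
    cohort: Sequence[float] | None = None,
) -> str:
    """Risk group from the alpha3/alpha2 ratio.

    fixed-cutoff: low < 1.0 <= middle < 1.17 <= high.
    cohort-tertile: empirical tertile boundaries of ``cohort``; a ratio
    equal to a boundary goes to the lower group.
    """
    if rule == "fixed-cutoff":
        if ratio < RISK_CUTOFF_LOW:
            return "low"
        if ratio >= RISK_CUTOFF_HIGH:
            return "high"
        return "middle"
    if rule == "cohort-tertile":
        if cohort is None or len(cohort) < 3:
            raise ValueError("cohort-tertile rule needs >= 3 cohort ratios")
        q1, q2 = np.quantile(np.asarray(cohort, float), [1 / 3, 2 / 3])
        if ratio <= q1:
            return "low"
        if ratio <= q2:
            return "middle"
        return "high"
    raise ValueError(f"unknown risk rule {rule!r}")


# ---------------------------------------------------------------------------
# end-to-end


def subject_pipeline(
    rec: Recording,
    config: PipelineConfig | None = None,
    cohort_ratios: Sequence[float] | None = None,
) -> SubjectResult:
    """Full deterministic marker pipeline for one subject.

    Re-reference -> epoch -> reject artifacts -> Welch -> collapse ->
    anchors -> bands -> relative powers -> ratios -> risk group.  Stage
    failures are re-raised as :class:`PipelineError` naming the stage.
    """
    cfg = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage '{name}': {exc}") from exc

    reref = stage("rereference", rereference_common_average, rec)
    epochs = stage("segment", segment_epochs, reref, cfg.epoch_length_s)
    clean = stage(
        "artifact-rejection",
        reject_artifact_epochs,
        epochs,
        cfg.amp_threshold_uv,
        cfg.grad_threshold_uv,
    )
    psd = stage("welch", welch_psd, clean)
    collapsed = stage("collapse", collapse_spectrum, psd)
    iaf, iaf_flags = stage("iaf", detect_iaf, collapsed, cfg.iaf_search_hz)
    tf, tf_flags = stage(
        "tf", detect_tf, collapsed, iaf,
        floor=cfg.tf_floor_hz, iaf_offset=cfg.tf_iaf_offset_hz,
    )
    anchors = AnchorFrequencies(tf=tf, iaf=iaf, flags=iaf_flags | tf_flags)
    scheme = stage("bands", define_bands, anchors, cfg)
    powers = stage("powers", band_powers, collapsed, scheme, cfg.total_range_hz)
    a3a2, thg = stage("ratios", compute_ratios, powers)
    risk = stage("risk", classify_risk, a3a2, cfg.risk_rule, cohort_ratios)
    markers = SubjectMarkers(
        rel_power=powers, a3_a2_ratio=a3a2, theta_gamma_ratio=thg, risk_group=risk
    )
    return SubjectResult(
        markers=markers,
        anchors=anchors,
        scheme=scheme,
        spectrum=psd,
        spectrum_source=collapsed,
        n_epochs_total=epochs.n_epochs,
        n_epochs_kept=clean.n_kept,
    )
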