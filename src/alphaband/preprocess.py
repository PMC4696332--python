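"""Preprocessing: common-average re-referencing, epoching, artifact rejection.

The contract mirrors standard resting-state practice: re-reference first,
then cut consecutive non-overlapping epochs from sample 0, then drop
epochs that exceed amplitude or gradient thresholds.  Rejected epochs are
kept in the container (mask set false) so the bookkeeping is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording


@dataclass
class EpochSet:
    """Consecutive fixed-length epochs cut from one recording.

    ``epochs`` is n x channels x samples-per-epoch (µV); ``kept_mask``
    marks epochs that survived artifact screening.
    """

    epochs: np.ndarray
    epoch_length: float
    fs: float
    kept_mask: np.ndarray
    source_channels: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n x channels x samples")
        n, _, spe = self.epochs.shape
        if n < 1:
            raise ValueError("need at least one epoch")
        expected = self.epoch_length * self.fs
        if abs(spe - expected) > 1e-9:
            raise ValueError(
                f"samples per epoch {spe} != epoch_length*fs = {expected}"
            )
        if self.kept_mask.shape != (n,):
            raise ValueError("kept_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept_epochs(self) -> np.ndarray:
        return self.epochs[self.kept_mask]


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel.

    After the operation the spatial mean is zero at every time point.
    Idempotent; a single-channel recording becomes identically zero.
    """
    mean = rec.samples.mean(axis=0, keepdims=True)
    return Recording(
        samples=rec.samples - mean,
        fs=rec.fs,
        channels=list(rec.channels),
        reference="common-average",
    )


def segment_epochs(rec: Recording, epoch_length: float = 2.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs starting at sample 0.

    A trailing partial epoch is discarded.  Raises if the recording is
    shorter than one epoch.
    """
    spe = int(round(epoch_length * rec.fs))
    if abs(spe - epoch_length * rec.fs) > 1e-9:
        raise ValueError(
            f"epoch_length {epoch_length} s is not an integer number of "
            f"samples at fs={rec.fs}"
        )
    n = rec.n_samples // spe
    if n < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    trimmed = rec.samples[:, : n * spe]
    epochs = trimmed.reshape(rec.n_channels, n, spe).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        epoch_length=float(epoch_length),
        fs=rec.fs,
        kept_mask=np.ones(n, dtype=bool),
        source_channels=list(rec.channels),
    )


def reject_artifact_epochs(
    ep: EpochSet,
    amplitude_threshold: float = 100.0,
    gradient_threshold: float = 50.0,
) -> EpochSet:
    """Flag artifact epochs by peak-to-peak amplitude and gradient.

    An epoch is rejected when, on any channel, the peak-to-peak amplitude
    exceeds ``amplitude_threshold`` (µV) or the maximum absolute
    sample-to-sample difference exceeds ``gradient_threshold``
    (µV/sample).  This is a deterministic automated stand-in for expert
    visual screening; thresholds are configuration, not clinical claims.

    Raises if no epoch survives.
    """
    if amplitude_threshold <= 0 or gradient_threshold <= 0:
        raise ValueError("thresholds must be positive")
    p2p = ep.epochs.max(axis=2) - ep.epochs.min(axis=2)          # n x ch
    grad = np.abs(np.diff(ep.epochs, axis=2)).max(axis=2)        # n x ch
    ok = (p2p.max(axis=1) <= amplitude_threshold) & (
        grad.max(axis=1) <= gradient_threshold
    )
    kept = ep.kept_mask & ok
    if not kept.any():
        raise ValueError(
            "artifact rejection removed every epoch; no data to analyze"
        )
    return EpochSet(
        epochs=ep.epochs,
        epoch_length=ep.epoch_length,
        fs=ep.fs,
        kept_mask=kept,
        source_channels=list(ep.source_channels),
    )
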