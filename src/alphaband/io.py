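"""Readers and writers for recordings, cohort tables and marker reports.

Two recording dialects are supported: EDF (read through MNE) and a plain
delimited numeric matrix (channels x samples, TSV) accompanied by a JSON
sidecar declaring the sampling rate, channel labels and units.  Cohort
tables are delimited text with one row per subject; missing values are
empty cells, never sentinel numbers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import canonicalize_labels

logger = logging.getLogger(__name__)

REFERENCES = ("as-recorded", "linked-mastoid", "common-average")

#: Clinical outcome labels after follow-up.
OUTCOME_LEVELS = ("non-converter", "AD-converter", "nonAD-converter")

#: Canonical cohort-table column order.  Columns beyond this set are kept
#: verbatim after the known block.
COHORT_COLUMNS = (
    "id", "age", "sex", "education", "mmse",
    "babcock", "avlt_immediate", "avlt_delayed",
    "hippo_left_mm3", "hippo_right_mm3",
    "wscore_frontal_l", "wscore_frontal_r",
    "wscore_parietal_l", "wscore_parietal_r",
    "wscore_temporal_l", "wscore_temporal_r",
    "wscore_thalamus_l", "wscore_thalamus_r",
    "wscore_hippamyg_l", "wscore_hippamyg_r",
    "tf_hz", "iaf_hz",
    "rel_delta", "rel_theta", "rel_alpha1", "rel_alpha2", "rel_alpha3",
    "rel_beta1", "rel_beta2", "rel_gamma",
    "a3_a2_ratio", "theta_gamma_ratio", "risk_group",
    "outcome",
)

_NON_NUMERIC = {"id", "sex", "risk_group", "outcome"}


@dataclass
class Recording:
    """A multichannel scalp EEG recording.

    samples are channels x time in microvolts; ``fs`` in Hz; ``channels``
    are 10–20 labels matching the row order.
    """

    samples: np.ndarray
    fs: float
    channels: list[str]
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} labels for {self.samples.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.reference not in REFERENCES:
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds (= samples / fs exactly)."""
        return self.n_samples / self.fs


@dataclass
class CohortTable:
    """Subjects x (markers, covariates, outcome) table.

    Thin validated wrapper over a pandas DataFrame.  Subject ids are
    unique; the outcome column, when present, is restricted to
    :data:`OUTCOME_LEVELS` (missing allowed).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        if "id" not in df.columns:
            raise ValueError("cohort table needs an 'id' column")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if "outcome" in df.columns:
            bad = set(df["outcome"].dropna()) - set(OUTCOME_LEVELS)
            if bad:
                raise ValueError(f"unknown outcome labels: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_outcome(self) -> bool:
        return "outcome" in self.df.columns and self.df["outcome"].notna().any()


# ---------------------------------------------------------------------------
# recordings


def _read_matrix_recording(path: Path, sidecar: Path | None) -> Recording:
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar not found for {path}: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} missing required key 'fs'")
    if "channels" not in meta:
        raise ValueError(f"sidecar {sidecar} missing required key 'channels'")
    units = meta.get("units", "microvolts")
    if units not in ("microvolts", "uV", "µV"):
        raise ValueError(f"unsupported units {units!r}; expected microvolts")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    channels = canonicalize_labels(meta["channels"])
    if data.shape[0] != len(channels):
        raise ValueError(
            f"{len(channels)} channel labels but {data.shape[0]} matrix rows"
        )
    return Recording(
        samples=data,
        fs=float(meta["fs"]),
        channels=channels,
        reference=meta.get("reference", "as-recorded"),
    )


def _read_edf_recording(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # MNE returns volts; the package works in microvolts throughout.
    data = raw.get_data() * 1e6
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channels=canonicalize_labels(raw.ch_names),
        reference="as-recorded",
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    sidecar: str | Path | None = None,
) -> Recording:
    """Read a recording from EDF or a TSV matrix with JSON sidecar.

    ``format`` is 'edf' or 'matrix'; when omitted it is inferred from the
    file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf_recording(path)
    if format == "matrix":
        return _read_matrix_recording(path, Path(sidecar) if sidecar else None)
    raise ValueError(f"unknown recording format {format!r}")


def write_matrix_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording as TSV matrix + JSON sidecar (inverse of reading)."""
    path = Path(path)
    np.savetxt(path, rec.samples, delimiter="\t")
    meta = {
        "fs": rec.fs,
        "channels": list(rec.channels),
        "units": "microvolts",
        "reference": rec.reference,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort(path: str | Path, sep: str = "\t") -> CohortTable:
    """Read a delimited cohort table (header row required).

    Numeric columns are coerced; unparseable cells become missing with a
    warning.  Duplicate ids and unknown outcome labels raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if len(df) == 0:
        raise ValueError(f"cohort file {path} has a header but no data rows")
    for col in df.columns:
        if col in _NON_NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            warnings.warn(
                f"column {col!r}: {int(bad.sum())} unparseable numeric "
                f"cell(s) set to missing",
                stacklevel=2,
            )
        df[col] = coerced
    return CohortTable(df)


def write_markers(cohort: CohortTable, path: str | Path, sep: str = "\t") -> None:
    """Write a cohort/marker table as delimited text.

    Column order is stable: known columns first in canonical order, then
    any extras in their existing order.  Missing cells are written empty.
    Round-trips through :func:`read_cohort`.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort table")
    df = cohort.df
    known = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    df[known + extra].to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# per-subject reports


def write_subject_report(result, out_dir: str | Path, subject_id: str = "subject") -> Path:
    """Write a per-subject report (JSON + TSV) from a pipeline result.

    ``result`` is a :class:`alphaband.banding.SubjectResult`.  Returns the
    JSON path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "id": subject_id,
        "anchors": {
            "tf_hz": result.anchors.tf,
            "iaf_hz": result.anchors.iaf,
            "flags": sorted(result.anchors.flags),
        },
        "bands": {name: [lo, hi] for name, (lo, hi) in result.scheme.bands.items()},
        "relative_power": result.markers.rel_power,
        "a3_a2_ratio": result.markers.a3_a2_ratio,
        "theta_gamma_ratio": result.markers.theta_gamma_ratio,
        "risk_group": result.markers.risk_group,
        "n_epochs_used": result.spectrum.n_epochs_used,
        "n_epochs_total": result.n_epochs_total,
    }
    json_path = out_dir / f"{subject_id}.json"
    json_path.write_text(json.dumps(payload, indent=1))
    rows = {f"rel_{k}": v for k, v in result.markers.rel_power.items()}
    rows.update(
        id=subject_id,
        tf_hz=result.anchors.tf,
        iaf_hz=result.anchors.iaf,
        a3_a2_ratio=result.markers.a3_a2_ratio,
        theta_gamma_ratio=result.markers.theta_gamma_ratio,
        risk_group=result.markers.risk_group,
    )
    pd.DataFrame([rows]).to_csv(out_dir / f"{subject_id}.tsv", sep="\t", index=False)
    return json_path
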