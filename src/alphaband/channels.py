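"""10–20 montage channel names and scalp macroarea groupings.

The canonical 19-electrode montage (Fp1 … O2) is the reference set for
label matching; matching is case-insensitive so that "FP1", "fp1" and
"Fp1" all resolve to the canonical spelling.
"""

from __future__ import annotations

from typing import Iterable, Sequence

#: The 19 scalp electrodes of the standard 10–20 montage, in conventional order.
CANONICAL_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

_CANON_BY_LOWER = {name.lower(): name for name in CANONICAL_19}

#: Scalp macroareas by 10–20 lobe nomenclature.  Central electrodes
#: (C3, Cz, C4) belong to neither area.  Configurable at call sites.
MACROAREAS: dict[str, tuple[str, ...]] = {
    "frontotemporal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
                       "T3", "T4", "T5", "T6"),
    "parietoccipital": ("P3", "Pz", "P4", "O1", "O2"),
}


def canonicalize_label(label: str) -> str:
    """Map a channel label to its canonical 10–20 spelling when recognised.

    Unrecognised labels are returned stripped but otherwise unchanged, so
    non-standard montages still round-trip.
    """
    return _CANON_BY_LOWER.get(label.strip().lower(), label.strip())


def canonicalize_labels(labels: Iterable[str]) -> list[str]:
    return [canonicalize_label(lab) for lab in labels]


def resolve_subset(subset: Sequence[str], available: Sequence[str]) -> list[str]:
    """Resolve ``subset`` against ``available`` labels, case-insensitively.

    Raises ``KeyError`` for a label absent from ``available``.
    """
    by_lower = {lab.lower(): lab for lab in available}
    out = []
    for lab in subset:
        key = lab.strip().lower()
        if key not in by_lower:
            raise KeyError(f"channel label {lab!r} not present in recording")
        out.append(by_lower[key])
    return out
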