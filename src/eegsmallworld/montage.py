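"""The 19-channel scalp montage used throughout the analysis.

Nineteen electrodes of the international 10-20 system form the analysis
montage; the two remaining applied electrodes (reference/ground) are dropped
at ingestion.  Channel order is fixed so adjacency matrices from different
epochs and subjects are comparable entry-for-entry.
"""

from __future__ import annotations

import numpy as np

#: Fixed analysis channel order (classic 10-20 names, temporal chain T3/T4/T5/T6).
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

N_CHANNELS = len(CHANNELS_1020)

#: Modern alias -> classic label (modified combinatorial nomenclature).
LABEL_ALIASES: dict[str, str] = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

# Approximate 2-D scalp positions (nose up, unit head radius).  Only relative
# distances matter: they define spatial neighbourhoods for the simulator's
# "clustered" oscillator placement.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.42, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.42, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.42, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def normalize_label(label: str) -> str:
    """Map a raw EDF channel label onto the canonical montage name.

    Handles 'EEG ' prefixes, reference suffixes such as '-REF' or '-A1',
    case differences and T7/T8/P7/P8 aliases.  Returns the canonical name,
    or the cleaned label unchanged if it is not an analysis channel.
    """
    clean = label.strip()
    if clean.upper().startswith("EEG "):
        clean = clean[4:]
    clean = clean.split("-")[0].strip()
    for canon in CHANNELS_1020:
        if clean.lower() == canon.lower():
            return canon
    alias = LABEL_ALIASES.get(clean.upper().capitalize()) or LABEL_ALIASES.get(clean.upper())
    if alias is not None:
        return alias
    return clean


def channel_index(label: str) -> int:
    return CHANNELS_1020.index(normalize_label(label))


def neighbourhood(center: str, size: int) -> tuple[str, ...]:
    """The ``size`` montage channels closest to ``center`` (inclusive)."""
    cx, cy = _POSITIONS[normalize_label(center)]
    dist = {
        ch: np.hypot(x - cx, y - cy) for ch, (x, y) in _POSITIONS.items()
    }
    ordered = sorted(CHANNELS_1020, key=lambda ch: dist[ch])
    return tuple(ordered[:size])
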