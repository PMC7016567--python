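"""Scalp montages and 10-20 channel-label geography.

Channels are grouped into named scalp areas by their 10-20 label prefix.
Central-area channels (FC*, C*, CP*) overlie motor cortex and are excluded
from vigilance analyses to avoid movement-count confounds; prefrontal (Fp*)
channels are reserved for ocular artifact handling.
"""

from __future__ import annotations

# 61-channel high-resolution laboratory montage.
PVT_MONTAGE_61 = [
    "Fpz", "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

# 16-channel field montage; Fpz is the dedicated ocular-correction channel.
ATM_MONTAGE_16 = [
    "Fpz", "AF3", "AF4", "AF7", "AF8", "Fz", "F3", "F4", "F7", "F8",
    "CP3", "CP4", "Pz", "P3", "P4", "Oz",
]

# Longest prefix first so e.g. "Fp1" matches "Fp" before "F".
_PREFIX_AREAS = [
    ("Fp", "prefrontal"),
    ("AF", "frontal"),
    ("FT", "temporal"),
    ("FC", "central"),
    ("TP", "temporal"),
    ("CP", "central"),
    ("PO", "parietal"),
    ("F", "frontal"),
    ("T", "temporal"),
    ("C", "central"),
    ("P", "parietal"),
    ("O", "occipital"),
]

POSTERIOR_AREAS = frozenset({"parietal", "occipital"})


def channel_prefix(label: str) -> str:
    """Return the 10-20 site prefix of ``label`` (``"Fpz"`` -> ``"Fp"``)."""
    core = label.rstrip("0123456789").rstrip("zh")
    return core if core else label


def channel_area(label: str) -> str:
    """Map a 10-20 channel label onto a named scalp area.

    Raises ``ValueError`` for labels outside the recognised 10-20 scheme.
    """
    prefix = channel_prefix(label)
    for pfx, area in _PREFIX_AREAS:
        if prefix == pfx:
            return area
    raise ValueError(f"unknown 10-20 channel label: {label!r}")


def area_map(labels) -> dict[str, str]:
    return {lab: channel_area(lab) for lab in labels}


def is_central(label: str) -> bool:
    return channel_area(label) == "central"


def is_prefrontal(label: str) -> bool:
    return channel_area(label) == "prefrontal"


def analysis_channels(labels) -> list[str]:
    """Channels admissible for vigilance analysis: montage minus central and
    prefrontal sites."""
    return [c for c in labels if not (is_central(c) or is_prefrontal(c))]


def posterior_channels(labels) -> list[str]:
    return [c for c in labels if channel_area(c) in POSTERIOR_AREAS]
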