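"""Default EEG channel naming.

The 64-electrode Biosemi cap labelled with extended 10-20 positions, in the
vendor's A1..A32, B1..B32 connector order. Names are cosmetic metadata; all
indexing in the package is positional (0-based).
"""

from __future__ import annotations

BIOSEMI64: tuple[str, ...] = (
    # A1..A32
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    # B1..B32
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)


def default_channel_names(n_channels: int) -> tuple[str, ...]:
    """Channel labels for an ``n_channels``-electrode montage.

    Returns the Biosemi 64 layout when ``n_channels == 64``, otherwise
    generic ``Ch1..ChN`` labels.
    """
    if n_channels == 64:
        return BIOSEMI64
    return tuple(f"Ch{i + 1}" for i in range(n_channels))
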