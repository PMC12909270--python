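"""Channel conventions for the 64-electrode 10-20 montage.

The label order below follows the BioSemi 64-channel cap (A1–A32 then
B1–B32 in their conventional 10-20 names).  Channel order is fixed to this
list everywhere in the package; no montage-dependent reordering is applied.
"""

from __future__ import annotations

import numpy as np

BIOSEMI_64: tuple[str, ...] = (
    # A1-A32 (left hemisphere + midline, front to back)
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    # B1-B32 (right hemisphere + remaining midline)
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

assert len(BIOSEMI_64) == 64

#: Channels carrying the simulated visual-evaluation signal by default:
#: occipital and parieto-occipital sites, where early visual and later
#: evaluative ERP components are largest at the scalp.
DEFAULT_SIGNAL_CHANNELS: tuple[str, ...] = (
    "O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8",
)


def spatial_pattern(
    labels: tuple[str, ...] | list[str] = BIOSEMI_64,
    signal_channels: tuple[str, ...] | list[str] = DEFAULT_SIGNAL_CHANNELS,
) -> np.ndarray:
    """Unit-norm per-channel weight vector concentrated on ``signal_channels``.

    Equal weights on the signal channels, zero elsewhere, normalised to unit
    Euclidean norm so that ``amplitude`` in the generator is expressed in μV
    of total pattern magnitude.
    """
    w = np.zeros(len(labels))
    idx = [list(labels).index(ch) for ch in signal_channels]
    if not idx:
        raise ValueError("signal_channels must name at least one channel")
    w[idx] = 1.0
    return w / np.linalg.norm(w)
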