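"""Electrode montages (10-10 system naming).

The reference montage has 64 channels and includes the six posterior
electrodes over visual cortex (O1, O2, Oz, PO3, PO4, POz) that the
channel-perturbation experiment targets.  A smaller 18-channel montage is
provided for desk-scale runs; it keeps the same six posterior channels.
"""

from __future__ import annotations

#: Occipital / parieto-occipital channels over visual cortex.
POSTERIOR_CHANNELS: tuple[str, ...] = ("O1", "O2", "Oz", "PO3", "PO4", "POz")

#: 64-channel 10-10 montage (reference configuration).
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: 18-channel subset for fast desk-scale experiments (posterior set intact).
MONTAGE_18: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4",
    "P3", "Pz", "P4", "PO3", "POz", "PO4", "O1", "Oz", "O2",
)

assert len(MONTAGE_64) == 64
assert set(POSTERIOR_CHANNELS) <= set(MONTAGE_64)
assert set(POSTERIOR_CHANNELS) <= set(MONTAGE_18)


def posterior_indices(channel_names) -> list[int]:
    """Indices of the six visual-cortex channels within ``channel_names``."""
    return [i for i, name in enumerate(channel_names)
            if name in POSTERIOR_CHANNELS]
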