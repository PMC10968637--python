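"""The 35-channel 10-20 montage and scalp-region grouping.

The default montage mirrors a press-task ErrP recording setup: standard
10-20 scalp positions plus the three cerebellar electrodes CB1, CBZ, CB2
placed below the occipital row.  Region grouping is prefix-based and
configurable; cerebellar channels form their own CB region.
"""

from __future__ import annotations

#: 35-channel montage including the cerebellar electrodes.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "FCz", "FC3", "FC4", "FT7", "FT8",
    "Cz", "C3", "C4", "T7", "T8",
    "CP3", "CP4", "TP7", "TP8",
    "Pz", "P3", "P4", "P7", "P8",
    "POz", "PO3", "PO4",
    "O1", "Oz", "O2",
    "CB1", "CBZ", "CB2",
)

#: Cerebellar electrodes (matching is case-insensitive: "CBz" == "CBZ").
CEREBELLAR = ("CB1", "CBZ", "CB2")

REGION_NAMES = ("F", "C", "P", "O", "CB")


def region_of(channel: str) -> str | None:
    """Scalp region of a 10-20 channel name.

    Frontal (Fp/AF/F/FC/FT) -> "F"; central and temporal (C/CP/T/TP) -> "C";
    parietal (P/PO) -> "P"; occipital -> "O"; cerebellar -> "CB".
    Returns None for labels outside the scheme.
    """
    u = channel.upper()
    if u.startswith("CB"):
        return "CB"
    if u.startswith(("FP", "AF", "F")):
        return "F"
    if u.startswith(("C", "T")):
        return "C"
    if u.startswith(("P",)):
        return "P"
    if u.startswith("O"):
        return "O"
    return None


def region_map(channel_names) -> dict[str, list[str]]:
    """Group channel names into regions, preserving montage order."""
    groups: dict[str, list[str]] = {}
    for name in channel_names:
        region = region_of(name)
        if region is not None:
            groups.setdefault(region, []).append(name)
    return groups
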