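"""Channel montage, task list and regional channel groupings.

The cohort uses a 32-channel cap in the extended 10-20 layout: 30 scalp
electrodes plus horizontal/vertical EOG. Two consecutive subject ids form a
twin pair throughout the package.
"""

from __future__ import annotations

# 30 scalp channels, front-to-back ordering of a 32-channel Quick-Cap style
# montage (T3/T4/T5/T6 written in modern T7/T8/P7/P8 nomenclature).
SCALP_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2",
    "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CPZ", "CP4", "TP8",
    "P7", "P3", "PZ", "P4", "P8",
    "O1", "OZ", "O2",
)

EOG_CHANNELS: tuple[str, ...] = ("HEO", "VEO")

ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + EOG_CHANNELS

#: Regional partition used by the regional identification experiments.
#: Disjoint; P7/P8 are left unassigned, as in conventional 5-region splits
#: of this cap. Fully overridable wherever a region map is accepted.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("FP1", "FP2", "F3", "F4", "F7", "F8", "FZ"),
    "central": ("FC3", "FCZ", "FC4", "C3", "CZ", "C4"),
    "parietal": ("CP3", "CPZ", "CP4", "P3", "PZ", "P4"),
    "temporal": ("FT7", "FT8", "T7", "T8", "TP7", "TP8"),
    "occipital": ("O1", "OZ", "O2"),
}

#: Ten instructed 65-s task conditions plus the free task.
#: rce/roe: resting, eyes closed/open; m* executed movement, i* motor
#: imagery; l/r/b: left fist, right fist, both fists; be/ibe: both feet.
TASKS: tuple[str, ...] = (
    "rce", "roe",
    "mli", "mri", "ili", "iri",
    "mbi", "mbe", "ibi", "ibe",
    "fre",
)

MOTOR_TASKS: tuple[str, ...] = ("mli", "mri", "mbi", "mbe")
IMAGERY_TASKS: tuple[str, ...] = ("ili", "iri", "ibi", "ibe")

#: Relative blink coupling of each scalp channel (1.0 at the forehead,
#: decaying toward the back of the head); multiplied by the generator's
#: frontal gain.
BLINK_TOPOGRAPHY: dict[str, float] = {
    "FP1": 1.0, "FP2": 1.0,
    "F7": 0.5, "F3": 0.5, "FZ": 0.5, "F4": 0.5, "F8": 0.5,
    "FT7": 0.25, "FC3": 0.25, "FCZ": 0.25, "FC4": 0.25, "FT8": 0.25,
    "T7": 0.1, "C3": 0.1, "CZ": 0.1, "C4": 0.1, "T8": 0.1,
}


def region_of(channel: str, regions: dict[str, tuple[str, ...]] | None = None) -> str | None:
    """Return the region a scalp channel belongs to, or None if unassigned."""
    regions = DEFAULT_REGIONS if regions is None else regions
    for name, chans in regions.items():
        if channel in chans:
            return name
    return None
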