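"""Shared constants: microenvironment coding, slot geometry, day types."""

MICROENVS = ("residential_indoor", "transportation", "other")
ME_INDEX = {m: i for i, m in enumerate(MICROENVS)}

N_SLOTS = 144          # 10-min slots per 24-h day
N_MICROENVS = 3
N_CELLS = N_SLOTS * N_MICROENVS
SLOT_MINUTES = 10
DAY_MINUTES = 1440

DAY_TYPES = ("weekday", "saturday", "sunday")

#: Korean 24-h PM2.5 ambient air quality standard, ug/m3.
DEFAULT_EXCEEDANCE_STANDARD = 35.0

#: Mapping from the finer seven-category location scheme used by later
#: time-use surveys onto the three-microenvironment scheme of this model.
SEVEN_CATEGORY_MAP = {
    "own_home": "residential_indoor",
    "walk": "transportation",
    "private_transport": "transportation",
    "public_transport": "transportation",
    "workplace_school": "other",
    "restaurant": "other",
    "other": "other",
}


def slot_of_minute(minute: int) -> int:
    """1-based slot index for a minute-of-day; slot t covers [10(t-1), 10t)."""
    if not 0 <= minute <= 1439:
        raise ValueError(f"minute_of_day {minute} outside [0, 1439]")
    return minute // SLOT_MINUTES + 1


def cell_index(slot: int, me_idx: int) -> int:
    """Canonical flat index of a (slot, microenvironment) cell, 0..431."""
    return (slot - 1) * N_MICROENVS + me_idx
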