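"""Frequency-band definitions used for band-power features.

Band edges are half-open intervals [low, high) so that a set of adjacent
bands partitions the axis without double counting.  The default 11-band
layout spans 1-100 Hz and deliberately leaves the 49-51 Hz notch region
(mains frequency, filtered at the device) unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A named half-open frequency interval [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError(f"need 0 <= low < high, got [{self.low}, {self.high})")

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high


def validate_band_set(bands: list[Band]) -> None:
    """Check that bands do not overlap under the half-open convention."""
    for a in bands:
        for b in bands:
            if a is not b and a.low < b.high and b.low < a.high:
                raise ValueError(f"bands overlap: {a.name} and {b.name}")


#: Fine 11-band layout (1-100 Hz with a 49-51 Hz gap at the mains notch).
BANDS_11 = [
    Band("band_1_4", 1, 4),
    Band("band_4_8", 4, 8),
    Band("band_8_10", 8, 10),
    Band("band_10_12", 10, 12),
    Band("band_12_14", 12, 14),
    Band("band_14_26", 14, 26),
    Band("band_26_40", 26, 40),
    Band("band_40_49", 40, 49),
    Band("band_51_65", 51, 65),
    Band("band_65_80", 65, 80),
    Band("band_80_100", 80, 100),
]

#: Classical drowsiness bands: theta and alpha power track sleepiness ratings.
BANDS_THETA_ALPHA = [
    Band("theta", 4, 8),
    Band("alpha", 8, 12),
]

#: The 4-band practical set (delta, theta and two alpha sub-bands) that
#: stepwise selection typically retains when the low bands carry the signal.
BANDS_PRACTICAL_4 = [
    Band("band_1_4", 1, 4),
    Band("band_4_8", 4, 8),
    Band("band_10_12", 10, 12),
    Band("band_12_14", 12, 14),
]

BAND_SETS = {
    "eleven": BANDS_11,
    "theta-alpha": BANDS_THETA_ALPHA,
    "practical": BANDS_PRACTICAL_4,
}

for _bands in BAND_SETS.values():
    validate_band_set(_bands)
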