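"""Audiometric summaries: pure-tone average, severity bins, audiogram shape.

Pure-tone audiometry at 0.5, 1, 2 and 4 kHz; the pure-tone average (PTA)
is the arithmetic mean of the four thresholds.  Severity bins follow the
clinical convention: moderate 41-70 dB HL, severe 71-95 dB HL, profound
above 95 dB HL (inclusive bounds as written); a PTA below 41 dB is
flagged below-range rather than forced into a bin.

The four audiogram configurations (low-frequency, U-shaped,
high-frequency, flat) are named clinically without numeric rules; here a
15 dB slope/flatness criterion is used, exposed as parameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

FREQUENCIES_KHZ = (0.5, 1.0, 2.0, 4.0)


class Ear(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BINAURAL = "binaural-average"


class Severity(enum.Enum):
    MODERATE = "moderate"
    SEVERE = "severe"
    PROFOUND = "profound"
    BELOW_RANGE = "below-range"


class Shape(enum.Enum):
    LOW_FREQUENCY = "low_frequency"
    U_SHAPED = "u_shaped"
    HIGH_FREQUENCY = "high_frequency"
    FLAT = "flat"


class AudiogramError(ValueError):
    pass


@dataclass(frozen=True)
class Audiogram:
    thresholds_db: Mapping[float, float]
    ear: Ear = Ear.BINAURAL

    def __post_init__(self) -> None:
        for f, v in self.thresholds_db.items():
            if not -10.0 <= v <= 130.0:
                raise AudiogramError(f"threshold {v} dB at {f} kHz outside [-10, 130]")

    def threshold(self, freq_khz: float) -> float:
        try:
            return self.thresholds_db[freq_khz]
        except KeyError:
            raise AudiogramError(f"missing threshold at {freq_khz} kHz") from None


def pta(audiogram: Audiogram) -> float:
    """Pure-tone average over 0.5/1/2/4 kHz (dB HL)."""
    return sum(audiogram.threshold(f) for f in FREQUENCIES_KHZ) / len(FREQUENCIES_KHZ)


def severity(pta_db: float) -> Severity:
    if pta_db > 95.0:
        return Severity.PROFOUND
    if pta_db >= 71.0:
        return Severity.SEVERE
    if pta_db >= 41.0:
        return Severity.MODERATE
    return Severity.BELOW_RANGE


def audiogram_shape(
    audiogram: Audiogram,
    slope_db: float = 15.0,
    flat_range_db: float = 15.0,
) -> Shape:
    """Classify the audiometric configuration.

    Precedence: high-frequency (mean(2,4) - mean(0.5,1) >= slope), then
    low-frequency (the reverse), then U-shaped (mid frequencies worse
    than both edges by >= slope), then flat (max-min <= flat_range);
    anything else defaults to flat as the residual class.
    """
    t = {f: audiogram.threshold(f) for f in FREQUENCIES_KHZ}
    low = (t[0.5] + t[1.0]) / 2.0
    high = (t[2.0] + t[4.0]) / 2.0
    mid = (t[1.0] + t[2.0]) / 2.0
    edge = (t[0.5] + t[4.0]) / 2.0
    if high - low >= slope_db:
        return Shape.HIGH_FREQUENCY
    if low - high >= slope_db:
        return Shape.LOW_FREQUENCY
    if mid - edge >= slope_db:
        return Shape.U_SHAPED
    return Shape.FLAT
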