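"""Canonical LFP frequency-band definitions.

The six bands used throughout the analyses: theta (4-8 Hz), alpha (8-12 Hz),
low beta (12-20 Hz), high beta (20-30 Hz), low gamma (30-50 Hz), and
high gamma (50-80 Hz). Bands are half-open on neither side here; a frequency
grid bin belongs to a band when ``low <= f <= high``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named LFP frequency band in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.low_hz < self.high_hz <= 90.0):
            raise ValueError(
                f"band {self.name!r}: require 1 <= low < high <= 90, "
                f"got [{self.low_hz}, {self.high_hz}]"
            )

    def contains(self, freq_hz) -> bool:
        return (self.low_hz <= freq_hz) & (freq_hz <= self.high_hz)


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
LOW_BETA = BandDefinition("low_beta", 12.0, 20.0)
HIGH_BETA = BandDefinition("high_beta", 20.0, 30.0)
LOW_GAMMA = BandDefinition("low_gamma", 30.0, 50.0)
HIGH_GAMMA = BandDefinition("high_gamma", 50.0, 80.0)

BANDS: dict[str, BandDefinition] = {
    b.name: b for b in (THETA, ALPHA, LOW_BETA, HIGH_BETA, LOW_GAMMA, HIGH_GAMMA)
}

#: Broader summary bands used for depth profiles (beta 12-30, gamma 30-80).
BETA_WIDE = BandDefinition("beta", 12.0, 30.0)
GAMMA_WIDE = BandDefinition("gamma", 30.0, 80.0)


def get_band(band: "BandDefinition | str | tuple[float, float]") -> BandDefinition:
    """Coerce a band name, (low, high) pair, or BandDefinition to a BandDefinition."""
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    low, high = band
    return BandDefinition(f"{low:g}-{high:g}Hz", float(low), float(high))
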