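"""Canonical frequency-band definitions for oscillatory microstate analysis.

The analysis decomposes resting-state sensor data into the five classical
rhythms (delta through gamma) plus a broadband "overall" band, each defined
by a high-pass and a low-pass edge in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its filter edges.

    Parameters
    ----------
    name : str
        Band label (``delta`` ... ``gamma``, or ``overall``).
    high_pass : float
        Lower edge of the band in Hz (applied as a high-pass filter).
    low_pass : float
        Upper edge of the band in Hz (applied as a low-pass filter).
    """

    name: str
    high_pass: float
    low_pass: float

    def __post_init__(self) -> None:
        if not 0 < self.high_pass < self.low_pass:
            raise ValueError(
                f"band edges must satisfy 0 < high_pass < low_pass, "
                f"got ({self.high_pass}, {self.low_pass})"
            )


#: The fixed band table used throughout the pipeline.
BAND_TABLE: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 3.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 14.0, 30.0),
    "gamma": BandSpec("gamma", 31.0, 40.0),
    "overall": BandSpec("overall", 1.0, 40.0),
}

#: Band names in canonical reporting order.
BAND_ORDER: tuple[str, ...] = ("overall", "delta", "theta", "alpha", "beta", "gamma")


def get_band(name: str) -> BandSpec:
    """Look up a band by name, raising ``KeyError`` with the known names."""
    try:
        return BAND_TABLE[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known bands: {sorted(BAND_TABLE)}"
        ) from None
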