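"""Visual stimulus bookkeeping and contrast definitions.

Light stimuli in these experiments are spots, static bars, or drifting
bars presented on a steady photopic background.  Two contrast
conventions are used in the field and both are provided here:

* **Weber contrast** for increments/decrements on a background,
  ``C = 100 (L_stim - L_back) / L_back`` (percent, signed: negative for
  dark stimuli, positive for bright ones).
* **Michelson contrast** for modulated stimuli,
  ``C = 100 (L_max - L_min) / (L_max + L_min)`` (percent, in [0, 100]).

Intensities may be expressed either as luminous power density (uW/m^2)
or photon flux (photons/um^2/s).  Contrast is a unit-free ratio, but
mixing differently tagged intensities in one computation is an error —
no conversion between the two systems is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "Intensity",
    "StimulusSpec",
    "weber_contrast",
    "michelson_contrast",
    "normalize_direction",
]

#: recognised intensity unit tags
INTENSITY_UNITS = ("uW/m^2", "photons/um^2/s")


@dataclass(frozen=True)
class Intensity:
    """A light intensity with an explicit unit tag."""

    value: float
    unit: str = "uW/m^2"

    def __post_init__(self):
        if self.unit not in INTENSITY_UNITS:
            raise ValueError(f"unknown intensity unit {self.unit!r}; "
                             f"expected one of {INTENSITY_UNITS}")
        if self.value < 0:
            raise ValueError("intensity must be >= 0")


def _value_unit(x, default_unit=None):
    if isinstance(x, Intensity):
        return x.value, x.unit
    return float(x), default_unit


def _check_units(a, b):
    va, ua = _value_unit(a)
    vb, ub = _value_unit(b)
    if ua is not None and ub is not None and ua != ub:
        raise ValueError(f"mixed intensity units: {ua!r} vs {ub!r}")
    return va, vb


def normalize_direction(deg: float) -> float:
    """Map an angle in degrees onto [0, 360).

    Package-wide convention: degrees, counterclockwise, 0 deg along the
    positive x-axis of the recording frame.
    """
    d = math.fmod(float(deg), 360.0)
    return d + 360.0 if d < 0 else d


def weber_contrast(stimulus_intensity, background_intensity) -> float:
    """Percent Weber contrast, 100 (L_stim - L_back) / L_back.

    Negative for dark (decrement) stimuli, positive for bright
    (increment) stimuli.  ``background_intensity`` must be > 0.
    """
    ls, lb = _check_units(stimulus_intensity, background_intensity)
    if lb <= 0:
        raise ValueError("background intensity must be > 0 for Weber contrast")
    if ls < 0:
        raise ValueError("stimulus intensity must be >= 0")
    return 100.0 * (ls - lb) / lb


def michelson_contrast(l_max, l_min) -> float:
    """Percent Michelson contrast, 100 (L_max - L_min) / (L_max + L_min)."""
    vmax, vmin = _check_units(l_max, l_min)
    if vmin < 0:
        raise ValueError("intensities must be >= 0")
    if vmax < vmin:
        raise ValueError("l_max must be >= l_min")
    if vmax + vmin <= 0:
        raise ValueError("at least one intensity must be > 0")
    return 100.0 * (vmax - vmin) / (vmax + vmin)


@dataclass
class StimulusSpec:
    """Metadata describing one light stimulus.

    Geometry fields are in micrometres on the retina; times in seconds.
    ``direction`` follows the package convention (degrees CCW, 0 deg =
    +x of the recording frame) and is normalised to [0, 360).
    """

    kind: str = "spot"                     # spot | bar | drifting_bar
    background_intensity: float = 150.0    # uW/m^2 by convention
    stimulus_intensity: float = 270.0
    intensity_unit: str = "uW/m^2"
    diameter: Optional[float] = None       # um, spots
    bar_length: Optional[float] = None     # um
    bar_width: Optional[float] = None      # um
    speed: Optional[float] = None          # um/s, drifting bars
    direction: Optional[float] = None      # degrees in [0, 360)
    onset: Optional[float] = None          # s
    offset: Optional[float] = None         # s

    KINDS = ("spot", "bar", "drifting_bar")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if self.background_intensity < 0 or self.stimulus_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.intensity_unit not in INTENSITY_UNITS:
            raise ValueError(f"unknown intensity unit {self.intensity_unit!r}")
        if self.direction is not None:
            self.direction = normalize_direction(self.direction)
        if self.onset is not None and self.offset is not None:
            if not self.offset > self.onset:
                raise ValueError("offset must be > onset")

    # -- derived quantities -------------------------------------------------

    def weber_contrast(self) -> float:
        return weber_contrast(self.stimulus_intensity, self.background_intensity)

    # -- flat key/value serialisation ---------------------------------------
    # A stimulus block is embedded in the headers of trace and raster files
    # as ``stimulus.<field> = <value>`` lines.

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        fields = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        for k in ("background_intensity", "stimulus_intensity", "diameter",
                  "bar_length", "bar_width", "speed", "direction",
                  "onset", "offset"):
            if k in fields and fields[k] is not None:
                fields[k] = float(fields[k])
        return cls(**fields)
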