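"""Core series containers shared by the phenometrics and season modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

#: Recognized measurement variables.
VARIABLES = ("leaf_length_cm", "greenness", "root_area", "vigour")


@dataclass
class MeasurementSeries:
    """One measured variable for one experimental unit over day-of-year.

    ``doy`` must be strictly increasing; values are stored as float64.
    ``scaled`` marks series already mapped to percent-of-maximum (0-100).
    """

    unit_id: str
    group: str
    variable: str
    doy: np.ndarray
    value: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.doy.ndim != 1 or self.doy.shape != self.value.shape:
            raise InvalidInputError("doy and value must be 1-D and equal length")
        if self.doy.size >= 2 and not np.all(np.diff(self.doy) > 0):
            raise InvalidInputError("doy must be strictly increasing")

    def __len__(self) -> int:
        return self.doy.size

    def with_values(self, value: np.ndarray, scaled: bool | None = None) -> "MeasurementSeries":
        return replace(
            self, value=np.asarray(value, dtype=float),
            scaled=self.scaled if scaled is None else scaled,
        )


@dataclass
class SeasonWindow:
    """Per-unit growing-season bounds in day-of-year units."""

    unit_id: str
    start_doy: float
    end_doy: float
    source: str = "configured"  # {"detected", "configured"}

    def __post_init__(self) -> None:
        if not self.start_doy < self.end_doy:
            raise InvalidInputError(
                f"season start ({self.start_doy}) must precede end ({self.end_doy})"
            )

    @property
    def length(self) -> float:
        return self.end_doy - self.start_doy
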