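"""Weighted CT / cone-beam dose indices from pencil-chamber DLP readings.

Inputs are the five dose-length products (mGy mm) measured in the central
and four peripheral boreholes of an IEC 61223-2-6 dosimetry phantom with a
100 mm pencil ionisation chamber.  With DLPs in mGy mm and the nominal beam
width C in mm, both indices come out in mGy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["DlpSet", "ctdi_w", "cbdi_w"]

#: fixed chamber length used by the cone-beam index (mm)
CBDI_CHAMBER_LENGTH_MM = 300.0


@dataclass(frozen=True)
class DlpSet:
    """Five DLP readings (mGy mm) plus the nominal beam width (mm)."""

    central: float
    peripheral: tuple[float, float, float, float]
    nominal_beam_width: float | None = None  # mm; required for CTDIw only

    def validate(self, require_beam_width: bool = False) -> None:
        if self.central < 0 or any(p < 0 for p in self.peripheral):
            raise ValidationError("dlp", "DLP readings must be >= 0")
        if len(self.peripheral) != 4:
            raise ValidationError("peripheral", "exactly 4 peripheral DLPs required")
        if require_beam_width:
            if self.nominal_beam_width is None or not math.isfinite(self.nominal_beam_width):
                raise ValidationError("nominal_beam_width", "required for CTDIw")
            if self.nominal_beam_width <= 0:
                raise ValidationError("nominal_beam_width", "must be > 0 mm")

    @property
    def peripheral_mean(self) -> float:
        return sum(self.peripheral) / 4.0


def ctdi_w(dlp: DlpSet) -> float:
    """Weighted CT dose index:

        CTDI_w = DLP_central / (3 C) + 2 DLP_peripheral / (3 C)

    with DLP_peripheral the mean of the four peripheral readings and C the
    nominal beam width in mm.  Result in mGy.
    """
    dlp.validate(require_beam_width=True)
    c = dlp.nominal_beam_width
    return dlp.central / (3.0 * c) + 2.0 * dlp.peripheral_mean / (3.0 * c)


def cbdi_w(dlp: DlpSet) -> float:
    """Weighted cone-beam dose index with a fixed 300 mm chamber length:

        CBDI_w = DLP_central / 300 mm + 2 DLP_peripheral / 300 mm
    """
    dlp.validate(require_beam_width=False)
    return (dlp.central + 2.0 * dlp.peripheral_mean) / CBDI_CHAMBER_LENGTH_MM
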