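"""Nominal CatPhan 504 geometry and material constants.

Single source of truth consumed by both the synthetic renderer and the
landmark detectors.  In-plane coordinates are millimetres relative to the
phantom axis, with +x to the right and +y up when looking at an axial
slice; clock-position angles are measured clockwise from 12 o'clock, so
3 o'clock is +x and 6 o'clock is -y.  Longitudinal (z) offsets are
millimetres relative to the centre plane of the CTP404 module.

None of these constants are printed in the published method description;
they are transcribed from the manufacturer's phantom manual where publicly
documented (phantom and module diameters, 50 mm rod spacing, 23 deg ramp
inclination, standard sensitometry HU values) and otherwise chosen as clean
nominal positions.  Every value can be overridden through a layout file
(see :func:`load_layout`) so a user can correct constants without touching
code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "MaterialSpec",
    "InsertPosition",
    "RodPosition",
    "PhantomLayout",
    "default_layout",
    "material_table",
    "load_layout",
]


@dataclass(frozen=True)
class MaterialSpec:
    """A sensitometry material: label, nominal CT number and insert size."""

    name: str
    nominal_hu: float  # HU
    insert_radius: float = 6.1  # mm (12.2 mm diameter sensitometry insert)

    def validate(self) -> None:
        if not (-1100.0 <= self.nominal_hu <= 2000.0):
            raise ValidationError("nominal_hu", f"{self.nominal_hu} outside [-1100, 2000] HU")
        if self.insert_radius <= 0:
            raise ValidationError("insert_radius", "must be > 0")


@dataclass(frozen=True)
class InsertPosition:
    """One CTP404 sensitometry insert on the insert ring.

    ``angle_deg`` is the clock angle (clockwise from 12 o'clock), ``radius``
    the distance of the insert centre from the phantom axis in mm.
    """

    angle_deg: float
    radius: float
    material: MaterialSpec
    key: str  # unique label; materials can repeat (two air inserts)

    def center_xy(self) -> tuple[float, float]:
        a = math.radians(self.angle_deg)
        return (self.radius * math.sin(a), self.radius * math.cos(a))


@dataclass(frozen=True)
class RodPosition:
    """One of the four CTP404 linearity rods (labels 1-4)."""

    label: int
    center_xy: tuple[float, float]  # mm
    material: MaterialSpec


# --- nominal material table (manual-derived nominal HU) ------------------
_AIR = MaterialSpec("air", -1000.0)
_PMP = MaterialSpec("pmp", -200.0)
_LDPE = MaterialSpec("ldpe", -100.0)          # fat-like
_POLYSTYRENE = MaterialSpec("polystyrene", -35.0)  # soft-tissue-like
_ACRYLIC = MaterialSpec("acrylic", 120.0)
_DELRIN = MaterialSpec("delrin", 340.0)       # bone-like
_TEFLON = MaterialSpec("teflon", 990.0)


@dataclass(frozen=True)
class PhantomLayout:
    """Complete nominal CatPhan 504 layout.

    ``module_offsets`` places the CTP404 centre plane, the CTP528
    point-source plane and the CTP486 centre plane on the phantom's z axis;
    ``module_z_extents`` gives each module's physical slab, and ``body_z``
    the longitudinal extent of the whole phantom housing (all relative to
    the CTP404 centre).
    """

    phantom_radius: float = 100.0  # mm; 20 cm housing diameter
    uniformity_module_radius: float = 75.0  # mm; 15 cm module diameter
    body_z: tuple[float, float] = (-24.0, 95.0)
    module_offsets: dict[str, float] = field(
        default_factory=lambda: {"ctp404": 0.0, "ctp528_source": 30.0, "ctp486": 70.0}
    )
    module_z_extents: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ctp404": (-12.5, 12.5),
            "ctp528": (20.0, 40.0),
            "ctp486": (45.0, 95.0),
        }
    )
    insert_positions: tuple[InsertPosition, ...] = (
        InsertPosition(0.0, 58.4, _AIR, "air"),
        InsertPosition(45.0, 58.4, _PMP, "pmp"),
        InsertPosition(90.0, 58.4, _LDPE, "ldpe"),
        InsertPosition(135.0, 58.4, _POLYSTYRENE, "polystyrene"),
        # Fig-style second, unlabeled air insert at 6 o'clock
        InsertPosition(180.0, 58.4, _AIR, "air_2"),
        InsertPosition(225.0, 58.4, _ACRYLIC, "acrylic"),
        InsertPosition(270.0, 58.4, _DELRIN, "delrin"),
        InsertPosition(315.0, 58.4, _TEFLON, "teflon"),
    )
    # Rods span a 50 mm square (centre-to-centre); one Teflon, three air.
    rod_positions: tuple[RodPosition, ...] = (
        RodPosition(1, (-25.0, 25.0), _TEFLON),
        RodPosition(2, (25.0, 25.0), _AIR),
        RodPosition(3, (25.0, -25.0), _AIR),
        RodPosition(4, (-25.0, -25.0), _AIR),
    )
    rod_radius: float = 2.5  # mm
    # Two opposed slice-width ramps: wires running along y at fixed x,
    # inclined by ramp_angle_deg against the axial plane.
    ramp_angle_deg: float = 23.0  # manual-derived default
    ramp_x_offsets: tuple[float, ...] = (-15.0, 15.0)
    ramp_half_length: float = 25.0  # mm along y
    ramp_radius: float = 0.5  # mm wire radius
    ramp_hu: float = 1000.0
    point_source_inplane: tuple[float, float] = (0.0, 0.0)
    background_hu: float = 0.0  # water-like housing material

    # rod pairings used for spatial linearity (Fig-style labelling)
    rod_sides: tuple[tuple[int, int], ...] = ((1, 2), (2, 3), (3, 4), (4, 1))
    rod_diagonals: tuple[tuple[int, int], ...] = ((1, 3), (2, 4))

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(self.rod_positions) != 4:
            raise ValidationError("rod_positions", "exactly 4 rods required")
        labels = [r.label for r in self.rod_positions]
        if len(set(labels)) != 4:
            raise ValidationError("rod_positions", "rod labels must be unique")
        d1, d2 = self.rod_diagonal_lengths()
        if abs(d1 - d2) > 1e-9:
            raise ValidationError("rod_positions", "rod diagonals differ in nominal layout")
        if not (0.0 < self.ramp_angle_deg < 90.0):
            raise ValidationError("ramp_angle_deg", "must lie in (0, 90) degrees")
        keys = [p.key for p in self.insert_positions]
        if len(set(keys)) != len(keys):
            raise ValidationError("insert_positions", "insert keys must be unique")
        for p in self.insert_positions:
            p.material.validate()
        for r in self.rod_positions:
            r.material.validate()
        if self.uniformity_module_radius <= 0 or self.phantom_radius <= 0:
            raise ValidationError("phantom_radius", "radii must be > 0")

    def rod_center(self, label: int) -> tuple[float, float]:
        for r in self.rod_positions:
            if r.label == label:
                return r.center_xy
        raise KeyError(label)

    def rod_diagonal_lengths(self) -> tuple[float, float]:
        out = []
        for a, b in self.rod_diagonals:
            (xa, ya), (xb, yb) = self.rod_center(a), self.rod_center(b)
            out.append(math.hypot(xa - xb, ya - yb))
        return out[0], out[1]

    def insert_by_key(self, key: str) -> InsertPosition:
        for p in self.insert_positions:
            if p.key == key:
                return p
        raise KeyError(key)

    def module_z(self, name: str) -> float:
        """Absolute z (relative to the CTP404 centre) of a module landmark."""
        return self.module_offsets[name]


def default_layout() -> PhantomLayout:
    """Return the canonical CatPhan 504 layout (validated)."""
    layout = PhantomLayout()
    layout.validate()
    return layout


def material_table(layout: PhantomLayout | None = None) -> list[MaterialSpec]:
    """Unique materials appearing in the sensitometry module.

    The two air inserts share one :class:`MaterialSpec`; use the layout's
    ``insert_positions`` to address each insert individually.
    """
    layout = layout or default_layout()
    seen: dict[str, MaterialSpec] = {}
    for p in layout.insert_positions:
        seen.setdefault(p.material.name, p.material)
    for r in layout.rod_positions:
        seen.setdefault(r.material.name, r.material)
    return list(seen.values())


# --- layout override file -------------------------------------------------
def load_layout(path: str | Path) -> PhantomLayout:
    """Load a layout-override file (YAML or JSON).

    The file holds a mapping of :class:`PhantomLayout` field names to values;
    unspecified fields keep their defaults.  ``insert_positions`` entries are
    mappings with keys ``angle_deg, radius, key, material`` where ``material``
    is ``{name, nominal_hu, insert_radius}``; ``rod_positions`` entries use
    ``label, center_xy, material``.
    """
    import json

    import yaml

    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError("layout", "layout file must contain a mapping")

    def _mat(d: dict) -> MaterialSpec:
        return MaterialSpec(d["name"], float(d["nominal_hu"]),
                            float(d.get("insert_radius", 6.1)))

    kwargs: dict = {}
    for key, value in data.items():
        if key == "insert_positions":
            kwargs[key] = tuple(
                InsertPosition(float(e["angle_deg"]), float(e["radius"]),
                               _mat(e["material"]), str(e["key"]))
                for e in value
            )
        elif key == "rod_positions":
            kwargs[key] = tuple(
                RodPosition(int(e["label"]), tuple(map(float, e["center_xy"])),
                            _mat(e["material"]))
                for e in value
            )
        elif key in ("module_offsets",):
            kwargs[key] = {str(k): float(v) for k, v in value.items()}
        elif key in ("module_z_extents",):
            kwargs[key] = {str(k): tuple(map(float, v)) for k, v in value.items()}
        elif key in ("body_z", "ramp_x_offsets", "point_source_inplane",
                     "rod_sides", "rod_diagonals"):
            kwargs[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                                for x in value) if key in ("rod_sides", "rod_diagonals") \
                else tuple(map(float, value))
        elif hasattr(PhantomLayout, "__dataclass_fields__") and key in PhantomLayout.__dataclass_fields__:
            kwargs[key] = value
        else:
            raise ValidationError(key, "unknown layout field")
    layout = replace(PhantomLayout(), **kwargs)
    layout.validate()
    return layout
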