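"""Parameterized muscle-tendon-unit (MTU) construct geometry.

An MTU is a rectilinear construct: a central muscle section flanked by two
tendon-mimicking anchor sections.  The muscle section is either *compact*
(one full-width block) or *sparse* (``n_bridges`` parallel slabs, "bridges",
separated by gaps).  All dimensions are millimetres.  The long (contraction)
axis is z, the width axis is x, the height (print) axis is y, and the origin
sits at the construct center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MTUDesign",
    "make_design",
    "surface_area",
    "interdigitation_fraction",
]


@dataclass(frozen=True)
class MTUDesign:
    """Fully resolved MTU construct geometry (units: mm).

    ``n_bridges == 1`` with ``bridge_width == width`` is the compact design.
    Anchor holes are rectangular through-holes (full height) in each tendon
    section, ``anchor_hole = (extent along x, extent along z)``.
    """

    total_length: float = 15.0
    width: float = 6.0
    height: float = 3.0
    n_bridges: int = 1
    bridge_width: float = 6.0
    bridge_gap: float = 0.0
    muscle_section_length: float = 9.0
    interdigitation_radius: float = 0.8
    anchor_hole: tuple[float, float] = (2.0, 1.0)

    @property
    def tendon_section_length(self) -> float:
        return (self.total_length - self.muscle_section_length) / 2.0

    @property
    def is_compact(self) -> bool:
        return self.n_bridges == 1 and self.bridge_width == self.width

    def bridge_spans(self) -> list[tuple[float, float]]:
        """(x_lo, x_hi) of every bridge, evenly spaced across the width."""
        n, w = self.n_bridges, self.bridge_width
        if n == 1:
            lo = -w / 2.0
            return [(lo, lo + w)]
        gap = self.bridge_gap
        x = -self.width / 2.0
        spans = []
        for _ in range(n):
            spans.append((x, x + w))
            x += w + gap
        return spans

    def validate(self) -> None:
        dims = {
            "total_length": self.total_length,
            "width": self.width,
            "height": self.height,
            "bridge_width": self.bridge_width,
            "muscle_section_length": self.muscle_section_length,
        }
        for name, v in dims.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_bridges < 1:
            raise ValueError(f"n_bridges must be >= 1, got {self.n_bridges}")
        if self.bridge_gap < 0:
            raise ValueError("bridge_gap must be >= 0")
        if self.muscle_section_length >= self.total_length:
            raise ValueError("muscle_section_length must be < total_length")
        occupied = (
            self.n_bridges * self.bridge_width
            + (self.n_bridges - 1) * self.bridge_gap
        )
        if occupied > self.width + 1e-12:
            raise ValueError(
                "bridges overflow construct width: "
                f"{self.n_bridges} x {self.bridge_width} mm bridges with "
                f"{self.bridge_gap} mm gaps occupy {occupied} mm > "
                f"width {self.width} mm"
            )
        if not 0 < self.interdigitation_radius < self.muscle_section_length / 2:
            raise ValueError(
                "interdigitation_radius must lie in "
                "(0, muscle_section_length/2), got "
                f"{self.interdigitation_radius}"
            )
        hx, hz = self.anchor_hole
        if hx <= 0 or hz <= 0:
            raise ValueError("anchor_hole extents must be positive")
        if hx > self.width or hz > self.tendon_section_length:
            raise ValueError("anchor_hole does not fit inside the tendon section")


# Default total in-plane bridge width for sparse designs (mm): half of the
# 6 mm construct width, giving the four-bridge default w_b = 0.75 mm.
_DEFAULT_TOTAL_BRIDGE_WIDTH = 3.0


def make_design(
    n_bridges: int = 1,
    bridge_width: float | None = None,
    *,
    total_length: float = 15.0,
    width: float = 6.0,
    height: float = 3.0,
    muscle_section_length: float = 9.0,
    interdigitation_radius: float = 0.8,
    anchor_hole: tuple[float, float] = (2.0, 1.0),
) -> MTUDesign:
    """Resolve an MTU design from its free parameters.

    ``bridge_width`` defaults to the full width for the compact design
    (``n_bridges == 1``) and to an equal split of a 3 mm total bridge width
    for sparse designs.  Gaps are sized so the bridges span the full width
    symmetrically.  Raises ``ValueError`` when the bridges do not fit.
    """
    if n_bridges < 1:
        raise ValueError(f"n_bridges must be >= 1, got {n_bridges}")
    if bridge_width is None:
        if n_bridges == 1:
            bridge_width = width
        else:
            bridge_width = _DEFAULT_TOTAL_BRIDGE_WIDTH / n_bridges
    if n_bridges == 1:
        gap = 0.0
    else:
        gap = (width - n_bridges * bridge_width) / (n_bridges - 1)
        if gap < 0:
            raise ValueError(
                f"bridges overflow construct width: {n_bridges} x "
                f"{bridge_width} mm > width {width} mm"
            )
    design = MTUDesign(
        total_length=total_length,
        width=width,
        height=height,
        n_bridges=n_bridges,
        bridge_width=bridge_width,
        bridge_gap=gap,
        muscle_section_length=muscle_section_length,
        interdigitation_radius=interdigitation_radius,
        anchor_hole=anchor_hole,
    )
    design.validate()
    return design


def _box_area(a: float, b: float, c: float) -> float:
    return 2.0 * (a * b + a * c + b * c)


def surface_area(design: MTUDesign) -> float:
    """Exterior surface area of the muscle section in mm^2.

    The muscle section is a set of ``n_bridges`` rectangular slabs of size
    ``bridge_width x height x muscle_section_length``; the total area is the
    sum of the slab box areas (gap-facing faces are exterior for sparse
    designs, which is what makes the sparse design's area larger).
    """
    design.validate()
    per_bridge = _box_area(
        design.bridge_width, design.height, design.muscle_section_length
    )
    return design.n_bridges * per_bridge


def interdigitation_fraction(r_i: float, total_length: float) -> float:
    """Interpenetration of the two tissues as a percent of construct length.

    ``r_i`` is the invagination radius of the interdigitated muscle-tendon
    interface (mm); ``total_length`` the construct length (mm).  Returns
    ``100 * r_i / total_length``.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if not 0 < r_i < total_length:
        raise ValueError(
            f"interdigitation radius must lie in (0, total_length), got {r_i}"
        )
    return 100.0 * r_i / total_length


def with_bridges(design: MTUDesign, n_bridges: int, bridge_width: float) -> MTUDesign:
    """Copy ``design`` with a new bridge configuration (gap auto-sized)."""
    if n_bridges == 1:
        new = replace(
            design, n_bridges=1, bridge_width=bridge_width, bridge_gap=0.0
        )
    else:
        gap = (design.width - n_bridges * bridge_width) / (n_bridges - 1)
        if gap < 0:
            raise ValueError(
                f"bridges overflow construct width: {n_bridges} x "
                f"{bridge_width} mm > width {design.width} mm"
            )
        new = replace(
            design,
            n_bridges=n_bridges,
            bridge_width=bridge_width,
            bridge_gap=gap,
        )
    new.validate()
    return new
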