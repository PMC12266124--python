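"""Tissue mechanics: Hertzian indentation and tensile-curve analysis.

Fits Young's moduli from spherical-microindentation force-depth curves
(Hertz contact, rigid indenter) and from uniaxial tensile force-displacement
curves, plus the small derived metrics used to compare construct groups
(fold changes, tissue-specific force, fracture-area fraction).

Units follow the instruments: depth in μm, indentation force in μN,
displacement in mm, tensile force in mN, moduli in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IndentationCurve",
    "TensileCurve",
    "HertzFit",
    "TensileSummary",
    "hertz_force",
    "fit_hertz",
    "tensile_summary",
    "fold_change",
    "tissue_specific_force",
    "fracture_area_fraction",
]

# max indentation depth as a fraction of the indenter radius for the Hertz
# approximation to stay acceptable (the measurement protocol's own limit)
HERTZ_DEPTH_LIMIT = 0.1


def hertz_force(
    depth_um: np.ndarray | float,
    E_kpa: float,
    nu: float = 0.4,
    R_um: float = 100.0,
) -> np.ndarray | float:
    """Hertz sphere-on-halfspace force F = (4/3) E* sqrt(R) delta^(3/2).

    Rigid-indenter reduced modulus E* = E / (1 - nu^2); inputs in μm/kPa,
    output in μN.
    """
    delta = np.asarray(depth_um, dtype=float)
    e_star = E_kpa / (1.0 - nu**2)
    # kPa * um^0.5 * um^1.5 -> 1e3 Pa * 1e-3 m^0.5... collapses to 1e-3 uN
    out = (4.0 / 3.0) * e_star * np.sqrt(R_um) * delta**1.5 * 1e-3
    return out if out.ndim else float(out)


@dataclass
class IndentationCurve:
    """Spherical-indentation force-depth samples (μm, μN)."""

    depth_um: np.ndarray
    force_uN: np.ndarray
    indenter_radius_um: float = 100.0
    condition: str = "immersed"

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.force_uN = np.asarray(self.force_uN, dtype=float)
        if self.depth_um.shape != self.force_uN.shape:
            raise ValueError("depth and force must have the same length")
        if np.any(self.depth_um < 0):
            raise ValueError("depths must be non-negative")
        if np.any(np.diff(self.depth_um) < 0):
            raise ValueError("depths must be non-decreasing")
        if self.indenter_radius_um <= 0:
            raise ValueError("indenter radius must be positive")
        if self.condition not in ("immersed", "air"):
            raise ValueError("condition must be 'immersed' or 'air'")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"depth_um": self.depth_um, "force_uN": self.force_uN}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        indenter_radius_um: float = 100.0,
        condition: str = "immersed",
    ) -> "IndentationCurve":
        df = pd.read_csv(path)
        return cls(
            df["depth_um"].to_numpy(),
            df["force_uN"].to_numpy(),
            indenter_radius_um,
            condition,
        )


@dataclass
class TensileCurve:
    """Uniaxial tensile force-displacement samples with specimen geometry."""

    displacement_mm: np.ndarray
    force_mN: np.ndarray
    cross_section_mm2: float
    gauge_length_mm: float

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_mN = np.asarray(self.force_mN, dtype=float)
        if self.displacement_mm.shape != self.force_mN.shape:
            raise ValueError("displacement and force must have the same length")
        if self.displacement_mm.size and self.displacement_mm[0] != 0:
            raise ValueError("displacement must start at 0")
        if self.cross_section_mm2 <= 0 or self.gauge_length_mm <= 0:
            raise ValueError("specimen geometry must be positive")

    @property
    def strain(self) -> np.ndarray:
        return self.displacement_mm / self.gauge_length_mm

    @property
    def stress_kpa(self) -> np.ndarray:
        # mN / mm^2 == kPa
        return self.force_mN / self.cross_section_mm2

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "displacement_mm": self.displacement_mm,
                "force_mN": self.force_mN,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, cross_section_mm2: float, gauge_length_mm: float
    ) -> "TensileCurve":
        df = pd.read_csv(path)
        return cls(
            df["displacement_mm"].to_numpy(),
            df["force_mN"].to_numpy(),
            cross_section_mm2,
            gauge_length_mm,
        )


@dataclass(frozen=True)
class HertzFit:
    E_kpa: float
    r_squared: float
    residual_rms_uN: float
    contact_offset_um: float = 0.0


def fit_hertz(
    curve: IndentationCurve,
    nu: float = 0.4,
    *,
    fit_contact_offset: bool = False,
) -> HertzFit:
    """Least-squares Hertz fit returning the Young's modulus in kPa.

    The model is linear in E after the delta^(3/2) transform, so the default
    fit is closed form (deterministic, no iterative optimizer).  With
    ``fit_contact_offset`` a two-parameter (E, delta0) nonlinear fit is used
    instead.
    """
    delta, F = curve.depth_um, curve.force_uN
    R = curve.indenter_radius_um
    if delta.size < 5:
        raise ValueError("need at least 5 samples for a Hertz fit")
    if delta.max() > HERTZ_DEPTH_LIMIT * R * (1 + 1e-12):
        raise ValueError(
            f"max depth {delta.max():.3g} μm exceeds "
            f"{100 * HERTZ_DEPTH_LIMIT:.0f}% of the indenter radius "
            f"({R:.3g} μm); outside Hertz validity"
        )
    if np.allclose(F, 0):
        raise ValueError("degenerate curve: all forces are zero")

    coeff = (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(R) * 1e-3  # F = coeff*E*d^1.5
    offset = 0.0
    if fit_contact_offset:
        from scipy.optimize import curve_fit

        def model(d, E, d0):
            dd = np.clip(d - d0, 0.0, None)
            return coeff * E * dd**1.5

        slope0 = float(F @ delta**1.5 / (delta**1.5 @ delta**1.5)) / coeff
        (E, offset), _ = curve_fit(model, delta, F, p0=(slope0, 0.0))
        pred = model(delta, E, offset)
    else:
        x = delta**1.5
        E = float(F @ x / (x @ x)) / coeff
        pred = coeff * E * x
    if E <= 0:
        raise ValueError(f"non-physical fitted modulus E = {E:.3g} kPa")
    ss_res = float(np.sum((F - pred) ** 2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HertzFit(
        E_kpa=E,
        r_squared=r2,
        residual_rms_uN=float(np.sqrt(ss_res / delta.size)),
        contact_offset_um=float(offset),
    )


@dataclass(frozen=True)
class TensileSummary:
    E_kpa: float
    fracture_detected: bool
    fracture_force_mN: float | None = None
    fracture_strain_pct: float | None = None


# force drop relative to the running maximum that counts as fracture
FRACTURE_DROP = 0.5


def tensile_summary(
    curve: TensileCurve, linear_region: tuple[float, float] = (0.02, 0.10)
) -> TensileSummary:
    """Elastic modulus and fracture point from a tensile test to rupture.

    E is the stress-strain slope over ``linear_region`` (strain window);
    fracture is the first drop of more than half the running force maximum,
    and the fracture point is the last sample before that drop.  A curve
    without such a drop yields ``fracture_detected=False`` with E still
    fitted from the window.
    """
    strain, stress = curve.strain, curve.stress_kpa
    F = curve.force_mN

    run_max = np.maximum.accumulate(F)
    # a drop counts as fracture only once the curve has loaded appreciably,
    # so baseline noise near zero strain cannot trigger it
    loaded = run_max > 0.2 * F.max()
    dropped = (F < (1 - FRACTURE_DROP) * run_max) & loaded
    i_drop = int(np.argmax(dropped)) if dropped.any() else None

    end = i_drop if i_drop is not None else strain.size
    lo, hi = linear_region
    sel = (strain[:end] >= lo) & (strain[:end] <= hi)
    if sel.sum() < 2:
        sel = np.ones(end, dtype=bool)  # degenerate window: use pre-fracture
    if sel.sum() < 2:
        raise ValueError("not enough pre-fracture samples to fit a modulus")
    slope = np.polyfit(strain[:end][sel], stress[:end][sel], 1)[0]

    if i_drop is None:
        return TensileSummary(E_kpa=float(slope), fracture_detected=False)
    i_frac = i_drop - 1
    return TensileSummary(
        E_kpa=float(slope),
        fracture_detected=True,
        fracture_force_mN=float(F[i_frac]),
        fracture_strain_pct=float(100.0 * strain[i_frac]),
    )


def fold_change(a: float, b: float) -> float:
    """Ratio a/b (e.g. tendon vs muscle stiffness, MTU vs control force)."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return a / b


def tissue_specific_force(force_uN: float, area_mm2: float) -> float:
    """Contractile force normalized by tissue surface area (μN/mm²)."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return force_uN / area_mm2


def fracture_area_fraction(
    damaged_mask: np.ndarray, tissue_mask: np.ndarray
) -> float:
    """Damaged muscle area as a percentage of total muscle tissue area."""
    damaged = np.asarray(damaged_mask, dtype=bool)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if damaged.shape != tissue.shape:
        raise ValueError("masks must have the same shape")
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    return 100.0 * int((damaged & tissue).sum()) / n_tissue
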