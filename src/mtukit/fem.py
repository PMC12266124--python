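"""Corotational finite-element simulation of MTU contraction.

Model
-----
Trilinear hexahedral elements with isotropic linear elasticity applied in a
per-element rotated (corotated) frame: the rotation is extracted by polar
decomposition of the element-center deformation gradient, so the model stays
valid under the large rotations / small strains of a soft contracting
construct.  Muscle actuation is a rest-shape modification: every contractile
element targets a rest configuration shortened by a factor ``1 - strain``
along the contraction direction, which makes a uniformly contracting free
bar reach its shortened stress-free state exactly.

Time integration is implicit backward Euler with lumped mass and Rayleigh
damping; each step solves the nonlinear balance with a warped-stiffness
Newton loop.  The construct floats freely (as in the study's simulations,
which exclude anchor contact), so the inertial/damping terms also serve to
regularize the six rigid-body modes; rigid drift is removed before the
deformation metric is evaluated.

Unit system: mm, kg, s  =>  forces in mN, moduli in kPa (1 kPa = 1 mN/mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MTUDesign, with_bridges
from .mesh import MUSCLE, HexMesh, hex_mesh

__all__ = [
    "MaterialParams",
    "ActuationSpec",
    "Trajectory",
    "simulate",
    "max_deformation",
    "design_sweep",
    "remove_rigid_motion",
]

# local node coordinates (signs) in VTK hexahedron ordering
_SIGNS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class MaterialParams:
    """Region moduli (kPa) and shared Poisson ratio / density (kg/m^3)."""

    E_muscle: float = 49.7
    E_tendon: float = 158.9
    nu: float = 0.4
    density: float = 1000.0

    def validate(self) -> None:
        if self.E_muscle <= 0 or self.E_tendon <= 0:
            raise ValueError("Young's moduli must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ActuationSpec:
    """Prescribed contractile strain along a principal direction.

    ``strain`` is the relative shortening of contractile elements (the study
    contracts all muscle elements by the same relative amount); ``direction``
    is the contraction axis (parallel to the bridges, i.e. z by default).
    """

    strain: float = 0.10
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    duration: float = 0.4
    dt: float = 0.010
    ramp: str = "linear"

    def validate(self) -> None:
        if not 0 <= self.strain < 1:
            raise ValueError("strain must lie in [0, 1)")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.ramp not in ("linear", "step"):
            raise ValueError(f"unknown ramp {self.ramp!r}")
        if np.linalg.norm(self.direction) == 0:
            raise ValueError("direction must be a nonzero vector")

    @property
    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        return d / np.linalg.norm(d)


@dataclass
class Trajectory:
    """Per-step vertex positions (mm); frame 0 is the rest configuration."""

    frames: np.ndarray  # (n_frames, n_vertices, 3)
    times: np.ndarray  # (n_frames,)
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    elastic_energy: np.ndarray = field(default_factory=lambda: np.empty(0))


def _local_gradients(xi: np.ndarray) -> np.ndarray:
    """(8, 3) trilinear shape-function gradients in local coordinates."""
    dN = np.empty((8, 3))
    for n in range(8):
        s = _SIGNS[n]
        dN[n, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8
        dN[n, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8
        dN[n, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8
    return dN


def _element_stiffness(coords: np.ndarray, nu: float) -> np.ndarray:
    """24x24 stiffness of a trilinear hex (node coords (8, 3)) for E = 1 kPa.

    Full isoparametric 2x2x2 Gauss quadrature, so arbitrarily oriented
    (e.g. rigidly rotated) elements are handled, not just axis-aligned ones.
    """
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    for gx, gy, gz in product((-g, g), repeat=3):
        dN_loc = _local_gradients(np.array([gx, gy, gz]))
        J = coords.T @ dN_loc  # (3, 3)
        detJ = np.linalg.det(J)
        if detJ <= 0:
            raise ValueError("element with non-positive Jacobian")
        dN = dN_loc @ np.linalg.inv(J)  # physical gradients
        B = np.zeros((6, 24))
        for n in range(8):
            bx, by, bz = dN[n]
            c = 3 * n
            B[0, c] = bx
            B[1, c + 1] = by
            B[2, c + 2] = bz
            B[3, c] = by
            B[3, c + 1] = bx
            B[4, c + 1] = bz
            B[4, c + 2] = by
            B[5, c] = bz
            B[5, c + 2] = bx
        K += B.T @ D @ B * detJ
    return K


def _element_volume(coords: np.ndarray) -> float:
    g = 1.0 / np.sqrt(3.0)
    vol = 0.0
    for gx, gy, gz in product((-g, g), repeat=3):
        J = coords.T @ _local_gradients(np.array([gx, gy, gz]))
        vol += np.linalg.det(J)
    return float(vol)


class _System:
    """Precomputed element data for a mesh + materials + actuation triple."""

    def __init__(self, mesh: HexMesh, materials: MaterialParams):
        self.mesh = mesh
        self.n = mesh.n_vertices
        self.elems = mesh.hexahedra
        coords = mesh.vertices[mesh.hexahedra]  # (n_el, 8, 3)
        # elements sharing a geometry (edge-vector signature) share Ke
        edges = np.concatenate(
            [
                coords[:, 1] - coords[:, 0],
                coords[:, 3] - coords[:, 0],
                coords[:, 4] - coords[:, 0],
            ],
            axis=1,
        )
        keys = np.round(edges, 9)
        uniq, first_idx, inv = np.unique(
            keys, axis=0, return_index=True, return_inverse=True
        )
        Ke_unit = np.stack(
            [_element_stiffness(coords[i], materials.nu) for i in first_idx]
        )
        E = np.where(mesh.region == MUSCLE, materials.E_muscle, materials.E_tendon)
        self.Ke = (Ke_unit[inv] * E[:, None, None]).reshape(-1, 8, 3, 8, 3)
        # shape-function gradients at the element center (rest frame)
        dN0 = _local_gradients(np.zeros(3))
        G_unit = np.empty((uniq.shape[0], 8, 3))
        vol_unit = np.empty(uniq.shape[0])
        for k, i in enumerate(first_idx):
            J0 = coords[i].T @ dN0
            G_unit[k] = dN0 @ np.linalg.inv(J0)
            vol_unit[k] = _element_volume(coords[i])
        self.G = G_unit[inv]  # (n_el, 8, 3)
        self.vol = vol_unit[inv]
        rho = materials.density * 1e-6  # kg/m^3 -> kg/mm^3
        m_el = rho * self.vol / 8.0
        mass = np.zeros(self.n)
        np.add.at(mass, self.elems.ravel(), np.repeat(m_el, 8))
        self.mass = mass
        # sparse assembly indices (fixed pattern)
        dof = (3 * self.elems[:, :, None] + np.arange(3)[None, None, :]).reshape(
            -1, 24
        )
        self.rows = np.repeat(dof, 24, axis=1).ravel()
        self.cols = np.tile(dof, (1, 24)).ravel()
        self.rest = mesh.vertices.copy()
        self.x0e = self.rest[self.elems]  # (n_el, 8, 3)
        self.centers = self.x0e.mean(axis=1)

    def actuated_rest(self, strain: float, direction: np.ndarray) -> np.ndarray:
        """Rest nodal coords with contractile elements shortened by strain."""
        x0 = self.x0e.copy()
        if strain > 0:
            c = self.mesh.contractile
            rel = x0[c] - self.centers[c][:, None, :]
            proj = rel @ direction
            x0[c] = (
                self.centers[c][:, None, :]
                + rel
                - strain * proj[:, :, None] * direction[None, None, :]
            )
        return x0

    def rotations(self, x: np.ndarray, corotational: bool) -> np.ndarray:
        if not corotational:
            return np.broadcast_to(np.eye(3), (self.elems.shape[0], 3, 3))
        xe = x[self.elems]
        F = np.einsum("ena,enb->eab", xe, self.G)
        detF = np.linalg.det(F)
        if np.any(detF <= 0):
            bad = int(np.argmin(detF))
            raise RuntimeError(
                f"inverted element {bad}: det(F) = {detF[bad]:.3e}"
            )
        U, _, Vt = np.linalg.svd(F)
        R = U @ Vt
        neg = np.linalg.det(R) < 0
        if np.any(neg):
            U[neg, :, -1] *= -1
            R[neg] = U[neg] @ Vt[neg]
        return R

    def forces_energy(
        self, x: np.ndarray, x0act: np.ndarray, corotational: bool
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Internal force vector (3n,), elastic energy, element rotations."""
        R = self.rotations(x, corotational)
        xe = x[self.elems]
        d = np.einsum("eba,enb->ena", R, xe) - x0act
        g = np.einsum("eicjd,ejd->eic", self.Ke, d)
        energy = 0.5 * float(np.einsum("eic,eic->", d, g))
        fe = np.einsum("eab,enb->ena", R, g)
        f = np.zeros(3 * self.n)
        np.add.at(f, (3 * self.elems[:, :, None] + np.arange(3)).ravel(), fe.ravel())
        return f, energy, R

    def tangent(self, R: np.ndarray) -> sp.csr_matrix:
        """Warped stiffness sum_e (I8 (x) R) Ke (I8 (x) R)^T."""
        Kw = np.einsum("eac,eicjd,ebd->eiajb", R, self.Ke, R)
        A = sp.coo_matrix(
            (Kw.reshape(-1), (self.rows, self.cols)), shape=(3 * self.n, 3 * self.n)
        )
        return A.tocsr()


def simulate(
    mesh: HexMesh,
    materials: MaterialParams = MaterialParams(),
    actuation: ActuationSpec = ActuationSpec(),
    *,
    corotational: bool = True,
    mass_damping: float = 10.0,
    stiffness_damping: float = 0.002,
    tol: float | None = None,
    max_iterations: int = 200,
    settle: bool = True,
) -> Trajectory:
    """Implicitly integrate the actuated construct and return its trajectory.

    The final frame is driven to elastic equilibrium (residual force
    infinity-norm below ``tol``, default ``1e-8 * E_muscle * h^2`` mN) by
    continuing un-recorded implicit steps after the prescribed time window;
    a ``RuntimeError`` reports the residual if the iteration cap is hit.
    """
    materials.validate()
    actuation.validate()
    mesh.validate()
    if actuation.strain > 0 and not mesh.contractile.any():
        raise ValueError("contractile set is empty but strain > 0")

    sys_ = _System(mesh, materials)
    h_ref = float(np.mean(sys_.vol) ** (1.0 / 3.0))
    if tol is None:
        tol = 1e-8 * materials.E_muscle * h_ref**2
    direction = actuation.unit_direction
    dt = actuation.dt
    n_steps = int(round(actuation.duration / dt))
    M = sys_.mass.repeat(3)

    x = sys_.rest.copy().ravel()
    v = np.zeros_like(x)
    frames = [x.copy().reshape(-1, 3)]
    times = [0.0]
    residual_hist: list[float] = []
    energy_hist: list[float] = []

    # Modified-Newton caches: the warped tangent changes slowly along the
    # ramp, so one factorization serves many iterations/steps; it is rebuilt
    # whenever the line search stops making progress.
    cache: dict[str, object] = {"K": None, "lu": None}

    def rebuild(R):
        K = sys_.tangent(R)
        A = (
            sp.diags(M * (1.0 / dt**2 + mass_damping / dt))
            + (1.0 + stiffness_damping / dt) * K
        )
        cache["K"] = K
        cache["lu"] = spla.splu(A.tocsc())

    def be_step(x, v, x0act):
        """One backward-Euler step; returns (x_new, v_new)."""
        x_pred = x + dt * v
        xi = x.copy()
        res = np.inf

        def residual(xq, fq):
            return (
                M * (xq - x_pred) / dt**2
                + mass_damping * M * (xq - x) / dt
                + (stiffness_damping / dt) * (cache["K"] @ (xq - x))
                + fq
            )

        for it in range(max_iterations + 1):
            f, energy, R = sys_.forces_energy(
                xi.reshape(-1, 3), x0act, corotational
            )
            if cache["lu"] is None:
                rebuild(R)
            g = residual(xi, f)
            res = np.abs(g).max()
            if res < tol:
                break
            if it == max_iterations:
                raise RuntimeError(
                    "corotational solve did not converge within "
                    f"{max_iterations} iterations; residual {res:.3e} mN "
                    f"(tolerance {tol:.3e} mN)"
                )
            fresh = False
            while True:
                delta = cache["lu"].solve(-g)
                best = None
                t = 1.0
                for _ls in range(6):
                    x_try = xi + t * delta
                    f_try, _, _ = sys_.forces_energy(
                        x_try.reshape(-1, 3), x0act, corotational
                    )
                    r_try = np.abs(residual(x_try, f_try)).max()
                    if best is None or r_try < best[0]:
                        best = (r_try, x_try)
                    if r_try < 0.9 * res:
                        break
                    t *= 0.5
                if best[0] < 0.9 * res or fresh:
                    break
                rebuild(R)  # stale tangent: refresh and retry once
                g = residual(xi, f)
                res = np.abs(g).max()
                fresh = True
            xi = best[1]
        v_new = (xi - x) / dt
        return xi, v_new

    for step in range(1, n_steps + 1):
        t = step * dt
        if actuation.ramp == "step":
            eps_t = actuation.strain
        else:
            eps_t = actuation.strain * min(t / actuation.duration, 1.0)
        x0act = sys_.actuated_rest(eps_t, direction)
        x, v = be_step(x, v, x0act)
        frames.append(x.copy().reshape(-1, 3))
        times.append(t)

    # settle the final frame to elastic equilibrium: quasistatic Newton with
    # a weak inertial regularizer that pins the six rigid-body modes without
    # slowing the soft elastic modes (unlike the time-step mass term).
    if settle and actuation.strain > 0:
        x0act = sys_.actuated_rest(actuation.strain, direction)
        reg = M * 1e-4 / dt**2
        converged = False
        res = np.inf
        lu = None
        prev_res = np.inf
        for _ in range(max_iterations):
            f, energy, R = sys_.forces_energy(
                x.reshape(-1, 3), x0act, corotational
            )
            res = np.abs(f).max()
            residual_hist.append(res)
            energy_hist.append(energy)
            if res < tol:
                converged = True
                break
            if lu is None or res > 0.5 * prev_res:
                K = sys_.tangent(R)
                lu = spla.splu((sp.diags(reg) + K).tocsc())
            prev_res = res
            delta = lu.solve(-f)
            t = 1.0
            best = None
            for _ls in range(6):
                x_try = x + t * delta
                f_try, _, _ = sys_.forces_energy(
                    x_try.reshape(-1, 3), x0act, corotational
                )
                r_try = np.abs(f_try).max()
                if best is None or r_try < best[0]:
                    best = (r_try, x_try)
                if r_try < res:
                    break
                t *= 0.5
            x = best[1]
        if not converged:
            raise RuntimeError(
                "equilibrium settle did not converge; residual "
                f"{res:.3e} mN (tolerance {tol:.3e} mN)"
            )
        frames[-1] = x.reshape(-1, 3).copy()

    return Trajectory(
        frames=np.stack(frames),
        times=np.asarray(times),
        residuals=np.asarray(residual_hist),
        elastic_energy=np.asarray(energy_hist),
    )


def remove_rigid_motion(
    reference: np.ndarray, deformed: np.ndarray
) -> np.ndarray:
    """Displacements after removing the best-fit rigid transform (Kabsch).

    Finds the rigid transform mapping ``reference`` onto ``deformed`` in the
    least-squares sense and returns ``deformed`` expressed back in the
    reference pose, minus ``reference`` — i.e. the non-rigid displacement
    field.
    """
    c0 = reference.mean(axis=0)
    c1 = deformed.mean(axis=0)
    H = (reference - c0).T @ (deformed - c1)
    U, _, Vt = np.linalg.svd(H)
    R = (U @ Vt).T  # maps reference -> deformed
    if np.linalg.det(R) < 0:
        Vt2 = Vt.copy()
        Vt2[-1] *= -1
        R = (U @ Vt2).T
    aligned = (deformed - c1) @ R + c0  # deformed pulled back to reference pose
    return aligned - reference


def max_deformation(traj: Trajectory) -> float:
    """Largest per-vertex displacement (mm) between first and last frames,
    after rigid-drift removal."""
    if traj.frames.shape[0] < 2:
        raise ValueError("trajectory needs at least two frames")
    disp = remove_rigid_motion(traj.frames[0], traj.frames[-1])
    return float(np.linalg.norm(disp, axis=1).max())


def design_sweep(
    base: MTUDesign,
    n_bridges_list: list[int],
    bridge_width_list: dict[int, list[float]] | list[float],
    materials: MaterialParams = MaterialParams(),
    actuation: ActuationSpec = ActuationSpec(),
    *,
    h: float = 0.5,
    surface_layer_depth: int = 1,
    **sim_kwargs,
) -> pd.DataFrame:
    """Sweep bridge count and width; one row per (n, w_b) pair.

    ``bridge_width_list`` is either one list applied to every n, or a dict
    mapping n -> widths.  Infeasible pairs (bridges overflow the width, or
    unresolvable at ``h``) are recorded with ``feasible = False`` and NaN
    deformation rather than aborting the sweep.
    """
    rows = []
    for n in n_bridges_list:
        widths = (
            bridge_width_list[n]
            if isinstance(bridge_width_list, dict)
            else bridge_width_list
        )
        for w in widths:
            row = {"n_bridges": n, "bridge_width_mm": w}
            try:
                design = with_bridges(base, n, w)
                mesh = hex_mesh(design, h=h, surface_layer_depth=surface_layer_depth)
                traj = simulate(mesh, materials, actuation, **sim_kwargs)
                row["max_deformation_mm"] = max_deformation(traj)
                row["n_vertices"] = mesh.n_vertices
                row["feasible"] = True
            except ValueError as exc:
                row["max_deformation_mm"] = np.nan
                row["n_vertices"] = 0
                row["feasible"] = False
                row["reason"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def optimal_design(sweep: pd.DataFrame) -> pd.Series:
    """Row with maximal deformation; ties broken toward fewer bridges."""
    ok = sweep[sweep["feasible"]]
    if ok.empty:
        raise ValueError("no feasible designs in sweep")
    best = ok.sort_values(
        ["max_deformation_mm", "n_bridges"], ascending=[False, True]
    )
    return best.iloc[0]
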