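import numpy as np
import pytest

from mtukit.fem import (
    ActuationSpec,
    MaterialParams,
    Trajectory,
    design_sweep,
    max_deformation,
    optimal_design,
    remove_rigid_motion,
    simulate,
)
from mtukit.geometry import make_design
from mtukit.mesh import box_mesh, hex_mesh


class TestSimulate:
    def test_zero_strain_is_static(self, uniform_bar):
        traj = simulate(uniform_bar, actuation=ActuationSpec(strain=0.0))
        assert np.allclose(traj.frames, traj.frames[0])
        assert max_deformation(traj) == 0.0

    def test_uniform_bar_reaches_closed_form_equilibrium(self, uniform_bar):
        # every element contracts 10%: stress-free state is the bar scaled
        # by 0.9 along z, so the 10 mm bar ends at 9 mm and end vertices
        # move 0.5 mm toward the center
        traj = simulate(uniform_bar, actuation=ActuationSpec(strain=0.1))
        final = traj.frames[-1]
        length = final[:, 2].max() - final[:, 2].min()
        assert length == pytest.approx(9.0, rel=1e-4)
        assert max_deformation(traj) == pytest.approx(0.5, rel=1e-4)

    def test_frame_count_and_times(self, uniform_bar):
        act = ActuationSpec(strain=0.05, duration=0.1, dt=0.01)
        traj = simulate(uniform_bar, actuation=act)
        assert traj.frames.shape[0] == 11
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(0.1)
        assert np.allclose(traj.frames[0], uniform_bar.vertices)

    def test_final_frame_is_equilibrium(self, uniform_bar):
        traj = simulate(uniform_bar, actuation=ActuationSpec(strain=0.1))
        assert traj.residuals[-1] < 1e-7

    def test_surface_actuation_bounded_by_full_depth(self):
        # only the surface shell contracts: the end displacement must lie
        # strictly between zero and the all-contractile bound eps*L/2
        bar = box_mesh(1.5, 1.5, 6.0, 0.5, contractile="surface")
        md = max_deformation(simulate(bar, actuation=ActuationSpec(strain=0.1)))
        assert 0.0 < md < 0.1 * 6.0 / 2

    def test_small_strain_corotational_matches_linear(self, uniform_bar):
        act = ActuationSpec(strain=1e-3)
        md_coro = max_deformation(simulate(uniform_bar, actuation=act))
        md_lin = max_deformation(
            simulate(uniform_bar, actuation=act, corotational=False)
        )
        assert md_coro == pytest.approx(md_lin, rel=0.01)

    def test_objectivity_under_rest_rotation(self, uniform_bar):
        th = np.deg2rad(30.0)
        R = np.array(
            [
                [np.cos(th), 0, np.sin(th)],
                [0, 1, 0],
                [-np.sin(th), 0, np.cos(th)],
            ]
        )
        rotated = box_mesh(2.0, 2.0, 10.0, 0.5, contractile="all")
        rotated.vertices = rotated.vertices @ R.T
        d = tuple(R @ np.array([0.0, 0.0, 1.0]))
        md_ref = max_deformation(
            simulate(uniform_bar, actuation=ActuationSpec(strain=0.1))
        )
        md_rot = max_deformation(
            simulate(rotated, actuation=ActuationSpec(strain=0.1, direction=d))
        )
        assert md_rot == pytest.approx(md_ref, rel=1e-5)

    def test_settle_energy_monotone_decreasing(self, uniform_bar):
        traj = simulate(uniform_bar, actuation=ActuationSpec(strain=0.1))
        e = traj.elastic_energy
        assert len(e) >= 2
        assert np.all(np.diff(e) <= 1e-12 + 1e-9 * e.max())

    def test_refinement_convergence(self):
        # surface-actuated bar with a fixed *physical* 0.5 mm contractile
        # shell: the metric changes < 2% when h is halved
        md = {}
        for h in (0.5, 0.25):
            bar = box_mesh(1.5, 1.5, 6.0, h, contractile="none")
            c = bar.vertices[bar.hexahedra].mean(axis=1)
            shell = (
                (np.abs(c[:, 0]) > 0.75 - 0.5)
                | (np.abs(c[:, 1]) > 0.75 - 0.5)
                | (np.abs(c[:, 2]) > 3.0 - 0.5)
            )
            bar.contractile = shell
            md[h] = max_deformation(
                simulate(bar, actuation=ActuationSpec(strain=0.1))
            )
        assert md[0.25] == pytest.approx(md[0.5], rel=0.02)

    def test_empty_contractile_set_rejected(self):
        bar = box_mesh(2.0, 2.0, 4.0, 0.5, contractile="none")
        with pytest.raises(ValueError, match="contractile set is empty"):
            simulate(bar, actuation=ActuationSpec(strain=0.1))

    def test_invalid_actuation_rejected(self):
        with pytest.raises(ValueError):
            ActuationSpec(strain=1.5).validate()
        with pytest.raises(ValueError):
            ActuationSpec(dt=-1).validate()
        with pytest.raises(ValueError):
            MaterialParams(nu=0.5).validate()


class TestMaxDeformation:
    def test_static_trajectory_is_zero(self, uniform_bar):
        X = uniform_bar.vertices
        traj = Trajectory(frames=np.stack([X, X]), times=np.array([0.0, 1.0]))
        assert max_deformation(traj) == 0.0

    def test_rigid_translation_removed(self, uniform_bar):
        X = uniform_bar.vertices
        traj = Trajectory(
            frames=np.stack([X, X + np.array([1.0, 0.0, 0.0])]),
            times=np.array([0.0, 1.0]),
        )
        assert max_deformation(traj) < 1e-10

    def test_rigid_rotation_removed(self, uniform_bar):
        X = uniform_bar.vertices
        th = 0.3
        R = np.array(
            [
                [np.cos(th), -np.sin(th), 0],
                [np.sin(th), np.cos(th), 0],
                [0, 0, 1],
            ]
        )
        traj = Trajectory(
            frames=np.stack([X, X @ R.T + 0.5]), times=np.array([0.0, 1.0])
        )
        assert max_deformation(traj) < 1e-9

    def test_single_frame_rejected(self, uniform_bar):
        traj = Trajectory(
            frames=uniform_bar.vertices[None], times=np.array([0.0])
        )
        with pytest.raises(ValueError):
            max_deformation(traj)

    def test_remove_rigid_motion_recovers_pure_strain(self, uniform_bar):
        # on a reflection-symmetric cloud the best-fit rigid transform of a
        # pure axis-aligned strain is the identity, so the non-rigid
        # displacement is recovered exactly
        X = uniform_bar.vertices
        S = np.diag([1.0, 1.0, 0.9])
        disp = remove_rigid_motion(X, X @ S)
        assert np.allclose(disp, X @ S - X, atol=1e-8)


class TestDesignSweep:
    def test_single_cell_matches_direct_call(self, materials):
        base = make_design(4)
        act = ActuationSpec(strain=0.1)
        table = design_sweep(base, [4], [0.75], materials, act, h=0.5)
        assert len(table) == 1
        mesh = hex_mesh(make_design(4), h=0.5)
        direct = max_deformation(simulate(mesh, materials, act))
        assert table.max_deformation_mm.iloc[0] == pytest.approx(direct)

    def test_infeasible_pairs_logged_not_fatal(self, materials):
        base = make_design(1)
        act = ActuationSpec(strain=0.05, duration=0.05)
        table = design_sweep(
            base, [4], [2.0, 0.3], materials, act, h=0.5
        )
        assert not table.feasible.any()
        assert table.reason.str.contains("overflow|elements").all(), table.reason

    def test_optimal_design_tie_breaks_toward_fewer_bridges(self):
        import pandas as pd

        sweep = pd.DataFrame(
            {
                "n_bridges": [4, 2],
                "bridge_width_mm": [0.75, 1.5],
                "max_deformation_mm": [0.4, 0.4],
                "feasible": [True, True],
            }
        )
        assert optimal_design(sweep).n_bridges == 2
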