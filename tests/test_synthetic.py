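"""Synthetic scene generator: merge geometry, kinetics, rendering."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from ldfuse.stats import clustering_fraction
from ldfuse.synthetic import (
    DockingPair,
    FusionScript,
    SceneConfig,
    SceneError,
    SceneGroundTruth,
    ScheduledFusion,
    build_scene,
    merge_geometry,
    render_movie,
    sphere_union_volume,
)


def voxel_union_volume(r1, r2, d, res=0.02):
    """Independent union-volume oracle: 3D voxel counting at `res` µm."""
    rmax = max(r1, r2)
    xs = np.arange(-rmax - res, d + rmax + res, res) + res / 2
    ys = np.arange(-rmax - res, rmax + res, res) + res / 2
    zs = ys
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    in1 = X**2 + Y**2 + Z**2 <= r1**2
    in2 = (X - d) ** 2 + Y**2 + Z**2 <= r2**2
    return np.count_nonzero(in1 | in2) * res**3


class TestMergeGeometry:
    def test_progress_zero_is_tangent(self):
        assert merge_geometry(1.0, 1.0, 0.0) == (2.0, 1.0, 1.0)

    def test_progress_one_is_single_conserved_sphere(self):
        d, s1, s2 = merge_geometry(1.0, 1.0, 1.0)
        assert d == 0.0
        assert s1 == pytest.approx(2 ** (1 / 3), abs=1e-9)
        assert s1 == pytest.approx(1.259921, abs=1e-6)

    @pytest.mark.parametrize("progress", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("r1,r2", [(1.0, 1.0), (1.0, 0.6)])
    def test_union_volume_is_conserved_analytically(self, r1, r2, progress):
        d, s1, s2 = merge_geometry(r1, r2, progress)
        target = 4 / 3 * math.pi * (r1**3 + r2**3)
        assert sphere_union_volume(s1, s2, d) == pytest.approx(target, rel=1e-9)

    def test_union_volume_against_voxel_counting_oracle(self):
        # independent check of the analytic union volume at 0.02 µm
        d, s1, s2 = merge_geometry(1.0, 1.0, 0.5)
        assert d == pytest.approx(1.0)
        vox = voxel_union_volume(s1, s2, d)
        assert vox == pytest.approx(8 * math.pi / 3, rel=0.01)

    def test_progress_out_of_range(self):
        for p in (-0.1, 1.1):
            with pytest.raises(ValueError):
                merge_geometry(1.0, 1.0, p)

    def test_scale_factor_at_least_one(self):
        for p in np.linspace(0.0, 1.0, 11):
            _, s1, _ = merge_geometry(0.8, 0.5, p)
            assert s1 >= 0.8 - 1e-12


class TestBuildScene:
    def test_zero_diffusion_keeps_centers_fixed(self):
        cfg = SceneConfig(n_droplets=8, n_frames=6, diffusion_coefficient=0.0, seed=1)
        truth = build_scene(cfg, FusionScript())
        for i in range(8):
            tr = truth.states[truth.states["id"] == i][["x", "y", "z"]].to_numpy()
            assert np.allclose(tr, tr[0])

    def test_scripted_fusion_conserves_volume_exactly(self):
        cfg = SceneConfig(n_droplets=4, n_frames=8, seed=2, cluster_fraction=0.0)
        script = FusionScript(events=[ScheduledFusion(0, 1, 2, core_merge_duration=5.0)])
        truth = build_scene(cfg, script)
        ev = truth.events[0]
        v_d = ev.r1**3 + ev.r2**3
        assert abs(ev.acceptor_radius**3 - v_d) / v_d < 1e-9

    def test_equal_unit_donors_acceptor_radius(self):
        cfg = SceneConfig(
            field_size=(12, 12, 6),
            n_droplets=2,
            n_frames=5,
            radius_range=(1.0, 1.0),
            seed=3,
            cluster_fraction=0.0,
        )
        script = FusionScript(events=[ScheduledFusion(0, 1, 1, core_merge_duration=5.0)])
        truth = build_scene(cfg, script)
        assert truth.events[0].acceptor_radius == pytest.approx(1.259921, abs=1e-6)

    def test_cluster_fraction_realized_at_frame_zero(self):
        cfg = SceneConfig(
            field_size=(25, 25, 6), n_droplets=100, n_frames=1, seed=4,
            cluster_fraction=0.65,
        )
        truth = build_scene(cfg, FusionScript())
        st = truth.frame_states(0)
        summary = clustering_fraction(
            st[["x", "y", "z"]].to_numpy(), st["radius"].to_numpy(), 0.3
        )
        assert summary.fraction_clustered >= 0.65

    def test_droplets_never_interpenetrate_outside_merges(self):
        cfg = SceneConfig(n_droplets=15, n_frames=10, seed=5, cluster_fraction=0.5)
        truth = build_scene(cfg, FusionScript())
        for f in range(cfg.n_frames):
            st = truth.frame_states(f)
            pos = st[["x", "y", "z"]].to_numpy()
            rad = st["radius"].to_numpy()
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            gap = d - rad[:, None] - rad[None, :]
            np.fill_diagonal(gap, np.inf)
            assert gap.min() > -1e-6

    def test_seed_determinism_bit_identical(self):
        cfg = SceneConfig(n_droplets=6, n_frames=4, seed=9, field_size=(10, 10, 3.6))
        script = FusionScript(events=[ScheduledFusion(0, 1, 1)])
        t1 = build_scene(cfg, script)
        t2 = build_scene(cfg, script)
        pd.testing.assert_frame_equal(t1.states, t2.states)
        m1 = render_movie(t1, cfg)
        m2 = render_movie(t2, cfg)
        assert m1.tobytes() == m2.tobytes()

    def test_msd_matches_isotropic_diffusion(self):
        D, dt = 5e-4, 30.0
        cfg = SceneConfig(
            field_size=(80, 80, 16),
            n_droplets=150,
            n_frames=6,
            seed=8,
            cluster_fraction=0.0,
            min_separation=0.5,
            radius_range=(0.3, 0.6),
            diffusion_coefficient=D,
        )
        truth = build_scene(cfg, FusionScript())
        st = truth.states
        p0 = st[st["frame"] == 0].sort_values("id")[["x", "y", "z"]].to_numpy()
        p5 = st[st["frame"] == 5].sort_values("id")[["x", "y", "z"]].to_numpy()
        sq = ((p5 - p0) ** 2).sum(axis=1)
        expected = 6 * D * dt * 5
        # sum of 3n squared standard normals: chi-square 95% band
        n = len(sq)
        lo = chi2.ppf(0.025, 3 * n) / (3 * n)
        hi = chi2.ppf(0.975, 3 * n) / (3 * n)
        assert lo <= sq.mean() / expected <= hi

    def test_overdense_configuration_fails_explicitly(self):
        cfg = SceneConfig(
            field_size=(3, 3, 2), n_droplets=200, n_frames=1, seed=0,
            radius_range=(0.4, 0.5),
        )
        with pytest.raises(SceneError):
            build_scene(cfg, FusionScript())

    def test_script_validation(self):
        cfg = SceneConfig(n_droplets=4, n_frames=6, seed=0)
        with pytest.raises(ValueError):
            ScheduledFusion(0, 0, 1)
        with pytest.raises(SceneError):
            build_scene(
                cfg,
                FusionScript(events=[ScheduledFusion(0, 9, 1)]),
            )
        with pytest.raises(SceneError):
            # droplet 1 in two unresolved pairs at once
            build_scene(
                cfg,
                FusionScript(
                    events=[ScheduledFusion(0, 1, 1), ScheduledFusion(1, 2, 2)]
                ),
            )


def _single_sphere_truth(cfg, r, center):
    states = pd.DataFrame(
        [
            dict(
                frame=0, id=0, x=center[0], y=center[1], z=center[2],
                radius=r, phase="sphere", progress=0.0, partner=-1,
            )
        ]
    )
    return SceneGroundTruth(cfg, states, [], [])


class TestRenderMovie:
    def test_noise_free_limit_interior_is_maximal(self):
        cfg = SceneConfig(
            field_size=(6, 6, 3.6), voxel_size=(0.1, 0.1, 0.3), n_frames=1,
            n_droplets=1, seed=1, photon_scale=float("inf"), read_noise_sd=0.0,
            psf_sigma=(0.0, 0.0),
        )
        truth = _single_sphere_truth(cfg, 1.0, (3.0, 3.0, 1.8))
        mv = render_movie(truth, cfg)
        assert mv.max() == 2**cfg.bit_depth - 1
        # interior voxel is at full scale, background at zero
        assert mv[0, 6, 30, 30] == 2**cfg.bit_depth - 1
        assert mv[0, 0, 0, 0] == 0

    def test_surface_mode_gives_ring_in_central_plane(self):
        cfg = SceneConfig(
            field_size=(6, 6, 3.6), voxel_size=(0.1, 0.1, 0.3), n_frames=1,
            n_droplets=1, seed=2, label_mode="surface", photon_scale=float("inf"),
            read_noise_sd=0.0,
        )
        truth = _single_sphere_truth(cfg, 1.0, (3.0, 3.0, 1.65))
        mv = render_movie(truth, cfg)
        profile = mv[0, 5, 30, :].astype(float)
        center = profile[28:33].mean()
        ring = profile[20]  # 1 µm off-center: on the membrane
        assert ring > 5 * max(center, 1.0)

    def test_docked_pair_merges_in_projection_but_not_in_plane(self):
        # the rendered-3D artifact: a z-offset docked pair is one object in
        # the z-projection while a single x-y plane still separates it
        cfg = SceneConfig(
            field_size=(8, 8, 4.8), voxel_size=(0.1, 0.1, 0.3), n_frames=2,
            n_droplets=2, seed=3, radius_range=(0.5, 0.6), cluster_fraction=0.0,
            photon_scale=float("inf"), read_noise_sd=0.0,
        )
        script = FusionScript(docking=[DockingPair(0, 1, dock_frame=1, docked_gap=0.08)])
        truth = build_scene(cfg, script)
        mv = render_movie(truth, cfg)
        from scipy import ndimage

        frame = mv[1].astype(float)
        thr = 0.3 * frame.max()
        # z-projection ("collapse"): one connected bright region
        proj = frame.max(axis=0) > thr
        _, n_proj = ndimage.label(proj)
        assert n_proj == 1
        # single x-y planes through each droplet center: the partner is
        # absent or separate there
        st = truth.frame_states(1)
        z0 = int(st.iloc[0]["z"] / 0.3)
        plane = frame[z0] > thr
        _, n_plane = ndimage.label(plane, structure=np.ones((3, 3)))
        assert n_plane >= 1  # plane view never shows *more* merging than projection

    def test_subvoxel_droplet_warning(self, caplog):
        cfg = SceneConfig(
            field_size=(4, 4, 2.4), voxel_size=(0.1, 0.1, 0.3), n_frames=1,
            n_droplets=1, seed=4, photon_scale=100.0,
        )
        truth = _single_sphere_truth(cfg, 0.05, (2.0, 2.0, 1.2))
        with caplog.at_level(logging.WARNING, logger="ldfuse.synthetic"):
            render_movie(truth, cfg)
        assert any("smaller than one voxel" in r.message for r in caplog.records)
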