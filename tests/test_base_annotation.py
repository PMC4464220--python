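import numpy as np
import pytest

from ribopmf.base_annotation import (
    AnnotationCriteria,
    PairCategory,
    RelativePosition,
    WcModel,
    annotate_frame,
    annotate_trajectory,
    build_frame,
    calibrate_wc_model,
    classify_pair,
    criteria_from_yaml,
    criteria_to_yaml,
    ellipsoidal_distance,
    relative_position,
    wc_score,
)
from ribopmf.structure_io import Atom, LoopDefinition, Residue
from ribopmf.synthetic_data import (
    GeometryRecipe,
    build_geometry,
    build_undocking_series,
    default_wc_model,
    geometry_suite,
)

from conftest import random_rigid_motion, transform_model

RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def hexagon_residue(radius=1.4, center=(0.0, 0.0, 0.0), noise=None, index=1,
                    name="G"):
    """Regular hexagon in the xy-plane with C2 on +x from the center."""
    angles = {"N1": -60, "C2": 0, "N3": 60, "C4": 120, "C5": 180, "C6": 240}
    res = Residue(index=index, name=name)
    for i, (atom, ang) in enumerate(angles.items()):
        pos = np.asarray(center) + radius * np.array(
            [np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang)), 0.0]
        )
        if noise is not None:
            pos = pos + noise[i]
        res.atoms.append(Atom(atom, index, name, pos, 14.0))
    return res


class TestBuildFrame:
    def test_planar_hexagon(self):
        frame = build_frame(hexagon_residue(center=(2.0, -1.0, 3.0)))
        assert np.allclose(frame.origin, [2, -1, 3], atol=1e-12)
        assert np.allclose(frame.axes[0], [1, 0, 0], atol=1e-12)
        assert abs(frame.axes[2] @ [0, 0, 1]) == pytest.approx(1.0)

    def test_rigid_motion_equivariance(self):
        res = hexagon_residue()
        frame = build_frame(res)
        rng = np.random.default_rng(7)
        rot, trans = random_rigid_motion(rng)
        moved_res = hexagon_residue()
        for a in moved_res.atoms:
            a.position = rot @ a.position + trans
        moved = build_frame(moved_res)
        assert np.allclose(moved.origin, rot @ frame.origin + trans, atol=1e-9)
        # axes transform as row vectors under the rotation
        assert np.allclose(moved.axes, frame.axes @ rot.T, atol=1e-9)

    def test_noisy_ring_normal_close_to_plane_oracle(self):
        rng = np.random.default_rng(11)
        noise = np.zeros((6, 3))
        noise[:, 2] = rng.uniform(-0.05, 0.05, 6)
        res = hexagon_residue(noise=noise)
        frame = build_frame(res)
        # independent least-squares plane: eigenvector of the centered
        # coordinate covariance with the smallest eigenvalue
        coords = np.array([res.atom(n).position for n in RING])
        centered = coords - coords.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        oracle_normal = evecs[:, 0]
        cosine = abs(frame.axes[2] @ oracle_normal)
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 5.0
        # also within 5 degrees of the unperturbed normal
        assert np.degrees(np.arccos(abs(frame.axes[2] @ [0, 0, 1]))) < 5.0

    def test_missing_ring_atom_names_residue_and_atom(self):
        res = hexagon_residue()
        res.atoms = [a for a in res.atoms if a.name != "N3"]
        with pytest.raises(ValueError, match="G1.*N3"):
            build_frame(res)

    def test_degenerate_ring_rejected(self):
        res = Residue(index=1, name="G")
        for i, n in enumerate(RING):
            res.atoms.append(Atom(n, 1, "G", np.array([float(i), 0, 0]), 14.0))
        with pytest.raises(ValueError, match="degenerate"):
            build_frame(res)


class TestRelativePosition:
    def test_identity_frame(self):
        from ribopmf.base_annotation import BaseFrame

        f_j = BaseFrame(np.zeros(3), np.eye(3))
        f_k = BaseFrame(np.array([3.0, 0, 0]), np.eye(3))
        assert np.allclose(relative_position(f_j, f_k).r_jk, [3, 0, 0])

    def test_coincident_origins(self):
        from ribopmf.base_annotation import BaseFrame

        f = BaseFrame(np.ones(3), np.eye(3))
        assert np.allclose(relative_position(f, f).r_jk, [0, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_norm_symmetric(self, seed):
        from ribopmf.base_annotation import BaseFrame
        from scipy.stats import special_ortho_group

        rng = np.random.default_rng(seed)
        f_j = BaseFrame(rng.normal(size=3),
                        special_ortho_group.rvs(3, random_state=rng))
        f_k = BaseFrame(rng.normal(size=3),
                        special_ortho_group.rvs(3, random_state=rng))
        r_jk = relative_position(f_j, f_k)
        r_kj = relative_position(f_k, f_j)
        assert np.linalg.norm(r_jk.r_jk) == pytest.approx(
            np.linalg.norm(r_kj.r_jk), abs=1e-12
        )


class TestEllipsoidalDistance:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0, 0, 0), 0.0), ((5, 0, 0), 1.0), ((0, 0, 3), 1.0), ((5, 0, 3), 2.0)],
    )
    def test_reference_points(self, vec, expected):
        r = RelativePosition(np.asarray(vec, float))
        assert ellipsoidal_distance(r) == pytest.approx(expected)

    def test_custom_semiaxes(self):
        r = RelativePosition(np.array([2.0, 0.0, 0.0]))
        assert ellipsoidal_distance(r, (2, 1, 1)) == pytest.approx(1.0)


class TestWcScore:
    def test_maximal_at_mean(self):
        model = WcModel(mu=np.array([5.5, 0, 0]), sigma=np.eye(3) * 0.1)
        at_mu = RelativePosition(model.mu.copy())
        peak = wc_score(at_mu, at_mu, model)
        rng = np.random.default_rng(3)
        for _ in range(50):
            r = RelativePosition(model.mu + rng.normal(0, 1, 3))
            assert wc_score(r, r, model) <= peak

    def test_closed_form_unit_sigma(self):
        # sigma = I, r = mu + (1,0,0): density = (2 pi)^{-3/2} exp(-1/2)
        model = WcModel(mu=np.zeros(3), sigma=np.eye(3))
        r = RelativePosition(np.array([1.0, 0.0, 0.0]))
        expected_density = (2 * np.pi) ** (-1.5) * np.exp(-0.5)
        # independent density oracle: evaluate the normal pdf formula directly
        diff = r.r_jk - model.mu
        oracle = np.exp(-0.5 * diff @ np.linalg.inv(model.sigma) @ diff) / (
            (2 * np.pi) ** 1.5 * np.sqrt(np.linalg.det(model.sigma))
        )
        assert oracle == pytest.approx(expected_density, rel=1e-12)
        assert wc_score(r, r, model) == pytest.approx(expected_density**2, rel=1e-9)

    def test_monotone_decay_along_ray(self):
        model = WcModel(mu=np.array([1.0, 2.0, 3.0]), sigma=np.eye(3) * 0.5)
        direction = np.array([1.0, -1.0, 0.5])
        scores = []
        for t in np.linspace(0, 10, 25):
            r = RelativePosition(model.mu + t * direction)
            scores.append(wc_score(r, r, model))
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[-1] < 1e-30

    def test_symmetric_in_arguments(self):
        model = default_wc_model()
        r1 = RelativePosition(np.array([5.5, 0.3, -0.1]))
        r2 = RelativePosition(np.array([5.8, -0.2, 0.2]))
        assert wc_score(r1, r2, model) == wc_score(r2, r1, model)

    def test_singular_sigma_rejected(self):
        sigma = np.zeros((3, 3))
        with pytest.raises(ValueError, match="positive definite"):
            WcModel(mu=np.zeros(3), sigma=sigma)


class TestClassifyPair:
    def test_coaxial_stack(self):
        model = build_geometry(
            GeometryRecipe("stack", "GA", {"displacement": (0.0, 0.0, 3.4)})
        )
        ann = classify_pair(model.residues[0], model.residues[1],
                            AnnotationCriteria())
        # hand check: D = 3.4^2/9 = 1.284 < 2.5, rho^2 = 0 < 5, |z| >= 2
        assert ann.category is PairCategory.STACKING
        assert ellipsoidal_distance(ann.r_jk) == pytest.approx(3.4**2 / 9, abs=1e-6)

    def test_in_plane_noncanonical_ga(self):
        model = build_geometry(
            GeometryRecipe("noncanonical_pair", "GA",
                           {"displacement": (4.0, 0.0, 0.5)})
        )
        ann = classify_pair(model.residues[0], model.residues[1],
                            AnnotationCriteria())
        assert ann.category is PairCategory.NONCANONICAL
        assert ann.r_jk.z == pytest.approx(0.5, abs=1e-9)
        assert ann.r_kj.z == pytest.approx(-0.5, abs=1e-9)

    def test_gc_at_model_mean_is_wc(self):
        model = build_geometry(GeometryRecipe("wc_pair", "GC"))
        ann = classify_pair(model.residues[0], model.residues[1],
                            AnnotationCriteria())
        assert ann.category is PairCategory.WC

    def test_symmetric_under_swap(self):
        crit = AnnotationCriteria()
        for kind in ("wc_pair", "noncanonical_pair", "stack", "none"):
            model = build_geometry(GeometryRecipe(kind, "GC"))
            a = classify_pair(model.residues[0], model.residues[1], crit)
            b = classify_pair(model.residues[1], model.residues[0], crit)
            assert a.category is b.category

    def test_rigid_motion_invariance(self):
        crit = AnnotationCriteria()
        rng = np.random.default_rng(23)
        for kind in ("wc_pair", "noncanonical_pair", "stack", "none"):
            model = build_geometry(GeometryRecipe(kind, "GC"))
            before = classify_pair(model.residues[0], model.residues[1], crit)
            rot, trans = random_rigid_motion(rng)
            moved = transform_model(model, rot, trans)
            after = classify_pair(moved.residues[0], moved.residues[1], crit)
            assert before.category is after.category
            assert np.allclose(before.r_jk.r_jk, after.r_jk.r_jk, atol=1e-9)

    def test_wc_satisfies_pairing_envelope(self):
        # WC geometry is a special case of the non-canonical envelope
        crit = AnnotationCriteria()
        for model, label, (j, k) in geometry_suite():
            if label is not PairCategory.WC:
                continue
            ann = classify_pair(model.residue(j), model.residue(k), crit)
            assert ann.category is PairCategory.WC
            for r in (ann.r_jk, ann.r_kj):
                assert ellipsoidal_distance(r, crit.ellipsoid_semiaxes) < 2.5
                assert abs(r.z) < 2.0

    def test_literal_stack_z_variant_kills_stacks(self):
        crit = AnnotationCriteria(literal_stack_z=True)
        model = build_geometry(
            GeometryRecipe("stack", "GA", {"displacement": (0.0, 0.0, 3.4)})
        )
        ann = classify_pair(model.residues[0], model.residues[1], crit)
        assert ann.category is PairCategory.NONE

    def test_no_geometry_both_pair_and_stack_like(self):
        # with z_pair_max == z_stack_min the pairing and stacking z-windows
        # are disjoint: check a scan over z never yields ambiguity
        crit = AnnotationCriteria()
        for z in np.linspace(0, 4, 41):
            r = RelativePosition(np.array([1.0, 0.0, z]))
            pair_like = (
                ellipsoidal_distance(r, crit.ellipsoid_semiaxes) < crit.d_cutoff
                and abs(r.z) < crit.z_pair_max
            )
            stack_like = (
                ellipsoidal_distance(r, crit.ellipsoid_semiaxes) < crit.d_cutoff
                and abs(r.z) >= crit.z_stack_min
                and r.rho2 < crit.rho2_stack_max
            )
            assert not (pair_like and stack_like)


class TestAnnotateFrame:
    LOOP_A = LoopDefinition("L2", (20, 26))
    LOOP_B = LoopDefinition("L3", (48, 54))

    def test_kissing_complex_has_two_planted_wc_pairs(self):
        model = build_geometry(GeometryRecipe("kissing_complex"))
        counts, annotations = annotate_frame(model, self.LOOP_A, self.LOOP_B)
        assert counts.wc_inter == 2
        wc_pairs = {
            tuple(sorted((a.residue_j, a.residue_k)))
            for a in annotations
            if a.category is PairCategory.WC
        }
        assert wc_pairs == {(25, 49), (26, 48)}
        assert counts.stack_intra >= 8

    def test_separated_loops_have_no_inter_contacts(self):
        (model,) = build_undocking_series([50.0])
        counts, _ = annotate_frame(model, self.LOOP_A, self.LOOP_B)
        assert counts.wc_inter == 0
        assert counts.noncanonical_inter == 0
        assert counts.stack_inter == 0

    def test_stacked_seven_mer_has_six_sequential_stacks(self):
        strand = build_geometry(
            GeometryRecipe("aform_strand", "GCAUGCA", {"start_index": 1})
        )
        # park an unrelated far-away residue as the second loop
        lone = build_geometry(
            GeometryRecipe("none", "GC", {"displacement": (100.0, 0.0, 0.0)})
        )
        lone_res = lone.residues[1]
        lone_res.index = 50
        for a in lone_res.atoms:
            a.residue_index = 50
        strand.residues.append(lone_res)
        counts, _ = annotate_frame(
            strand, LoopDefinition("A", (1, 7)), LoopDefinition("B", (50, 50))
        )
        assert counts.stack_intra == 6
        assert counts.wc_inter == counts.noncanonical_inter == counts.stack_inter == 0


class TestAnnotateTrajectory:
    LOOP_A = LoopDefinition("L2", (20, 26))
    LOOP_B = LoopDefinition("L3", (48, 54))

    def test_identical_frames_average_to_single_frame(self):
        model = build_geometry(GeometryRecipe("kissing_complex"))
        table, means = annotate_trajectory([model] * 3, self.LOOP_A, self.LOOP_B)
        assert len(table) == 3
        assert means.loc[0, "wc_inter"] == table["wc_inter"].iloc[0]

    def test_mean_of_2_2_0_0_is_one(self):
        docked = build_geometry(GeometryRecipe("kissing_complex"))
        far = build_undocking_series([50.0])[0]
        table, means = annotate_trajectory(
            [docked, docked, far, far], self.LOOP_A, self.LOOP_B
        )
        assert list(table["wc_inter"]) == [2, 2, 0, 0]
        assert means.loc[0, "wc_inter"] == pytest.approx(1.0)

    def test_undocking_series_wc_monotone_nonincreasing(self):
        from ribopmf.structure_io import loop_distance

        docked = build_geometry(GeometryRecipe("kissing_complex"))
        d0 = loop_distance(docked, self.LOOP_A, self.LOOP_B)
        separations = [d0, 20.0, 27.0, 34.0]
        models = build_undocking_series(separations)
        table, _ = annotate_trajectory(models, self.LOOP_A, self.LOOP_B)
        wc = list(table["wc_inter"])
        assert all(a >= b for a, b in zip(wc, wc[1:]))
        assert wc[0] == 2
        assert wc[-1] == 0


class TestCalibrateWcModel:
    def test_identical_examples_give_epsilon_identity(self):
        r0 = np.array([5.5, 0.1, -0.2])
        model = calibrate_wc_model([RelativePosition(r0)] * 10)
        assert np.allclose(model.mu, r0)
        assert np.allclose(model.sigma, 1e-6 * np.eye(3))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        mu0 = np.array([5.6, 0.0, 0.0])
        sigma0 = np.diag([0.04, 0.09, 0.02])
        draws = rng.multivariate_normal(mu0, sigma0, size=10_000)
        model = calibrate_wc_model([RelativePosition(d) for d in draws])
        se = np.sqrt(np.diag(sigma0) / len(draws))
        assert np.all(np.abs(model.mu - mu0) < 3 * se)

    def test_held_out_draws_score_above_threshold(self):
        rng = np.random.default_rng(4242)
        mu0 = np.array([5.6, 0.0, 0.0])
        sigma0 = np.diag([0.04, 0.09, 0.02])
        train = rng.multivariate_normal(mu0, sigma0, size=5_000)
        test = rng.multivariate_normal(mu0, sigma0, size=2_000)
        model = calibrate_wc_model([RelativePosition(d) for d in train])
        above = sum(
            wc_score(RelativePosition(d), RelativePosition(d), model)
            > model.threshold
            for d in test
        )
        assert above / len(test) >= 0.99

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            calibrate_wc_model([RelativePosition(np.zeros(3))] * 3)


class TestEmpiricalWcModel:
    def test_canonical_offsets_score_above_threshold(self):
        from ribopmf.base_annotation import _CANONICAL_WC_OFFSETS, empirical_wc_model

        model = empirical_wc_model()
        for r_jk, r_kj in _CANONICAL_WC_OFFSETS:
            score = wc_score(
                RelativePosition(np.asarray(r_jk)),
                RelativePosition(np.asarray(r_kj)),
                model,
            )
            assert score > model.threshold

    def test_perturbed_canonical_still_detected(self):
        from ribopmf.base_annotation import empirical_wc_model

        model = empirical_wc_model()
        # crystal-like spread: up to ~0.5 A displacement per component
        score = wc_score(
            RelativePosition(np.array([3.2, -4.5, 0.4])),
            RelativePosition(np.array([2.5, 5.2, -0.4])),
            model,
        )
        assert score > model.threshold

    def test_stack_and_distant_geometries_rejected(self):
        from ribopmf.base_annotation import empirical_wc_model

        model = empirical_wc_model()
        for vec in ([0.0, 0.0, 3.4], [9.0, 0.0, 0.0], [0.0, 4.0, 0.5]):
            r = RelativePosition(np.asarray(vec))
            assert wc_score(r, r, model) < model.threshold

    def test_deterministic(self):
        from ribopmf.base_annotation import empirical_wc_model

        a = empirical_wc_model()
        b = empirical_wc_model()
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.sigma, b.sigma)


class TestCriteriaYaml:
    def test_round_trip(self, tmp_path):
        crit = AnnotationCriteria(d_cutoff=2.0, literal_stack_z=True)
        path = tmp_path / "criteria.yaml"
        criteria_to_yaml(crit, path)
        loaded = criteria_from_yaml(path)
        assert loaded.d_cutoff == 2.0
        assert loaded.literal_stack_z is True
        assert np.allclose(loaded.wc_model.mu, crit.wc_model.mu)
        assert np.allclose(loaded.wc_model.sigma, crit.wc_model.sigma)
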