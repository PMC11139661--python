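import numpy as np
import pytest

from blastonet.errors import InvalidParameterError
from blastonet.meshes import contact_network
from blastonet.networks import (
    classify_arrangement_4cell,
    hickman_vector,
    mean_contacts,
    validate_hickman_vector,
)
from blastonet.stats import gardner_quality
from blastonet.synthetic import (
    ArrangementSpec,
    LogisticOutcomeModel,
    TwoGroupOutcomeModel,
    analytic_contact_network,
    generate_arrangement,
    icosphere,
    pack_spheres,
    sample_gardner_grades,
    simulate_outcomes,
)

from conftest import CANONICAL


class TestIcosphere:
    def test_closed_and_valid(self):
        icosphere(1.0, (0, 0, 0), 2).validate()

    def test_vertex_count_grows(self):
        assert len(icosphere(subdivisions=0).vertices) == 12
        assert len(icosphere(subdivisions=1).vertices) == 42
        assert len(icosphere(subdivisions=2).vertices) == 162

    def test_radius_and_center(self):
        m = icosphere(2.5, (1, 2, 3), 1)
        r = np.linalg.norm(m.vertices - np.array([1.0, 2.0, 3.0]), axis=1)
        assert np.allclose(r, 2.5, atol=1e-12)

    def test_bad_params(self):
        with pytest.raises(InvalidParameterError):
            icosphere(0.0)
        with pytest.raises(InvalidParameterError):
            icosphere(1.0, subdivisions=-1)


class TestGenerateArrangement:
    @pytest.mark.parametrize("name", list(CANONICAL))
    def test_ground_truth_vectors(self, name):
        vector, label, mc = CANONICAL[name]
        emb = generate_arrangement(ArrangementSpec(name=name))
        net = contact_network(emb)
        assert hickman_vector(net) == vector
        assert classify_arrangement_4cell(hickman_vector(net)) == label
        assert mean_contacts(net) == pytest.approx(mc)

    def test_mesh_pipeline_matches_analytic_graph(self):
        # jitter 0: mesh contact network equals the sphere contact graph
        from blastonet.synthetic import canonical_centers

        for name in CANONICAL:
            emb = generate_arrangement(ArrangementSpec(name=name))
            centers = canonical_centers(name)
            truth = analytic_contact_network(centers, np.ones(4))
            assert contact_network(emb).edges == truth.edges

    def test_determinism(self):
        spec = ArrangementSpec(name="planar", jitter_sd=0.05, seed=3)
        a = generate_arrangement(spec)
        b = generate_arrangement(spec)
        for ma, mb in zip(a.blastomeres, b.blastomeres):
            assert np.array_equal(ma.vertices, mb.vertices)

    def test_unknown_name(self):
        with pytest.raises(InvalidParameterError):
            generate_arrangement(ArrangementSpec(name="dodecahedral"))

    def test_named_arrangement_needs_4_cells(self):
        with pytest.raises(InvalidParameterError):
            generate_arrangement(ArrangementSpec(name="linear", n_cells=5))

    def test_packed_8cell(self):
        emb = generate_arrangement(
            ArrangementSpec(name="packed_n8", n_cells=8, seed=2)
        )
        assert emb.stage == 8
        net = contact_network(emb)
        assert 2.0 <= mean_contacts(net) <= 6.0

    def test_bad_spec_params(self):
        with pytest.raises(InvalidParameterError):
            ArrangementSpec(name="planar", radius_mean=-1.0)
        with pytest.raises(InvalidParameterError):
            ArrangementSpec(name="planar", jitter_sd=-0.1)


class TestPackSpheres:
    def test_two_spheres_tangent(self):
        centers = pack_spheres(2, [1.0, 1.0], seed=1)
        d = np.linalg.norm(centers[0] - centers[1])
        assert d == pytest.approx(2.0, abs=1e-4)

    def test_no_overlap_and_connected(self):
        radii = np.ones(8)
        centers = pack_spheres(8, radii, seed=7)
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert (d > 2.0 - 1e-5).all()
        net = analytic_contact_network(centers, radii)
        assert len(net.edges) >= 7  # connected needs >= n-1 edges

    def test_eight_cell_property_over_seeds(self):
        # graphical vectors with mean contacts in [2, 6]; 20 seeds keeps the
        # suite quick (the full 50-seed sweep behaves identically)
        for seed in range(20):
            centers = pack_spheres(8, np.ones(8), seed=seed)
            net = analytic_contact_network(centers, np.ones(8))
            validate_hickman_vector(hickman_vector(net))
            assert 2.0 <= mean_contacts(net) <= 6.0

    def test_four_cell_compactness_rate(self):
        # regression fixture: relaxation of 4 equal spheres reached a
        # tetrahedral/pseudotetrahedral cluster in 20/20 of seeds 1..20
        good = 0
        for seed in range(1, 21):
            centers = pack_spheres(4, np.ones(4), seed=seed)
            label = classify_arrangement_4cell(
                hickman_vector(analytic_contact_network(centers, np.ones(4)))
            )
            good += label in ("Tetrahedral", "Pseudotetrahedral")
        assert good / 20 >= 0.80

    def test_determinism(self):
        a = pack_spheres(6, np.ones(6), seed=11)
        b = pack_spheres(6, np.ones(6), seed=11)
        assert np.array_equal(a, b)

    def test_bad_args(self):
        with pytest.raises(InvalidParameterError):
            pack_spheres(1, [1.0], seed=0)
        with pytest.raises(InvalidParameterError):
            pack_spheres(3, [1.0, -1.0, 1.0], seed=0)


class TestSimulateOutcomes:
    def test_zero_slope_rate_matches_intercept(self):
        x = np.linspace(0, 3, 5000)
        _, labels = simulate_outcomes(
            LogisticOutcomeModel(intercept=0.5, slope=0.0), x, seed=0
        )
        expected = 1.0 / (1.0 + np.exp(-0.5))
        assert labels.mean() == pytest.approx(expected, abs=0.02)

    def test_steep_slope_approaches_step(self):
        x = np.linspace(-1, 1, 400)
        _, labels = simulate_outcomes(
            LogisticOutcomeModel(intercept=0.0, slope=1e6), x, seed=0
        )
        assert np.array_equal(labels, (x > 0).astype(int))

    def test_two_group_moments_converge(self):
        model = TwoGroupOutcomeModel(3.3, 0.5, 10_000, 2.9, 0.6, 10_000)
        values, labels = simulate_outcomes(model, seed=4)
        pos, neg = values[labels == 1], values[labels == 0]
        assert abs(pos.mean() - 3.3) < 3 * 0.5 / np.sqrt(10_000)
        assert abs(neg.mean() - 2.9) < 3 * 0.6 / np.sqrt(10_000)
        assert pos.std(ddof=1) == pytest.approx(0.5, abs=0.02)

    def test_truncation_respected(self):
        model = TwoGroupOutcomeModel(2.8, 1.0, 2000, 2.0, 1.0, 2000, truncate=(0.0, 3.0))
        values, _ = simulate_outcomes(model, seed=2)
        assert values.min() >= 0.0 and values.max() <= 3.0

    def test_published_pregnancy_power(self):
        # Monte-Carlo power of the pooled t-test at the published t8
        # pregnancy parameterization (3.32+-0.56 n=59 vs 2.87+-0.63 n=21):
        # rejections at alpha=0.05 happen in well over 80% of replicates
        # (observed ~0.85 over 1000 draws)
        from blastonet.stats import pooled_t_test

        model = TwoGroupOutcomeModel(3.32, 0.56, 59, 2.87, 0.63, 21)
        reject = 0
        reps = 1000
        for seed in range(reps):
            values, labels = simulate_outcomes(model, seed=seed)
            res = pooled_t_test(values[labels == 1], values[labels == 0])
            reject += res.p_value < 0.05
        assert reject / reps >= 0.80

    def test_logistic_requires_biomarker(self):
        with pytest.raises(InvalidParameterError):
            simulate_outcomes(LogisticOutcomeModel(0.0, 1.0), None, seed=0)

    def test_two_group_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            TwoGroupOutcomeModel(3.0, 0.0, 10, 2.0, 0.5, 10)
        with pytest.raises(InvalidParameterError):
            TwoGroupOutcomeModel(3.0, 0.5, 1, 2.0, 0.5, 10)

    def test_determinism(self):
        model = TwoGroupOutcomeModel(3.3, 0.5, 30, 2.9, 0.6, 20)
        a = simulate_outcomes(model, seed=8)
        b = simulate_outcomes(model, seed=8)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestGardnerSampling:
    def test_grades_parse_and_cover_both_classes(self):
        grades = sample_gardner_grades(200, p_good=0.5, seed=1)
        qualities = {gardner_quality(g) for g in grades}
        assert qualities == {"good", "poor"}

    def test_rate(self):
        grades = sample_gardner_grades(5000, p_good=0.7, seed=2)
        rate = np.mean([gardner_quality(g) == "good" for g in grades])
        assert rate == pytest.approx(0.7, abs=0.03)

    def test_bad_p(self):
        with pytest.raises(InvalidParameterError):
            sample_gardner_grades(10, p_good=1.5)
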