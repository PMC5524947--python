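import numpy as np
import pytest

from alignval.geometry import SymmetryGroup, euler_to_direction, geodesic_distance
from alignval.imageops import MatchSet
from alignval.scoring import (
    DegenerateReferenceError,
    ParticleScores,
    ValidationParams,
    accuracy_chi,
    accuracy_score,
    clusterability_alpha,
    noise_alpha_reference,
    noise_chi_reference,
    precision_score,
    prune,
    q_value,
    validate_particles,
)
from alignval.synthetic import simulate_dataset

from conftest import random_matchset


def brute_force_alpha(directions, weights, sym=None):
    """Literal double-loop over ordered pairs; the independent oracle."""
    num = den = 0.0
    xi = len(weights)
    for k in range(xi):
        for n in range(xi):
            if n == k:
                continue
            d = geodesic_distance(directions[n], directions[k], sym)
            num += weights[n] * weights[k] * d
            den += weights[n] * weights[k]
    return num / den


def brute_force_chi(p_hat, directions, weights, sym=None):
    num = den = 0.0
    for k in range(len(weights)):
        num += weights[k] * geodesic_distance(p_hat, directions[k], sym)
        den += weights[k]
    return num / den


class TestClusterability:
    def test_identical_directions_give_zero(self):
        d = np.tile(euler_to_direction(20, 60), (7, 1))
        ms = MatchSet(0, d, np.linspace(1, 0.5, 7), np.arange(7))
        assert clusterability_alpha(ms) == 0.0

    def test_two_orthogonal_unit_weights(self, c1):
        ms = MatchSet(0, np.array([[1.0, 0, 0], [0, 1.0, 0]]), np.ones(2), np.arange(2))
        assert np.isclose(clusterability_alpha(ms, c1), np.pi / 2, atol=1e-12)

    @pytest.mark.parametrize("label", ["C1", "C3"])
    def test_brute_force_oracle(self, label, rng):
        sym = SymmetryGroup(label)
        for _ in range(200):
            ms = random_matchset(rng, xi=int(rng.integers(3, 9)))
            assert np.isclose(
                clusterability_alpha(ms, sym),
                brute_force_alpha(ms.directions, ms.weights, sym),
                atol=1e-12,
            )

    def test_permutation_and_scale_invariance(self, c1, rng):
        ms = random_matchset(rng)
        a0 = clusterability_alpha(ms, c1)
        perm = rng.permutation(ms.xi)
        ms2 = MatchSet(0, ms.directions[perm], ms.weights[perm] * 17.3, np.arange(ms.xi))
        assert np.isclose(clusterability_alpha(ms2, c1), a0, atol=1e-12)

    def test_duplicating_central_match_never_increases_alpha(self, c1, rng):
        """Duplicating the most central entry (minimal weighted mean distance
        to the others) adds weight mass at zero distance and can only lower
        the statistic; its mean distance is below the overall weighted mean."""
        from alignval.geometry import geodesic_distance_matrix

        for _ in range(50):
            ms = random_matchset(rng)
            dmat = geodesic_distance_matrix(ms.directions, c1)
            w = ms.weights
            central = int(np.argmin((dmat * w).sum(1) / (w.sum() - w)))
            a0 = clusterability_alpha(ms, c1)
            dup = MatchSet(
                0,
                np.vstack([ms.directions, ms.directions[central]]),
                np.append(ms.weights, ms.weights[central]),
                np.arange(ms.xi + 1),
            )
            assert clusterability_alpha(dup, c1) <= a0 + 1e-12

    def test_doubling_every_entry_strictly_decreases_alpha(self, c1, rng):
        """Duplicating the whole set adds only zero-distance pairs, so the
        statistic must strictly decrease for any non-degenerate set."""
        for _ in range(20):
            ms = random_matchset(rng)
            dup = MatchSet(
                0,
                np.vstack([ms.directions, ms.directions]),
                np.append(ms.weights, ms.weights),
                np.arange(2 * ms.xi),
            )
            assert clusterability_alpha(dup, c1) < clusterability_alpha(ms, c1)

    def test_needs_two_matches(self):
        ms = MatchSet(0, np.array([[0, 0, 1.0]]), np.ones(1), np.zeros(1))
        with pytest.raises(ValueError):
            clusterability_alpha(ms)


class TestAccuracyChi:
    def test_zero_when_p_hat_matches_all(self, c1):
        p = euler_to_direction(45, 45)
        ms = MatchSet(0, np.tile(p, (7, 1)), np.ones(7), np.arange(7))
        assert accuracy_chi(p, ms, c1) < 1e-12

    def test_single_match_weight_cancels(self, c1):
        p = euler_to_direction(0, 0)
        q = euler_to_direction(0, 60)
        for w in (0.1, 1.0, 5.0):
            ms = MatchSet(0, q[None, :], np.array([w]), np.zeros(1))
            assert np.isclose(accuracy_chi(p, ms, c1), np.pi / 3, atol=1e-12)

    def test_brute_force_oracle(self, rng):
        sym = SymmetryGroup("C2")
        for _ in range(200):
            ms = random_matchset(rng)
            p = rng.standard_normal(3)
            p /= np.linalg.norm(p)
            assert np.isclose(
                accuracy_chi(p, ms, sym),
                brute_force_chi(p, ms.directions, ms.weights, sym),
                atol=1e-12,
            )


class TestNoiseReferences:
    def test_alpha_noise_near_half_pi_for_c1(self, c1):
        mean, samples = noise_alpha_reference(7, 500, c1, seed=11, return_samples=True)
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(mean - np.pi / 2) < 3 * se

    def test_chi_noise_near_half_pi_for_c1(self, c1):
        p = euler_to_direction(120, 75)
        mean, samples = noise_chi_reference(p, 7, 500, c1, seed=12, return_samples=True)
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(mean - np.pi / 2) < 3 * se
        assert 0 < mean < np.pi

    def test_seed_determinism(self, c1):
        p = euler_to_direction(10, 50)
        assert noise_alpha_reference(7, 50, c1, seed=5) == noise_alpha_reference(7, 50, c1, seed=5)
        assert noise_chi_reference(p, 7, 50, c1, seed=5) == noise_chi_reference(p, 7, 50, c1, seed=5)

    def test_symmetry_shrinks_alpha_noise(self, c1):
        c2 = SymmetryGroup("C2")
        wins = sum(
            noise_alpha_reference(7, 100, c2, seed=s) < noise_alpha_reference(7, 100, c1, seed=s)
            for s in range(20)
        )
        assert wins == 20


class TestScoreMappings:
    def test_endpoints(self):
        assert precision_score(1.5, 0.4, 1.5) == 0.0
        assert precision_score(0.4, 0.4, 1.5) == 1.0
        assert accuracy_score(1.5, 0.4, 1.5) == 0.0
        assert accuracy_score(0.4, 0.4, 1.5) == 1.0

    def test_midpoint(self):
        assert np.isclose(precision_score(0.95, 0.4, 1.5), 0.5, atol=1e-12)

    def test_matches_two_point_line_formula(self, rng):
        for _ in range(100):
            good, noise, x = rng.uniform(0.01, 3.0, 3)
            if abs(good - noise) < 1e-6:
                continue
            expected = (x - noise) / (good - noise)  # line through (noise,0),(good,1)
            assert np.isclose(accuracy_score(x, good, noise), expected, atol=1e-12)

    def test_exactly_linear(self, rng):
        good, noise = 0.3, 1.6
        a, b = rng.uniform(0, 3, 2)
        qa = precision_score(a, good, noise)
        qb = precision_score(b, good, noise)
        qm = precision_score((a + b) / 2, good, noise)
        assert np.isclose(qa + qb, 2 * qm, atol=1e-12)

    def test_unclamped(self):
        assert precision_score(0.1, 0.4, 1.5) > 1.0
        assert precision_score(1.9, 0.4, 1.5) < 0.0

    def test_degenerate_references(self):
        with pytest.raises(DegenerateReferenceError):
            precision_score(1.0, 1.0, 1.0 + 1e-12)


def _scores(pairs, flags=None):
    return [
        ParticleScores(index=i, q_p=p, q_a=a, flags=(flags or {}).get(i, ()))
        for i, (p, a) in enumerate(pairs)
    ]


class TestQValueAndPrune:
    def test_arithmetic(self):
        assert q_value(_scores([(1, 1)] * 4)) == 100.0
        assert q_value(_scores([(0, 0)] * 4)) == 0.0
        assert q_value(_scores([(1, 1), (1, 1), (1, 1), (0.2, 1)])) == 75.0

    def test_threshold_is_inclusive(self):
        assert q_value(_scores([(0.5, 0.5)])) == 100.0

    def test_flagged_particles_fail(self):
        scores = _scores([(1, 1), (1, 1)], flags={1: ("degenerate-reference",)})
        assert q_value(scores) == 50.0

    def test_monotone_in_tau(self, rng):
        scores = _scores([(rng.uniform(-0.2, 1.2), rng.uniform(-0.2, 1.2)) for _ in range(50)])
        qs = [q_value(scores, t) for t in np.linspace(-0.5, 1.5, 21)]
        assert (np.diff(qs) <= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q_value([])

    def test_prune_selection(self):
        from alignval.scoring import ReferenceStats, ValidationReport

        scores = _scores([(1, 1), (0.6, 0.4), (0.9, 0.8)])
        report = ValidationReport(
            scores=scores, Q=q_value(scores, 0.5), percent_precise=100.0,
            percent_accurate=2 / 3 * 100, mean_q_p=0.83, mean_q_a=0.73,
            references=ReferenceStats(1.5, 1.5, 10, 0), params=ValidationParams(),
        )
        kept = prune(report, 0.5)
        assert kept.tolist() == [0, 2]
        assert len(kept) / 3 * 100 == pytest.approx(report.Q)
        assert len(prune(report, -np.inf)) == 3
        assert len(prune(report, 1.01)) == 0
        assert set(prune(report, 0.9)) <= set(prune(report, 0.5))


class TestValidatePipeline:
    def test_precision_only_mode_contract(self, phantom32):
        ds = simulate_dataset(phantom32, 4, snr=np.inf, seed=2)

        class PrecisionRecord:
            orientation = None

            def __init__(self, ctf):
                self.ctf = ctf

        records = [PrecisionRecord(r.ctf) for r in ds.records]
        params = ValidationParams(delta=20, rot_step=20, M=50, seed=0, mode="precision")
        rep = validate_particles(phantom32, ds.images, records, params)
        assert all(s.q_p is not None for s in rep.scores)
        assert all(s.q_a is None for s in rep.scores)
        assert rep.percent_accurate is None

    def test_missing_orientation_in_full_mode(self, phantom32):
        ds = simulate_dataset(phantom32, 2, snr=np.inf, seed=2)
        ds.records[1].orientation = None
        with pytest.raises(ValueError, match="orientation"):
            validate_particles(phantom32, ds.images, ds.records, ValidationParams(delta=20, M=10))

    def test_box_mismatch_rejected(self, phantom32, phantom48):
        ds = simulate_dataset(phantom48, 2, snr=np.inf, seed=2)
        with pytest.raises(ValueError, match="box"):
            validate_particles(phantom32, ds.images, ds.records, ValidationParams(delta=20, M=10))

    def test_noiseless_particles_score_perfectly(self, phantom32):
        """Each noiseless particle equals its own perfect reference, so both
        scores are exactly 1 and Q = 100."""
        ds = simulate_dataset(phantom32, 6, snr=np.inf, seed=4)
        params = ValidationParams(delta=15, rot_step=15, M=100, seed=0)
        rep = validate_particles(phantom32, ds.images, ds.records, params)
        for s in rep.scores:
            assert np.isclose(s.q_p, 1.0, atol=1e-9)
            assert np.isclose(s.q_a, 1.0, atol=1e-9)
        assert rep.Q == 100.0

    def test_run_determinism(self, phantom32):
        ds = simulate_dataset(phantom32, 3, snr=1.0, seed=6)
        params = ValidationParams(delta=20, rot_step=20, M=50, seed=3)
        r1 = validate_particles(phantom32, ds.images, ds.records, params)
        r2 = validate_particles(phantom32, ds.images, ds.records, params)
        assert r1.to_dataframe().equals(r2.to_dataframe())
        assert r1.Q == r2.Q
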