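"""Sequential estimator: weights, selection, full runs vs the exact posterior."""

import math

import numpy as np
import pytest

from tdspool import (
    DataError,
    EngineConfig,
    PoolGenotype,
    SolutionStream,
    SufficientStatistics,
    enumerate_dataset,
    estimate_frequencies,
    extension_weight,
    prior_statistics,
    run_tds,
    select_streams,
    universe_from_solutions,
    update_statistics,
)
from conftest import make_dataset, universe_of
from oracles import exhaustive_posterior, posterior_mean_estimate


def stream(assignments=(), weight=1.0, rho=(1.0, 1.0, 1.0, 1.0)):
    return SolutionStream(
        assignments=tuple(assignments),
        log_weight=math.log(weight) if weight > 0 else -math.inf,
        stats=SufficientStatistics(np.array(rho, dtype=float)),
    )


class TestExtensionWeight:
    def test_uniform_prior_is_symmetric(self):
        uni = universe_of(["00", "01", "10", "11"])
        s = stream()
        for sol in [(0b00, 0b11), (0b01, 0b10), (0b00, 0b00)]:
            assert extension_weight(s, sol, uni) == pytest.approx(1 / 16)

    def test_seen_haplotypes_are_favoured(self):
        uni = universe_of(["00", "01", "10", "11"])
        s = stream(rho=(3.0, 1.0, 1.0, 1.0))
        assert extension_weight(s, (0b00, 0b00), uni) == pytest.approx(0.25)
        assert extension_weight(s, (0b01, 0b10), uni) == pytest.approx(1 / 36)

    def test_zero_weight_propagates(self):
        uni = universe_of(["00", "01", "10", "11"])
        s = stream(weight=0.0)
        assert extension_weight(s, (0b00, 0b11), uni) == 0.0

    def test_exact_predictive_uses_rising_factorials(self):
        uni = universe_of(["00", "01", "10", "11"])
        s = stream()
        # {z1, z1}: 1*2 / (4*5) vs product-of-means 1/16
        assert extension_weight(s, (0b00, 0b00), uni, exact_predictive=True) == (
            pytest.approx(2 / 20)
        )
        assert extension_weight(s, (0b00, 0b11), uni, exact_predictive=True) == (
            pytest.approx(1 / 20)
        )


class TestUpdateStatistics:
    def test_count_increments(self):
        uni = universe_of(["00", "01", "10", "11"])
        stats = SufficientStatistics(np.ones(4))
        up = update_statistics(stats, (0b00, 0b00), uni)
        assert list(up.rho) == [3.0, 1.0, 1.0, 1.0]
        up2 = update_statistics(stats, (0b01, 0b11), uni)
        assert list(up2.rho) == [1.0, 2.0, 1.0, 2.0]
        assert up2.total == stats.total + 2


class TestSelectStreams:
    def test_top_k_renormalized(self):
        cands = [
            stream(assignments=((0, 1),), weight=0.5),
            stream(assignments=((0, 2),), weight=0.3),
            stream(assignments=((1, 2),), weight=0.2),
        ]
        kept = select_streams(cands, 2)
        assert [s.assignments for s in kept] == [((0, 1),), ((0, 2),)]
        assert [s.weight for s in kept] == [pytest.approx(0.625), pytest.approx(0.375)]

    def test_duplicate_histories_merged(self):
        cands = [
            stream(assignments=((0, 1),), weight=0.3),
            stream(assignments=((0, 1),), weight=0.3),
            stream(assignments=((0, 2),), weight=0.2),
            stream(assignments=((0, 2),), weight=0.2),
            stream(assignments=((1, 2),), weight=0.1),
        ]
        assert len(select_streams(cands, 10)) == 3

    def test_equal_weights_tie_break_lexicographic(self):
        cands = [
            stream(assignments=((1, 2),), weight=0.5),
            stream(assignments=((0, 3),), weight=0.5),
        ]
        kept = select_streams(cands, 1)
        assert kept[0].assignments == ((0, 3),)
        assert kept[0].weight == pytest.approx(1.0)

    def test_all_zero_weights_is_an_error(self):
        from tdspool import InconsistentDataError

        with pytest.raises(InconsistentDataError):
            select_streams([stream(weight=0.0)], 1)


def run_on(dataset, config=None):
    config = config or EngineConfig()
    sols = enumerate_dataset(dataset)
    uni = universe_from_solutions(sols, dataset.n_loci)
    return run_tds(dataset.pools, sols, uni, config), uni, sols


class TestRunTds:
    def test_forced_single_solution_chain(self):
        # monomorphic pools leave exactly one stream carrying the data counts
        ds = make_dataset([(1, [2, 0]), (1, [2, 0]), (1, [0, 0])])
        streams, uni, _ = run_on(ds)
        assert len(streams) == 1
        assert streams[0].weight == pytest.approx(1.0)
        s = streams[0].stats
        prior = prior_statistics(EngineConfig(), uni)
        np.testing.assert_allclose(s.rho - prior.rho, [2.0, 4.0])  # 00 x2, 10 x4
        assert s.data_count == 6

    def test_two_heterozygous_pools_match_oracle(self):
        # frozen from tests/oracles.py: under the default 1/M prior the two
        # concordant histories carry 25/52 each, the discordant ones 1/52
        ds = make_dataset([(1, [1, 1]), (1, [1, 1])])
        streams, uni, sols = run_on(ds)
        assert len(streams) == 4
        by_hist = {s.assignments: s.weight for s in streams}
        s1, s2 = sols[0]  # (00,11) and (01,10)
        assert by_hist[(s1, s1)] == pytest.approx(25 / 52, abs=1e-12)
        assert by_hist[(s2, s2)] == pytest.approx(25 / 52, abs=1e-12)
        assert by_hist[(s1, s2)] == pytest.approx(1 / 52, abs=1e-12)
        assert by_hist[(s2, s1)] == pytest.approx(1 / 52, abs=1e-12)

    def test_two_heterozygous_pools_unit_prior(self):
        # same instance under a unit per-haplotype prior: 0.4 / 0.1
        ds = make_dataset([(1, [1, 1]), (1, [1, 1])])
        streams, _, sols = run_on(ds, EngineConfig(prior_rho=1.0))
        by_hist = {s.assignments: s.weight for s in streams}
        s1, s2 = sols[0]
        assert by_hist[(s1, s1)] == pytest.approx(0.4, abs=1e-12)
        assert by_hist[(s1, s2)] == pytest.approx(0.1, abs=1e-12)

    def test_weights_normalized_and_conserved(self, jain3):
        from tdspool import SimulationSpec, sample_pools

        spec = SimulationSpec(jain3, n_pools=30, pool_size=2, seed=5)
        ds, _, _ = sample_pools(spec)
        streams, uni, _ = run_on(ds)
        assert math.fsum(s.weight for s in streams) == pytest.approx(1.0, abs=1e-12)
        prior = prior_statistics(EngineConfig(), uni)
        for s in streams:
            assert s.stats.data_count == 30 * 4
            assert abs((s.stats.rho.sum() - prior.rho.sum()) - 120) < 1e-9

    def test_streams_consistent_with_all_pools(self, jain3):
        from tdspool import SimulationSpec, sample_pools

        spec = SimulationSpec(jain3, n_pools=25, pool_size=2, seed=9)
        ds, _, _ = sample_pools(spec)
        streams, _, _ = run_on(ds)
        for s in streams:
            for pool, sol in zip(ds.pools, s.assignments):
                assert pool.is_consistent(sol)

    @pytest.mark.parametrize("exact", [False, True])
    def test_exact_posterior_on_random_tiny_instances(self, exact):
        # with K exceeding the number of joint histories there is no
        # truncation, so stream weights must equal the enumerated posterior
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 30:
            T = rng.integers(1, 4)
            L = rng.integers(1, 4)
            N = int(rng.integers(1, 3))
            rows = []
            for _ in range(T):
                rows.append((N, list(rng.integers(0, 2 * N + 1, size=L))))
            ds = make_dataset(rows)
            sols = enumerate_dataset(ds)
            n_hist = math.prod(len(s) for s in sols)
            if n_hist > 200:
                continue
            uni = universe_from_solutions(sols, ds.n_loci)
            config = EngineConfig(n_streams=max(n_hist, 1), exact_predictive=exact)
            streams = run_tds(ds.pools, sols, uni, config)
            sols_str = [
                [
                    tuple(format(h, f"0{ds.n_loci}b") for h in sol)
                    for sol in pool_sols
                ]
                for pool_sols in sols
            ]
            uni_str = [format(h, f"0{ds.n_loci}b") for h in uni.haplotypes]
            prior = {h: 1.0 / len(uni) for h in uni_str}
            oracle = exhaustive_posterior(sols_str, uni_str, prior, exact)
            got = {
                tuple(sols[t].index(sol) for t, sol in enumerate(s.assignments)):
                s.weight
                for s in streams
            }
            assert len(got) == len(oracle)
            for hist, w in oracle.items():
                assert got[hist] == pytest.approx(w, abs=1e-10)
            checked += 1

    def test_empty_solution_set_raises(self):
        from tdspool import InconsistentDataError

        ds = make_dataset([(1, [1])])
        uni = universe_of(["0", "1"])
        with pytest.raises(InconsistentDataError, match="no consistent"):
            run_tds(ds.pools, [[]], uni, EngineConfig())


class TestEstimateFrequencies:
    def test_single_stream_dirichlet_mean(self):
        uni = universe_of(["00", "01", "10", "11"])
        s = stream(weight=1.0, rho=(3.0, 1.0, 1.0, 1.0))
        est = estimate_frequencies([s], uni)
        assert est[0b00] == pytest.approx(0.5)
        assert est[0b01] == pytest.approx(1 / 6)

    def test_weighted_average_of_streams(self):
        uni = universe_of(["0", "1"])
        a = stream(weight=0.75, rho=(1e9, 1e-9))
        b = stream(weight=0.25, rho=(1e-9, 1e9))
        est = estimate_frequencies([a, b], uni)
        assert est[0] == pytest.approx(0.75, abs=1e-6)
        assert est[1] == pytest.approx(0.25, abs=1e-6)

    def test_empty_streams_error(self):
        with pytest.raises(DataError):
            estimate_frequencies([], universe_of(["0", "1"]))

    def test_matches_oracle_posterior_mean(self):
        ds = make_dataset([(1, [1, 1]), (1, [0, 1]), (1, [1, 2])])
        sols = enumerate_dataset(ds)
        uni = universe_from_solutions(sols, 2)
        streams = run_tds(ds.pools, sols, uni, EngineConfig(n_streams=1000))
        est = estimate_frequencies(streams, uni)
        sols_str = [
            [tuple(format(h, "02b") for h in sol) for sol in ps] for ps in sols
        ]
        uni_str = [format(h, "02b") for h in uni.haplotypes]
        oracle = posterior_mean_estimate(
            sols_str, uni_str, {h: 1.0 / len(uni) for h in uni_str}
        )
        for h_str, v in oracle.items():
            assert est[int(h_str, 2)] == pytest.approx(v, abs=1e-10)
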