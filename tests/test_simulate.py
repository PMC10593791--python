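import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meioxo.ftl import i3bc_interference, seed_cm
from meioxo.genome import (
    GenomeModel,
    PathwayParams,
    PiecewiseTrack,
    boundary_stimulation_response,
    density_suppression_response,
    neutral_response,
)
from meioxo.presets import flat_pathway, two_chromosome_genome
from meioxo.simulate import (
    POLLEN_8CLASS_KEYS,
    build_intensity_profiles,
    coc_from_gametes,
    pollen_class_probabilities,
    seed_class_probabilities,
    simulate_f2_population,
    simulate_gamete,
    simulate_gbs,
    simulate_pollen_counts,
    simulate_seed_counts,
)


def uniform_model(length=10_000_000, density=4.0, het=None):
    het = het if het is not None else [(0, length)]
    return GenomeModel(
        chromosomes=(("chr1", length),),
        centromeres={"chr1": length // 2},
        snp_density={"chr1": PiecewiseTrack.constant(length, density)},
        het_blocks={"chr1": het},
    )


class TestIntensityProfiles:
    def test_neutral_responses_give_constant_base_rates(self):
        model = uniform_model()
        params = PathwayParams(
            classI_base_cM_per_Mb=2.0,
            classII_base_cM_per_Mb=1.0,
            classI_poly_response=neutral_response,
            classII_poly_response=lambda d: 1.0,
        )
        prof = build_intensity_profiles(model, params)
        assert np.allclose(prof.classI["chr1"].values, 2.0)
        assert np.allclose(prof.classII["chr1"].values, 1.0)
        cmI, cmII = prof.total_cM("chr1")
        assert cmI == pytest.approx(20.0)
        assert cmII == pytest.approx(10.0)

    def test_density_response_evaluated_pointwise(self):
        # 1/(1+d) at d=4 SNPs/kb scales Class II to 0.2 x base
        model = uniform_model(density=4.0)
        params = PathwayParams(
            classII_base_cM_per_Mb=1.0,
            classII_poly_response=density_suppression_response(1.0),
            classI_poly_response=neutral_response,
        )
        prof = build_intensity_profiles(model, params)
        assert np.allclose(prof.classII["chr1"].values, 0.2)

    def test_boundary_stimulation_peaks_at_het_hom_junction(self):
        # step density 0 -> 8 SNPs/kb at 10 Mb, het block ends at 10 Mb:
        # Class I must show a local maximum inside the boundary window,
        # matching a direct pointwise evaluation of the response
        length = 20_000_000
        model = GenomeModel(
            chromosomes=(("chr1", length),),
            centromeres={"chr1": length // 2},
            snp_density={"chr1": PiecewiseTrack([0, 10_000_000, length], [8.0, 0.0])},
            het_blocks={"chr1": [(0, 10_000_000)]},
        )
        A, L = 1.0, 300_000.0
        params = PathwayParams(
            classI_base_cM_per_Mb=2.0,
            classI_poly_response=boundary_stimulation_response(A, L),
        )
        prof = build_intensity_profiles(model, params)
        track = prof.classI["chr1"]
        mids = 0.5 * (track.edges[:-1] + track.edges[1:])
        het = mids < 10_000_000
        # oracle: direct evaluation of base * (1 + A exp(-dist/L)) at midpoints
        dist = np.abs(mids[het] - 10_000_000)
        oracle = 2.0 * (1.0 + A * np.exp(-dist / L))
        np.testing.assert_allclose(track.values[het], oracle, rtol=1e-12)
        peak = mids[np.argmax(track.values)]
        assert 10_000_000 - 2 * L <= peak <= 10_000_000

    def test_invalid_response_spec_is_a_configuration_error(self):
        model = uniform_model()
        params = PathwayParams(classI_poly_response="not callable")
        with pytest.raises(ValueError):
            build_intensity_profiles(model, params)


class TestSimulateGamete:
    def test_zero_intensity_never_produces_events(self, rng):
        zero = PiecewiseTrack.constant(1_000_000, 0.0)
        for _ in range(50):
            pos, cls = simulate_gamete(zero, zero, 1.0, rng)
            assert pos.size == 0 and cls.size == 0

    def test_poisson_limit_moments(self, rng):
        # nu = 1, 20 cM map: crossover count ~ Poisson(0.2)
        track = PiecewiseTrack.constant(20_000_000, 1.0)
        zero = PiecewiseTrack.constant(20_000_000, 0.0)
        counts = np.array(
            [simulate_gamete(track, zero, 1.0, rng)[0].size for _ in range(10_000)]
        )
        se_mean = np.sqrt(0.2 / counts.size)
        assert abs(counts.mean() - 0.2) < 3 * se_mean
        # index of dispersion ~ 1 under Poisson; null band via chi2 approx
        dispersion = counts.var(ddof=1) / counts.mean()
        assert abs(dispersion - 1.0) < 4 / np.sqrt(counts.size / 2)

    def test_positions_sorted_and_inside_chromosome(self, rng):
        track = PiecewiseTrack.constant(5_000_000, 20.0)
        for _ in range(100):
            pos, _ = simulate_gamete(track, track, 3.0, rng)
            assert np.all(np.diff(pos) >= 0)
            if pos.size:
                assert pos[0] >= 0 and pos[-1] <= 5_000_000

    def test_negative_intensity_rejected(self, rng):
        bad = PiecewiseTrack([0, 100], [1.0])
        bad.values[0] = -1.0
        with pytest.raises(ValueError):
            simulate_gamete(bad, bad, 1.0, rng)

    def test_obligate_crossover_guarantees_an_event(self, rng):
        # tiny 1 cM map: without the obligate flag most gametes are empty
        track = PiecewiseTrack.constant(1_000_000, 1.0)
        zero = PiecewiseTrack.constant(1_000_000, 0.0)
        # bivalent-level obligate CO still leaves ~half the gametes empty
        # after chromatid thinning, so check at the population level instead:
        counts = [
            simulate_gamete(track, zero, 1.0, rng, obligate_CO=True)[0].size
            for _ in range(2000)
        ]
        assert np.mean(counts) > 0.4  # ~0.5 expected; far above the 0.01 unconditional mean


class TestInterferenceReadout:
    def test_no_interference_gives_unit_coc(self, rng):
        # two adjacent 10 cM intervals on a 30 cM chromosome, nu = 1
        length = 20_000_000
        track = PiecewiseTrack.constant(length, 1.5)
        zero = PiecewiseTrack.constant(length, 0.0)
        third = length / 3
        gametes = [simulate_gamete(track, zero, 1.0, rng)[0] for _ in range(30_000)]
        coc, d_b, d_c, n = coc_from_gametes(gametes, (0, third), (third, 2 * third))
        # MC error on CoC ~ 1/sqrt(n_dco expected) ~ 0.06 at these sizes
        assert coc == pytest.approx(1.0, abs=0.2)
        assert d_b == pytest.approx(9.06, abs=1.0)  # r = (1 - exp(-0.2))/2 for 10 cM

    def test_strong_interference_suppresses_coc(self, rng):
        length = 20_000_000
        track = PiecewiseTrack.constant(length, 1.5)
        zero = PiecewiseTrack.constant(length, 0.0)
        third = length / 3
        gametes = [simulate_gamete(track, zero, 10.0, rng)[0] for _ in range(15_000)]
        coc, *_ = coc_from_gametes(gametes, (0, third), (third, 2 * third))
        assert coc < 1.0


class TestF2Population:
    def test_zero_intensity_individual_is_fully_parental(self, rng):
        model = uniform_model()
        params = flat_pathway(classI=0.0, classII=0.0)
        (ind,) = simulate_f2_population(model, params, 1, rng)
        assert ind.n_crossovers == 0
        segs = ind.segments["chr1"]
        assert len(segs) == 1
        assert segs[0][2] in {"AA", "AB", "BB"}

    def test_mean_crossovers_match_map_length(self, rng):
        # two 20 Mb chromosomes at 10 cM/Mb = 400 cM total: E[CO per F2] = 8
        model = two_chromosome_genome((20_000_000, 20_000_000))
        params = flat_pathway(classI=10.0, classII=0.0, nu=1.0)
        pop = simulate_f2_population(model, params, 500, rng)
        counts = np.array([ind.n_crossovers for ind in pop])
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 8.0) < 3 * se

    def test_segment_boundaries_conserve_crossovers(self, rng):
        model = two_chromosome_genome()
        params = flat_pathway(classI=5.0, classII=2.0)
        pop = simulate_f2_population(model, params, 30, rng)
        for ind in pop:
            boundaries = sum(len(ind.segments[c]) - 1 for c in ind.segments)
            # coincident breakpoints from the two gametes are measure-zero
            assert boundaries == ind.n_crossovers

    def test_population_is_reproducible_under_a_fixed_seed(self):
        model = two_chromosome_genome()
        params = flat_pathway()
        pop1 = simulate_f2_population(model, params, 10, np.random.default_rng(42))
        pop2 = simulate_f2_population(model, params, 10, np.random.default_rng(42))
        for a, b in zip(pop1, pop2):
            for chrom in a.gametes:
                for g1, g2 in zip(a.gametes[chrom], b.gametes[chrom]):
                    np.testing.assert_array_equal(g1.positions, g2.positions)
                    assert g1.start_phase == g2.start_phase


class TestSimulateGBS:
    def test_pure_parental_segments_report_no_alt_reads(self, rng):
        model = uniform_model()
        params = flat_pathway(classI=0.0, classII=0.0)
        pop = simulate_f2_population(model, params, 5, rng)
        table = simulate_gbs(
            pop, model, mean_coverage=20.0, error_rate=0.0, sites_per_Mb=20, rng=rng
        )
        for ind in pop:
            sub = table.df[table.df["individual"] == ind.id]
            geno = ind.genotype_at("chr1", int(sub["pos"].iloc[0]) - 1)
            if geno == "AA":
                assert (sub["alt_count"] == 0).all()
            elif geno == "BB":
                assert (sub["ref_count"] == 0).all()

    def test_mean_depth_matches_poisson_rate(self, rng):
        model = uniform_model(length=20_000_000, density=4.0)
        params = flat_pathway(classI=0.0, classII=0.0)
        pop = simulate_f2_population(model, params, 3, rng)
        table = simulate_gbs(
            pop, model, mean_coverage=3.0, error_rate=0.0, sites_per_Mb=500,
            rng=rng, coverage_shape=1e9,
        )
        depth = (table.df["ref_count"] + table.df["alt_count"]).to_numpy()
        se = np.sqrt(3.0 / depth.size)
        assert abs(depth.mean() - 3.0) < 3 * se

    def test_no_markers_inside_homozygous_blocks(self, rng):
        model = uniform_model(het=[(0, 3_000_000), (7_000_000, 10_000_000)])
        params = flat_pathway()
        pop = simulate_f2_population(model, params, 2, rng)
        table = simulate_gbs(pop, model, rng=rng, sites_per_Mb=50)
        pos = table.df["pos"].to_numpy() - 1
        in_hom = (pos >= 3_000_000) & (pos < 7_000_000)
        assert in_hom.sum() == 0

    def test_identical_seed_gives_identical_tables(self):
        model = uniform_model()
        params = flat_pathway()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            pop = simulate_f2_population(model, params, 3, rng)
            out.append(simulate_gbs(pop, model, rng=rng, sites_per_Mb=30).df)
        assert out[0].equals(out[1])

    def test_error_rate_bounds_enforced(self, rng):
        model = uniform_model()
        pop = simulate_f2_population(model, flat_pathway(), 1, rng)
        with pytest.raises(ValueError):
            simulate_gbs(pop, model, error_rate=0.6, rng=rng)
        with pytest.raises(ValueError):
            simulate_gbs(pop, model, mean_coverage=0.0, rng=rng)


def seed_probs_by_enumeration(r):
    """Brute-force oracle: enumerate the 4x4 gamete-pair table of a selfed
    coupling-phase hemizygous F1 (gametes GR, --, G-, -R)."""
    q = 1.0 - r
    gametes = {(1, 1): q / 2, (0, 0): q / 2, (1, 0): r / 2, (0, 1): r / 2}
    classes = {"green_only": 0.0, "red_only": 0.0, "both": 0.0, "neither": 0.0}
    for (g1, r1), p1 in gametes.items():
        for (g2, r2), p2 in gametes.items():
            has_g, has_r = g1 or g2, r1 or r2
            key = (
                "both" if has_g and has_r
                else "green_only" if has_g
                else "red_only" if has_r
                else "neither"
            )
            classes[key] += p1 * p2
    return classes


class TestSeedCounts:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.0, {"green_only": 0.0, "red_only": 0.0, "both": 0.75, "neither": 0.25}),
            (1.0, {"green_only": 0.25, "red_only": 0.25, "both": 0.5, "neither": 0.0}),
            (0.2, {"green_only": 0.09, "red_only": 0.09, "both": 0.66, "neither": 0.16}),
        ],
    )
    def test_class_probabilities_match_enumeration_oracle(self, r, expected):
        probs = seed_class_probabilities(r)
        oracle = seed_probs_by_enumeration(r)
        for key in expected:
            assert probs[key] == pytest.approx(expected[key])
            assert probs[key] == pytest.approx(oracle[key])

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, r):
        assert sum(seed_class_probabilities(r).values()) == pytest.approx(1.0)

    def test_draws_total_and_reject_invalid_r(self, rng):
        counts = simulate_seed_counts(0.15, 2500, rng)
        assert counts.n_total == 2500
        with pytest.raises(ValueError):
            simulate_seed_counts(1.2, 100, rng)

    def test_estimator_inverts_expectation_counts(self):
        # applying the seed estimator to exact expectation counts returns
        # 100 r to machine precision across the feasible range
        from meioxo.ftl import SeedCountSet

        for r in np.arange(0.0, 0.501, 0.05):
            p = seed_class_probabilities(r)
            n = 10**12  # large enough that integer rounding is negligible
            counts = SeedCountSet(
                int(p["green_only"] * n), int(p["red_only"] * n),
                int(p["both"] * n), int(p["neither"] * n),
            )
            assert seed_cm(counts).cM == pytest.approx(100 * r, abs=1e-6)


class TestPollenCounts:
    def test_zero_distances_populate_only_parental_classes(self, rng):
        counts = simulate_pollen_counts(0.0, 0.0, 1.0, 5000, rng)
        nonzero = {k for k, v in counts.counts.items() if v > 0}
        assert nonzero <= {"m1m2m3", "none"}

    def test_expectation_arithmetic_at_unit_coc(self):
        probs = pollen_class_probabilities(10.0, 10.0, 1.0)
        assert probs["m1m3"] + probs["m2"] == pytest.approx(0.01)
        assert probs["m1"] + probs["m2m3"] == pytest.approx(0.09)
        assert probs["m1m2"] + probs["m3"] == pytest.approx(0.09)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_draws_sum_to_n_total(self, rng):
        counts = simulate_pollen_counts(12.0, 15.0, 0.35, 30_000, rng)
        assert counts.n_total == 30_000
        assert set(counts.counts) == set(POLLEN_8CLASS_KEYS)

    def test_infeasible_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_pollen_counts(60.0, 60.0, 10.0, 100, rng)

    def test_interference_estimator_inverts_expectations(self):
        # i3bc estimator applied to exact expectation counts recovers
        # (d_b, d_c, coc) to machine precision on a feasible grid
        from meioxo.ftl import PollenClassCounts

        n = 10**9
        for d_b, d_c, coc in itertools.product((5.0, 12.0), (8.0, 15.0), (0.35, 1.0)):
            probs = pollen_class_probabilities(d_b, d_c, coc)
            counts = PollenClassCounts({k: int(round(v * n)) for k, v in probs.items()})
            est = i3bc_interference(counts)
            assert est.d_b == pytest.approx(d_b, abs=1e-6)
            assert est.d_c == pytest.approx(d_c, abs=1e-6)
            assert est.coc == pytest.approx(coc, abs=1e-6)
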