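"""Generator tests: pattern soundness, detectability, counts, determinism."""

import numpy as np
import pytest

from gaprepair.classify import MechanismCall, classify_event
from gaprepair.hdna import summarize_transfer
from gaprepair.simulate import (
    EventRecord,
    Mechanism,
    SimParams,
    TractLengthModel,
    TransformationSimParams,
    simulate_cohort,
    simulate_event,
    simulate_transformation_counts,
)

COVERING = TractLengthModel(mean_bp=400.0, min_bp=18)  # always reaches the anchored SNPs

EXPECTED_CLASS = {
    Mechanism.SDSA: MechanismCall.UNIDIRECTIONAL,
    Mechanism.DHJ_DISSOLUTION: MechanismCall.BIDIRECTIONAL,
    Mechanism.DOUBLE_SDSA: MechanismCall.BIDIRECTIONAL,
    Mechanism.HJ_CLEAVAGE_NCO: MechanismCall.CLEAVAGE_PATTERN,
    Mechanism.CONVERSION_ONLY: MechanismCall.CONVERSION_ONLY,
    Mechanism.NO_TRANSFER: MechanismCall.NO_TRANSFER,
}


def classify_record(event: EventRecord, snp_map) -> MechanismCall:
    plasmid, chrom = event.alleles(snp_map)
    return classify_event(summarize_transfer(plasmid, chrom, snp_map))


class TestTractLengthModel:
    def test_cdf_matches_direct_summation(self):
        model = TractLengthModel(mean_bp=150.0)
        p = 1.0 / 150.0
        for k in (1, 5, 17, 100):
            direct = sum(p * (1 - p) ** (j - 1) for j in range(1, k + 1))
            assert model.cdf(k) == pytest.approx(direct, abs=1e-12)

    def test_min_bp_shifts_support(self, rng):
        model = TractLengthModel(mean_bp=30.0, min_bp=18)
        draws = model.sample(rng, size=2000)
        assert draws.min() >= 19
        assert model.cdf(18) == 0.0

    def test_mean(self, rng):
        model = TractLengthModel(mean_bp=150.0)
        draws = model.sample(rng, size=200_000)
        assert np.mean(draws) == pytest.approx(150.0, rel=0.02)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TractLengthModel(mean_bp=10.0, min_bp=18)
        with pytest.raises(ValueError):
            TractLengthModel(min_bp=-1)


class TestSimulateEvent:
    @pytest.mark.parametrize("mechanism", sorted(EXPECTED_CLASS, key=lambda m: m.value))
    def test_pattern_soundness_with_covering_tracts(self, mechanism, default_map, rng):
        params = SimParams(tract_model=COVERING)
        for _ in range(200):
            event = simulate_event(mechanism, default_map, params, rng)
            assert classify_record(event, default_map) is EXPECTED_CLASS[mechanism]

    def test_sdsa_donor_untouched(self, default_map, rng):
        params = SimParams(tract_model=COVERING)
        for _ in range(100):
            e = simulate_event(Mechanism.SDSA, default_map, params, rng)
            assert set(e.chromosome_calls) <= {"R", "|"}
            assert "H" in e.plasmid_calls

    def test_cleavage_co_not_sequenced(self, default_map, rng):
        e = simulate_event(Mechanism.HJ_CLEAVAGE_CO, default_map, SimParams(), rng)
        assert e.stability_call == "CO"
        assert e.plasmid_calls == "" and e.chromosome_calls == ""

    def test_no_transfer_identity(self, default_map, rng):
        e = simulate_event(Mechanism.NO_TRANSFER, default_map, SimParams(), rng)
        assert e.stability_call == "NCO"
        assert set(e.plasmid_calls) == {"R", "|"} == set(e.chromosome_calls)
        assert classify_record(e, default_map) is MechanismCall.NO_TRANSFER

    def test_invalid_mechanism(self, default_map, rng):
        with pytest.raises(ValueError, match="mechanism"):
            simulate_event("SDSA-ish", default_map, SimParams(), rng)

    def test_undetectable_fraction_matches_cdf(self, default_map, rng):
        """Short-tract SDSA events leave no marker: their frequency must
        match P(tract < 18 bp) evaluated directly from the geometric CDF."""
        model = TractLengthModel(mean_bp=25.0)
        params = SimParams(tract_model=model)
        n = 10_000
        undetected = 0
        for _ in range(n):
            e = simulate_event(Mechanism.SDSA, default_map, params, rng)
            undetected += "H" not in e.plasmid_calls
        p = 1.0 / 25.0
        q = sum(p * (1 - p) ** (j - 1) for j in range(1, 18))  # independent CDF sum
        assert abs(undetected / n - q) <= 3 * np.sqrt(q * (1 - q) / n)

    def test_mmr_repair_prob_one_removes_all_hdna(self, default_map, rng):
        params = SimParams(tract_model=COVERING, mmr_repair_prob=1.0)
        for _ in range(50):
            e = simulate_event(Mechanism.SDSA, default_map, params, rng)
            assert "H" not in e.plasmid_calls


class TestSimulateCohort:
    def test_all_no_transfer(self, default_map):
        params = SimParams(mechanism_weights={Mechanism.NO_TRANSFER: 1.0}, n_events=50)
        cohort = simulate_cohort(params, default_map)
        assert len(cohort) == 50
        for e in cohort:
            assert set(e.plasmid_calls) == {"R", "|"} == set(e.chromosome_calls)

    def test_seed_determinism(self, default_map):
        params = SimParams(n_events=200, seed=7)
        assert simulate_cohort(params, default_map) == simulate_cohort(params, default_map)

    def test_different_seeds_differ(self, default_map):
        a = simulate_cohort(SimParams(n_events=200, seed=1), default_map)
        b = simulate_cohort(SimParams(n_events=200, seed=2), default_map)
        assert a != b

    def test_string_and_combined_weight_keys(self, default_map):
        params = SimParams(
            mechanism_weights={"SDSA": 0.5, "HJ_CLEAVAGE": 0.5},
            co_fraction_given_cleavage=1.0,
            n_events=100,
            seed=3,
        )
        cohort = simulate_cohort(params, default_map)
        mechanisms = {e.truth_mechanism for e in cohort}
        assert mechanisms <= {Mechanism.SDSA, Mechanism.HJ_CLEAVAGE_CO}
        assert any(e.stability_call == "CO" for e in cohort)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimParams(mechanism_weights={Mechanism.SDSA: 0.5}).resolved_weights()

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SimParams(
                mechanism_weights={Mechanism.SDSA: 1.5, Mechanism.NO_TRANSFER: -0.5}
            ).resolved_weights()

    def test_stability_iff_cleavage_co(self, default_map):
        params = SimParams(
            mechanism_weights={"SDSA": 0.4, "HJ_CLEAVAGE_CO": 0.3, "DHJ_DISSOLUTION": 0.3},
            n_events=300,
            seed=11,
        )
        for e in simulate_cohort(params, default_map):
            assert (e.stability_call == "CO") == (e.truth_mechanism is Mechanism.HJ_CLEAVAGE_CO)


class TestTransformationCounts:
    def test_mean_ratio_recovers_true_efficiency(self):
        params = TransformationSimParams(
            n_transformations=500, true_repair_efficiency=1.0, leu_mean=200.0,
            dispersion=0.1, seed=5,
        )
        records = simulate_transformation_counts(params)
        ratios = np.array([r.ratio for r in records])
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) <= 3 * se

    def test_zero_efficiency_means_zero_his(self):
        params = TransformationSimParams(
            n_transformations=36, true_repair_efficiency=0.0, seed=1
        )
        assert all(r.his_count == 0 for r in simulate_transformation_counts(params))

    def test_low_dispersion_limit_matches_delta_method_variance(self):
        """As dispersion -> 0 the culture factor degenerates and the ratio
        variance approaches the Poisson-sampling-only value
        eff(1+eff)/leu_mean (first-order delta method)."""
        eff, leu = 1.0, 500.0
        params = TransformationSimParams(
            n_transformations=40_000, true_repair_efficiency=eff, leu_mean=leu,
            dispersion=0.0, seed=9,
        )
        ratios = np.array([r.ratio for r in simulate_transformation_counts(params)])
        assert ratios.var(ddof=1) == pytest.approx(eff * (1 + eff) / leu, rel=0.05)

    def test_overdispersion_inflates_count_variance(self):
        base = dict(n_transformations=5000, true_repair_efficiency=1.0, leu_mean=200.0, seed=2)
        lo = simulate_transformation_counts(TransformationSimParams(dispersion=0.0, **base))
        hi = simulate_transformation_counts(TransformationSimParams(dispersion=0.5, **base))
        var_lo = np.var([r.leu_count for r in lo])
        var_hi = np.var([r.leu_count for r in hi])
        assert var_hi > 5 * var_lo

    def test_mix_id_attached(self):
        params = TransformationSimParams(n_transformations=3, mix_id=2, seed=0)
        assert all(r.mix_id == 2 for r in simulate_transformation_counts(params))
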