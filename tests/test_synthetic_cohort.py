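"""Simulator: closed-form VAFs, sampling noise, detection floor, survival
strata, single-cell draws, and end-to-end consistency with the classifier."""

from __future__ import annotations

import numpy as np
import pytest

from tp53allelic.classifier import classify_allelic
from tp53allelic.core_io import AllelicLabel, RunConfig
from tp53allelic.synthetic_cohort import (
    CellState,
    ClonalArchitecture,
    SimParams,
    STRATUM_BIALLELIC,
    STRATUM_MONO,
    STRATUM_WT,
    arch_compound_heterozygous,
    arch_cryptic_biallelic,
    arch_del17p_hemizygous,
    arch_heterozygous,
    arch_mosaic_two_clones,
    arch_upd_homozygous,
    arch_wild_type,
    call_del17p,
    compute_biallelic_fraction,
    expected_vaf,
    sample_bulk_vaf,
    sample_single_cells,
    sample_survival,
    simulate_cohort,
    truth_stratum,
)


class TestArchitectureTruth:
    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            CellState(total_copies=1, mutant_copies=(2,), fraction=0.5)
        with pytest.raises(ValueError):
            ClonalArchitecture(
                states=(CellState(2, (1,), 0.5),), n_mutations=1,
                truth_biallelic_fraction=0.0,
            )  # fractions do not sum to 1

    def test_stored_truth_must_match_states(self):
        states = (CellState(2, (2,), 0.3), CellState(2, (0,), 0.7))
        with pytest.raises(ValueError):
            ClonalArchitecture(states=states, n_mutations=1, truth_biallelic_fraction=0.1)
        arch = ClonalArchitecture.from_states(states, 1)
        assert arch.truth_biallelic_fraction == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "builder, kwargs, expected_biallelic",
        [
            (arch_heterozygous, dict(clone_fraction=0.8), 0.0),
            (arch_upd_homozygous, dict(clone_fraction=0.4), 0.4),
            (arch_compound_heterozygous, dict(clone_fraction=0.6), 0.6),
            (arch_del17p_hemizygous, dict(deleted_fraction=0.5), 0.5),
            (arch_mosaic_two_clones, dict(f1=0.2, f2=0.3), 0.0),
            (arch_cryptic_biallelic, dict(biallelic_fraction=0.06, het_fraction=0.04), 0.06),
        ],
    )
    def test_builders_have_declared_biallelic_truth(self, builder, kwargs, expected_biallelic):
        arch = builder(**kwargs)
        assert arch.truth_biallelic_fraction == pytest.approx(expected_biallelic)
        assert compute_biallelic_fraction(arch.states) == pytest.approx(expected_biallelic)


class TestExpectedVaf:
    def test_fully_clonal_heterozygous_is_half(self):
        assert expected_vaf(arch_heterozygous(1.0), 0) == pytest.approx(0.5)

    def test_half_hemizygous_is_one_third(self):
        # 50% cells with 1 mutant copy of 1, 50% WT diploid: 0.5 / 1.5
        assert expected_vaf(arch_del17p_hemizygous(0.5), 0) == pytest.approx(1 / 3)

    def test_cryptic_mixture_reproduces_eight_percent_bulk(self):
        # 6% UPD-homozygous + 4% heterozygous + 90% WT -> bulk VAF exactly 8%
        arch = arch_cryptic_biallelic(0.06, 0.04)
        assert expected_vaf(arch, 0) == pytest.approx(0.08, abs=1e-15)
        assert arch.truth_biallelic_fraction == pytest.approx(0.06)

    def test_bounds_and_degenerate_cases(self):
        assert expected_vaf(arch_upd_homozygous(1.0), 0) == 1.0
        assert expected_vaf(arch_heterozygous(0.0), 0) == 0.0
        all_deleted = ClonalArchitecture.from_states([CellState(0, (0,), 1.0)], 1)
        with pytest.raises(ValueError):
            expected_vaf(all_deleted, 0)
        with pytest.raises(IndexError):
            expected_vaf(arch_heterozygous(0.5), 1)


class TestBulkSampling:
    def test_huge_depth_concentrates_on_expectation(self, rng):
        arch = arch_heterozygous(1.0)
        obs = sample_bulk_vaf(arch, 0, depth=1_000_000, rng=rng)
        assert abs(obs - 0.5) < 0.002  # 3 sigma at depth 1e6 is ~0.0015

    def test_mean_and_variance_match_binomial_read_model(self, rng):
        arch = arch_cryptic_biallelic(0.06, 0.04)  # expectation 0.08
        draws = np.array([sample_bulk_vaf(arch, 0, 500, rng) for _ in range(10_000)])
        se = np.sqrt(0.08 * 0.92 / 500) / np.sqrt(10_000)
        assert abs(draws.mean() - 0.08) < 3 * se
        # Poisson depth inflates variance slightly above fixed-depth binomial
        binom_var = 0.08 * 0.92 / 500
        assert 0.8 * binom_var < draws.var() < 1.2 * binom_var

    def test_zero_expectation_always_observes_zero(self, rng):
        arch = arch_heterozygous(0.0)
        assert all(sample_bulk_vaf(arch, 0, 500, rng) == 0.0 for _ in range(50))


class TestDel17pCall:
    def test_subclonal_deletion_below_floor_is_cryptic(self, rng):
        called, clon = call_del17p(arch_del17p_hemizygous(0.10), 0.20, rng)
        assert called is False and clon is None

    def test_clonal_deletion_reported_with_noisy_clonality(self, rng):
        calls = [call_del17p(arch_del17p_hemizygous(0.60), 0.20, rng) for _ in range(200)]
        assert all(c[0] for c in calls)
        clons = np.array([c[1] for c in calls])
        assert abs(clons.mean() - 0.60) < 0.01
        assert np.all((clons >= 0.20) & (clons <= 1.0))

    def test_no_deletion_never_called(self, rng):
        assert call_del17p(arch_wild_type(), 0.20, rng) == (False, None)


class TestSurvival:
    def test_stratum_assignment(self):
        p = SimParams()
        assert truth_stratum(0.0, 0, p) == STRATUM_WT
        assert truth_stratum(0.0, 1, p) == STRATUM_MONO
        # a 6% biallelic subclone is already hazard-relevant
        assert truth_stratum(0.06, 1, p) == STRATUM_BIALLELIC
        assert truth_stratum(0.34, 2, p) == STRATUM_BIALLELIC
        assert truth_stratum(p.biallelic_hazard_threshold, 1, p) == STRATUM_MONO

    def test_wild_type_median_recovered(self):
        rng = np.random.default_rng(8)
        p = SimParams(censor_rate=0.0)
        draws = np.array(
            [sample_survival(0.0, p, rng, n_mutations=0)[0] for _ in range(10_000)]
        )
        assert abs(np.median(draws) - 42.0) / 42.0 < 0.05

    def test_biallelic_median_shorter_than_monoallelic(self):
        rng = np.random.default_rng(9)
        p = SimParams(censor_rate=0.0)
        bi = np.median([sample_survival(0.34, p, rng)[0] for _ in range(4000)])
        mono = np.median([sample_survival(0.0, p, rng)[0] for _ in range(4000)])
        assert abs(bi - 14.0) / 14.0 < 0.10
        assert abs(mono - 29.0) / 29.0 < 0.10

    def test_full_censoring(self):
        rng = np.random.default_rng(10)
        p = SimParams(censor_rate=1.0)
        assert not any(sample_survival(0.0, p, rng)[1] for _ in range(100))


class TestSingleCells:
    def test_biallelic_cell_share_recovered_without_dropout(self, rng):
        arch = arch_compound_heterozygous(0.32)
        draw = sample_single_cells(arch, n_cells=2000, ado_rate=0.0, rng=rng)
        share = draw.biallelic.mean()
        sd = np.sqrt(0.32 * 0.68 / 2000)
        assert abs(share - 0.32) < 3 * sd

    def test_total_dropout_hides_every_allele(self, rng):
        draw = sample_single_cells(arch_heterozygous(0.5), 100, ado_rate=1.0, rng=rng)
        assert (draw.obs_total == 0).all()
        assert (draw.obs_mutant == 0).all()

    def test_pre_dropout_matrix_reproduces_bulk_vaf(self, rng):
        for arch in (
            arch_heterozygous(0.6),
            arch_upd_homozygous(0.4),
            arch_del17p_hemizygous(0.5),
            arch_cryptic_biallelic(0.06, 0.04),
        ):
            draw = sample_single_cells(arch, 2000, ado_rate=0.3, rng=rng)
            bulk = draw.true_mutant[:, 0].sum() / draw.true_total.sum()
            p = expected_vaf(arch, 0)
            sd = np.sqrt(max(p * (1 - p), 1e-4) / (2 * 2000))
            assert abs(bulk - p) < 3 * sd

    def test_dropout_is_per_allele(self, rng):
        # het cells at ado 0.5: observed totals ~ Binomial(2, 0.5)
        draw = sample_single_cells(arch_heterozygous(1.0), 4000, ado_rate=0.5, rng=rng)
        frac_both_lost = (draw.obs_total == 0).mean()
        assert abs(frac_both_lost - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 4000)


class TestCohortAssembly:
    def test_empty_cohort(self):
        cohort, truth = simulate_cohort(SimParams(n_patients=0, seed=1))
        assert cohort == [] and truth.empty

    def test_same_seed_is_bit_identical(self):
        a_cohort, a_truth = simulate_cohort(SimParams(n_patients=120, seed=77))
        b_cohort, b_truth = simulate_cohort(SimParams(n_patients=120, seed=77))
        assert a_cohort == b_cohort
        assert a_truth.equals(b_truth)

    def test_observables_only_in_patient_records(self):
        cohort, truth = simulate_cohort(SimParams(n_patients=50, seed=3))
        assert not hasattr(cohort[0], "truth_biallelic_fraction")
        assert set(truth.columns) >= {"patient_id", "stratum", "biallelic_fraction", "n_true_hits"}

    def test_obligatory_calls_track_planted_dominant_share(self, default_config):
        cohort, truth = simulate_cohort(SimParams(n_patients=2000, seed=13))
        truth = truth.set_index("patient_id")
        mutated = [p for p in cohort if p.has_mutation]
        calls = [classify_allelic(p, default_config) for p in mutated]
        obligatory = np.mean([c.label is AllelicLabel.obligatory_biallelic for c in calls])
        fam = truth.loc[[p.patient_id for p in mutated], "family"]
        planted = fam.isin(["dominant_biallelic", "del17p_involving"]).mean()
        assert abs(obligatory - planted) <= 0.05

    def test_cryptic_patients_look_monoallelic_but_carry_high_hazard(self, default_config):
        # the discordance bulk sequencing cannot resolve, by construction
        cohort, truth = simulate_cohort(SimParams(n_patients=800, seed=21))
        truth = truth.set_index("patient_id")
        cryptic = [
            p
            for p in cohort
            if truth.loc[p.patient_id, "family"] == "cryptic_biallelic" and p.has_mutation
        ]
        assert len(cryptic) > 30
        labels = [classify_allelic(p, default_config).label for p in cryptic]
        mono_share = np.mean([l is AllelicLabel.probable_monoallelic for l in labels])
        assert mono_share > 0.8
        strata = truth.loc[[p.patient_id for p in cryptic], "stratum"]
        assert (strata == STRATUM_BIALLELIC).all()

    def test_detection_probability_monotone_in_biallelic_fraction(self, default_config):
        """P(biallelic-type label) is non-decreasing in the true biallelic
        cell fraction, over UPD architectures spanning the clone-size axis."""
        rng = np.random.default_rng(14)
        fracs = np.arange(0.05, 1.0, 0.1)
        probs = []
        for b in fracs:
            arch = arch_upd_homozygous(float(b))
            hits = 0
            n = 2000
            for _ in range(n):
                vaf = sample_bulk_vaf(arch, 0, 500, rng)
                p = arch_patient(vaf)
                label = classify_allelic(p, default_config).label
                hits += label in (
                    AllelicLabel.probable_biallelic,
                    AllelicLabel.obligatory_biallelic,
                )
            probs.append(hits / n)
        for lo, hi in zip(probs, probs[1:]):
            assert hi >= lo - 0.03  # Monte-Carlo slack at n=2000


def arch_patient(vaf: float):
    from .conftest import make_patient

    return make_patient(vafs=(min(vaf, 1.0),), with_cyto=False)
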