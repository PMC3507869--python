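"""Generator tests: band mapping, closed-form expectations, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from epimsap.dose_response import logistic_decline
from epimsap.synthetic_data import (
    DoseResponseSpec,
    PopulationSpec,
    TraitGroupParams,
    TraitSpec,
    build_population_pedigree,
    default_trait_spec,
    pedigree_counts,
    simulate_dose_response,
    simulate_msap_population,
    simulate_traits,
    study_cohort_spec,
    study_lines_metadata,
)


def _discordance(hpaii, mspi):
    """Fraction of cells where the two enzyme profiles disagree."""
    return float(
        (hpaii.values.to_numpy() != mspi.values.to_numpy()).mean()
    )


class TestMsapPopulation:
    def test_forced_band_patterns_by_state(self):
        """Pure-state populations produce exactly the band-mapping table."""
        cases = {
            # state_frequencies -> (hpaii band, mspi band) in control lines
            (1.0, 0.0, 0.0, 0.0): (1, 1),
            (0.0, 1.0, 0.0, 0.0): (0, 1),
            (0.0, 0.0, 1.0, 0.0): (0, 0),
            (0.0, 0.0, 0.0, 1.0): (0, 0),
        }
        for freqs, (h_band, m_band) in cases.items():
            spec = PopulationSpec(
                n_control_lines=2, n_treated_lines=2, n_samples_per_line=3,
                n_loci=20, state_frequencies=freqs, p_demeth=0.0,
                p_epi_noise=0.0, rng_seed=0,
            )
            hpaii, mspi, _ = simulate_msap_population(spec)
            assert (hpaii.values.to_numpy() == h_band).all()
            assert (mspi.values.to_numpy() == m_band).all()

    def test_full_demethylation_of_internal_cg_gives_identical_profiles(self):
        """CG-methylated loci + certain demethylation: treated lines carry
        both bands while controls stay HpaII-absent / MspI-present."""
        spec = PopulationSpec(
            n_control_lines=2, n_treated_lines=2, n_samples_per_line=3,
            n_loci=30, state_frequencies=(0.0, 1.0, 0.0, 0.0),
            p_demeth=1.0, p_epi_noise=0.0, rng_seed=0,
        )
        hpaii, mspi, lines = simulate_msap_population(spec)
        treated = lines[lines.treatment == "treated"].line_id
        for _, row in lines.iterrows():
            mask = hpaii.line_ids == row.line_id
            h = hpaii.values.loc[mask.to_numpy()]
            m = mspi.values.loc[mask.to_numpy()]
            if row.line_id in set(treated):
                assert (h.to_numpy() == 1).all() and (m.to_numpy() == 1).all()
            else:
                assert (h.to_numpy() == 0).all() and (m.to_numpy() == 1).all()
        assert lines.truly_hypomethylated.equals(
            lines.treatment.eq("treated")
        )

    def test_no_treatment_gives_statistically_identical_discordance(self):
        """p_demeth=0: treated and control discordance match the CG-state
        frequency within Monte-Carlo error (closed-form expectation)."""
        freq_cg = 0.3
        spec = PopulationSpec(
            n_control_lines=5, n_treated_lines=5, n_samples_per_line=4,
            n_loci=500, state_frequencies=(0.5, freq_cg, 0.1, 0.1),
            p_demeth=0.0, p_epi_noise=0.0, rng_seed=2,
        )
        hpaii, mspi, lines = simulate_msap_population(spec)
        for group in ("control", "treated"):
            ids = set(lines[lines.treatment == group].line_id)
            mask = hpaii.line_ids.isin(ids).to_numpy()
            disc = float(
                (hpaii.values.to_numpy()[mask]
                 != mspi.values.to_numpy()[mask]).mean()
            )
            # Discordance happens iff the latent state is internal-CG.
            se = np.sqrt(freq_cg * (1 - freq_cg) / (5 * 500))
            assert abs(disc - freq_cg) < 3 * se

    def test_discordance_monotone_in_demethylation_rate(self):
        """Treated-line HpaII/MspI discordance weakly decreases in p_demeth."""
        means = []
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = PopulationSpec(
                n_control_lines=2, n_treated_lines=6, n_samples_per_line=4,
                n_loci=400, p_demeth=p, p_epi_noise=0.0, rng_seed=7,
            )
            hpaii, mspi, lines = simulate_msap_population(spec)
            ids = set(lines[lines.treatment == "treated"].line_id)
            mask = hpaii.line_ids.isin(ids).to_numpy()
            means.append(
                float((hpaii.values.to_numpy()[mask]
                       != mspi.values.to_numpy()[mask]).mean())
            )
        assert all(a >= b - 0.01 for a, b in zip(means, means[1:]))
        assert means[-1] == 0.0

    def test_seeded_reproducibility_and_pairing(self):
        spec = study_cohort_spec(rng_seed=5, n_loci=60)
        h1, m1, l1 = simulate_msap_population(spec)
        h2, m2, l2 = simulate_msap_population(spec)
        pd.testing.assert_frame_equal(h1.values, h2.values)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(l1, l2)
        assert h1.sample_ids == m1.sample_ids
        assert h1.locus_ids == m1.locus_ids

    def test_invalid_state_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationSpec(state_frequencies=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="state_frequencies"):
            PopulationSpec(state_frequencies=(1.5, -0.5, 0.0, 0.0))
        with pytest.raises(ValueError, match="p_demeth"):
            PopulationSpec(p_demeth=1.5)


class TestDoseResponse:
    def test_control_dose_always_fully_responds(self):
        """y(0) = 100% exactly, so every control replicate is saturated."""
        tab = simulate_dose_response(DoseResponseSpec(rng_seed=1))
        ctrl = tab[tab.dose == 0]
        assert (ctrl.responders == ctrl.total).all()

    def test_high_dose_approaches_lower_asymptote(self):
        assert logistic_decline(1e9, 40.0, 3.0, 0.32) == pytest.approx(40.0, abs=1e-6)
        assert logistic_decline(0.0, 40.0, 3.0, 0.32) == 100.0

    def test_midpoint_mean_matches_binomial_expectation(self):
        """Empirical mean at dose m over 10,000 replicates ~ (100+A)/2."""
        spec = DoseResponseSpec(
            doses=(0.0, 0.32), reps_per_dose=10_000, n_per_rep=100,
            true_params={"A": 40.0, "b": 3.0, "m": 0.32}, rng_seed=3,
        )
        tab = simulate_dose_response(spec)
        at_m = tab[tab.dose == 0.32]
        mean_pct = 100.0 * at_m.responders.sum() / at_m.total.sum()
        p = 0.70
        se_pct = 100.0 * np.sqrt(p * (1 - p) / (100 * 10_000))
        assert abs(mean_pct - 70.0) < 3 * se_pct

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="include the 0"):
            DoseResponseSpec(doses=(0.1, 0.5))
        with pytest.raises(ValueError, match="lower asymptote"):
            DoseResponseSpec(true_params={"A": 150.0, "b": 1.0, "m": 0.3})


class TestTraits:
    def test_zero_latent_effect_decorrelates_fatty_acids(self):
        spec = default_trait_spec(rng_seed=4, latent_desaturation_effect=0.0)
        lines = study_lines_metadata(0, 200)
        table = simulate_traits(spec, lines)
        wide = (
            table.groupby(["line_id", "trait"])["value"].mean().unstack()
        )
        r = np.corrcoef(wide["erucic_pct"], wide["linoleic_pct"])[0, 1]
        # Null correlation bound: 3 / sqrt(n) for n = 200 lines.
        assert abs(r) < 3 / np.sqrt(200)

    def test_degenerate_variances_reproduce_group_means(self):
        g = TraitGroupParams
        spec = TraitSpec(
            traits={"oil_pct": {"control": g(48.9, 0.0, 0.0),
                                "treated": g(43.1, 0.0, 0.0)}},
            latent_loadings={}, n_samples_per_line=3, rng_seed=0,
        )
        lines = pd.DataFrame({
            "line_id": ["c1", "t1"], "treatment": ["control", "treated"],
        })
        table = simulate_traits(spec, lines)
        ctrl = table[table.treatment == "control"].value
        trt = table[table.treatment == "treated"].value
        assert (ctrl == 48.9).all() and (trt == 43.1).all()

    def test_infeasible_composition_rejected(self):
        g = TraitGroupParams
        with pytest.raises(ValueError, match="oil \\+ protein"):
            TraitSpec(
                traits={
                    "oil_pct": {"control": g(60.0, 0, 0), "treated": g(60.0, 0, 0)},
                    "protein_pct": {"control": g(45.0, 0, 0),
                                    "treated": g(45.0, 0, 0)},
                },
                latent_loadings={},
            )

    def test_erucic_linoleic_interval_covers_calibrated_target(self):
        """Fisher-z 95% band of the simulated r covers the -0.88 target."""
        from epimsap.trait_stats import trait_correlations

        spec = default_trait_spec(rng_seed=6)
        lines = study_lines_metadata(0, 100)
        table = simulate_traits(spec, lines)
        corr = trait_correlations(table, ["erucic_pct", "linoleic_pct"])
        lo = corr.ci_low.loc["erucic_pct", "linoleic_pct"]
        hi = corr.ci_high.loc["erucic_pct", "linoleic_pct"]
        assert lo < -0.88 < hi


class TestPedigree:
    def test_study_accession_and_plant_counts(self):
        ledger = build_population_pedigree(
            n_e1=473, siliques_per_plant=3, pooled_per_plant=1,
            seeds_sown_per_selected_line=10, n_selected_lines=100,
        )
        counts = pedigree_counts(ledger)
        assert counts["n_e1_plants"] == 473
        assert counts["n_e2_seed_accessions"] == 1892
        assert counts["n_e2_plants"] == 1000
        assert ledger.accession_id.is_unique

    def test_empty_and_invalid(self):
        assert build_population_pedigree(0).empty
        with pytest.raises(ValueError, match="non-negative"):
            build_population_pedigree(-1)
        with pytest.raises(ValueError, match="exceed"):
            build_population_pedigree(5, n_selected_lines=6)

    def test_per_plant_accession_arithmetic(self):
        ledger = build_population_pedigree(
            n_e1=7, siliques_per_plant=2, pooled_per_plant=2,
            seeds_sown_per_selected_line=3, n_selected_lines=4,
        )
        counts = pedigree_counts(ledger)
        assert counts["n_e2_seed_accessions"] == 7 * 4
        assert counts["n_e2_plants"] == 4 * 3
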