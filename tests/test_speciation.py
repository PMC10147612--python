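"""Equilibrium solver: trivial cases, oracle agreement, invariants, pFe."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferrispec import (
    ChelatorDefinition,
    MediumComposition,
    SpeciationState,
    TransferrinParameters,
    ValidationError,
    compute_pfe,
    effective_betas,
    solve_equilibrium,
    tf_fractions,
)

from oracles import species_chelator_free, species_tf_free

pool = st.floats(min_value=1e-9, max_value=1e-3)


class TestTrivialCases:
    def test_no_iron_leaves_everything_apo_and_free(self, deferiprone):
        comp = MediumComposition(
            tf_total=13e-6, fe_total=0.0, ligand_total=156e-6
        )
        s = solve_equilibrium(comp, chelator=deferiprone)
        assert s.tf0 == comp.tf_total
        assert s.free_ligand == comp.ligand_total
        assert s.free_fe == 0.0
        assert s.tf1 == s.tf2 == 0.0
        assert all(c == 0.0 for c in s.complexes)

    def test_ligand_without_chelator_definition_rejected(self):
        comp = MediumComposition(tf_total=1e-6, fe_total=1e-6, ligand_total=1e-6)
        with pytest.raises(ValidationError):
            solve_equilibrium(comp)

    def test_negative_pool_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            MediumComposition(tf_total=-1e-6, fe_total=0.0)


class TestOracleAgreement:
    @pytest.mark.parametrize(
        "tf_total, fe_total",
        [(1.3e-6, 2.6e-6), (13e-6, 9.68e-6), (1e-7, 1e-4), (1e-4, 1e-8)],
    )
    def test_chelator_free_matches_bisection_oracle(
        self, tf_params, tf_total, fe_total
    ):
        comp = MediumComposition(tf_total=tf_total, fe_total=fe_total)
        s = solve_equilibrium(comp, tf=tf_params)
        ref = species_chelator_free(fe_total, tf_total, tf_params.k1, tf_params.k2)
        for mine, theirs in [
            (s.free_fe, ref["free_fe"]),
            (s.tf0, ref["tf0"]),
            (s.tf1, ref["tf1"]),
            (s.tf2, ref["tf2"]),
        ]:
            assert mine == pytest.approx(theirs, rel=1e-6)

    @pytest.mark.parametrize(
        "fe_total, ligand_total", [(1e-6, 1e-5), (52e-6, 156e-6), (1e-4, 1e-6)]
    )
    def test_transferrin_free_matches_ligand_oracle(
        self, deferiprone, fe_total, ligand_total
    ):
        comp = MediumComposition(
            tf_total=0.0, fe_total=fe_total, ligand_total=ligand_total
        )
        s = solve_equilibrium(comp, chelator=deferiprone)
        ref = species_tf_free(
            fe_total, ligand_total, effective_betas(deferiprone, comp.ph)
        )
        assert s.free_fe == pytest.approx(ref["free_fe"], rel=1e-6)
        assert s.free_ligand == pytest.approx(ref["free_ligand"], rel=1e-6)
        for mine, theirs in zip(s.complexes, ref["complexes"]):
            assert mine == pytest.approx(theirs, rel=1e-6)

    def test_fractions_of_solved_state_match_oracle(self, tf_params):
        comp = MediumComposition(tf_total=1.3e-6, fe_total=2.6e-6)
        s = solve_equilibrium(comp, tf=tf_params)
        ref = species_chelator_free(2.6e-6, 1.3e-6, tf_params.k1, tf_params.k2)
        fa, fm, fh, sat = tf_fractions(s, comp.tf_total)
        assert fa == pytest.approx(ref["tf0"] / 1.3e-6, rel=1e-6)
        assert fm == pytest.approx(ref["tf1"] / 1.3e-6, rel=1e-6)
        assert fh == pytest.approx(ref["tf2"] / 1.3e-6, rel=1e-6)
        assert sat == pytest.approx(
            (ref["tf1"] + 2 * ref["tf2"]) / 2.6e-6, rel=1e-6
        )


class TestTfFractions:
    def test_fully_loaded_state(self):
        s = SpeciationState(
            free_fe=0, free_ligand=0, tf0=0, tf1=0, tf2=1e-6, complexes=()
        )
        assert tf_fractions(s, 1e-6) == pytest.approx((0, 0, 1, 1.0))

    def test_apo_only_state(self):
        s = SpeciationState(
            free_fe=0, free_ligand=0, tf0=1e-6, tf1=0, tf2=0, complexes=()
        )
        assert tf_fractions(s, 1e-6) == pytest.approx((1, 0, 0, 0.0))

    def test_zero_transferrin_raises_instead_of_nan(self):
        s = SpeciationState(
            free_fe=0, free_ligand=0, tf0=0, tf1=0, tf2=0, complexes=()
        )
        with pytest.raises(ValidationError):
            tf_fractions(s, 0.0)


class TestSolvedStateProperties:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(tf_total=pool, fe_total=pool, ligand_total=pool)
    def test_mass_balances_conserved(
        self, deferiprone, tf_total, fe_total, ligand_total
    ):
        comp = MediumComposition(
            tf_total=tf_total, fe_total=fe_total, ligand_total=ligand_total
        )
        s = solve_equilibrium(comp, chelator=deferiprone)
        assert s.fe_total == pytest.approx(fe_total, rel=1e-10)
        assert s.ligand_total == pytest.approx(ligand_total, rel=1e-10)
        assert s.tf_total == pytest.approx(tf_total, rel=1e-10)
        fa, fm, fh, _ = tf_fractions(s, tf_total)
        assert fa + fm + fh == pytest.approx(1.0, abs=1e-12)
        for conc in (s.free_fe, s.free_ligand, s.tf0, s.tf1, s.tf2, *s.complexes):
            assert conc >= 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(tf_total=pool, fe_total=pool, ligand_total=pool)
    def test_mass_action_laws_hold(
        self, tf_params, deferiprone, tf_total, fe_total, ligand_total
    ):
        comp = MediumComposition(
            tf_total=tf_total, fe_total=fe_total, ligand_total=ligand_total
        )
        s = solve_equilibrium(comp, tf=tf_params, chelator=deferiprone)
        if s.tf0 > 0 and s.free_fe > 0:
            assert s.tf1 == pytest.approx(
                tf_params.k1 * s.tf0 * s.free_fe, rel=1e-10
            )
            assert s.tf2 == pytest.approx(
                tf_params.k2 * s.tf1 * s.free_fe, rel=1e-10
            )
        betas = effective_betas(deferiprone, comp.ph)
        for i, c in enumerate(s.complexes):
            expected = 10 ** betas[i] * s.free_fe * s.free_ligand ** (i + 1)
            assert c == pytest.approx(expected, rel=1e-10)

    def test_holo_fraction_monotone_in_iron(self, deferiprone):
        holo = [
            solve_equilibrium(
                MediumComposition(
                    tf_total=13e-6, fe_total=fe, ligand_total=78e-6
                ),
                chelator=deferiprone,
            ).frac_holo
            for fe in (1e-6, 5e-6, 13e-6, 26e-6, 52e-6, 1e-4)
        ]
        assert holo == sorted(holo)

    def test_free_iron_monotone_decreasing_in_ligand(self, deferiprone):
        free = [
            solve_equilibrium(
                MediumComposition(
                    tf_total=1.3e-6, fe_total=26e-6, ligand_total=lig
                ),
                chelator=deferiprone,
            ).free_fe
            for lig in (1e-6, 1e-5, 1e-4, 1e-3)
        ]
        assert free == sorted(free, reverse=True)

    def test_repeated_solves_are_bit_identical(self, deferiprone):
        comp = MediumComposition(
            tf_total=1.3e-6, fe_total=54.6e-6, ligand_total=156e-6
        )
        a = solve_equilibrium(comp, chelator=deferiprone)
        b = solve_equilibrium(comp, chelator=deferiprone)
        assert a == b  # dataclass equality on every float field


class TestReloadEquilibrium:
    def test_deferiprone_excess_loads_most_apotransferrin(self, deferiprone):
        # 1000 ug/mL aTf with a twofold site excess of chelated iron:
        # nearly all transferrin acquires iron at equilibrium, split
        # between monoferric and diferric forms
        comp = MediumComposition(
            tf_total=13e-6, fe_total=52e-6, ligand_total=156e-6
        )
        s = solve_equilibrium(comp, chelator=deferiprone)
        assert s.frac_apo < 0.10
        assert s.frac_mono + s.frac_holo > 0.90
        assert s.tf_site_saturation > 0.5


class TestPfe:
    def test_non_binding_chelator_leaves_iron_free(self):
        weak = ChelatorDefinition(
            name="weak", n_max=1, log_beta=(0.0,), ligand_molar_mass=100.0
        )
        assert compute_pfe(weak) == pytest.approx(6.0, abs=1e-3)

    def test_uncorrected_deferiprone_matches_oracle(self, deferiprone):
        ref = species_tf_free(1e-6, 1e-5, list(deferiprone.log_beta))
        expected = -math.log10(ref["free_fe"])
        got = compute_pfe(deferiprone, protonation_correction=False)
        assert got == pytest.approx(expected, abs=1e-6)
        assert 27.0 < got < 29.0  # the raw constants imply pFe ~ 28

    def test_corrected_deferiprone_sits_below_transferrin(
        self, deferiprone, tf_params
    ):
        pfe_def = compute_pfe(deferiprone)
        pfe_tf = compute_pfe(tf_params)
        assert 19.0 < pfe_def < 22.0
        assert pfe_def < pfe_tf

    def test_correction_always_lowers_pfe(self, deferiprone):
        corrected = compute_pfe(deferiprone, protonation_correction=True)
        raw = compute_pfe(deferiprone, protonation_correction=False)
        assert corrected <= raw
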