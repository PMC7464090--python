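import numpy as np
import pytest

from ilscreen import (
    HOFMEISTER_ANION_ORDER,
    ILPair,
    Ion,
    IonLibrary,
    PeakSpec,
    ProfileSpec,
    ValidationError,
    anion_concordance,
    build_il_profile,
    chain_length_trend,
    generate_profile,
    rank_from_capacities,
    screen,
)
from ilscreen.screening import ScreeningResult

from oracles import kendall_tau_pairs

#: the five validated ILs with their reported log-capacities (ranking inputs)
REPORTED_LOG_CAPACITIES = {
    "[TMAm][Cl]": 25.83,
    "[EMIM][Cl]": 11.58,
    "[BMIM][Cl]": 7.37,
    "[EMPyr][Br]": 7.29,
    "[EMPyrro][Br]": 7.10,
}


def toy_library(n_cations=2, n_anions=2):
    cations = [
        Ion(f"[C{i}]+", f"cation {i}", +1, "imidazolium", alkyl_chain_length=2 * (i + 1))
        for i in range(n_cations)
    ]
    anions = [
        Ion(f"[A{i}]-", f"anion {i}", -1, "anion", anion_class="inorganic")
        for i in range(n_anions)
    ]
    return IonLibrary(cations=cations, anions=anions)


def dilution_family_library():
    """Cation family whose members differ only by added neutral tail surface
    (chain-length-diluted charge), against moderate acceptor anions."""
    cations = [
        Ion(f"[C{n}MIM]+", f"1-C{n} imidazolium", +1, "imidazolium",
            alkyl_chain_length=n)
        for n in (2, 4, 6, 8)
    ]
    anions = [
        Ion(f"[X{i}]-", f"acceptor {i}", -1, "anion", anion_class="inorganic")
        for i in range(3)
    ]
    profiles = {}
    for cation in cations:
        n = cation.alkyl_chain_length
        profiles[cation.abbreviation] = generate_profile(
            ProfileSpec(
                cation.abbreviation,
                (
                    PeakSpec(-0.007, 0.003, 45.0),
                    PeakSpec(0.0, 0.0035, 40.0 + 18.0 * n),
                ),
            )
        )
    for anion, center in zip(anions, (0.014, 0.016, 0.018)):
        profiles[anion.abbreviation] = generate_profile(
            ProfileSpec(anion.abbreviation, (PeakSpec(center, 0.003, 60.0),))
        )
    return IonLibrary(cations=cations, anions=anions), profiles


class TestBuildIlProfile:
    def test_ion_pair_area_additivity(self, library, ion_profiles):
        pair = ILPair(library.get("[EMIM]+"), library.get("[Cl]-"))
        solvent = build_il_profile(pair, ion_profiles)
        expected = (
            ion_profiles["[EMIM]+"].total_area + ion_profiles["[Cl]-"].total_area
        )
        assert solvent.total_area == pytest.approx(expected)

    def test_deterministic(self, library, ion_profiles):
        pair = ILPair(library.get("[BMIM]+"), library.get("[Br]-"))
        a = build_il_profile(pair, ion_profiles)
        b = build_il_profile(pair, ion_profiles)
        np.testing.assert_array_equal(a.p_s, b.p_s)

    def test_missing_profile_is_lookup_error(self, library):
        pair = ILPair(library.get("[EMIM]+"), library.get("[Cl]-"))
        with pytest.raises(KeyError, match="no sigma profile"):
            build_il_profile(pair, {})

    def test_dissociated_mode_matches_ion_pair_distribution(
        self, library, ion_profiles
    ):
        pair = ILPair(library.get("[EMIM]+"), library.get("[Cl]-"))
        paired = build_il_profile(pair, ion_profiles)
        dissociated = build_il_profile(pair, ion_profiles, dissociated=True)
        np.testing.assert_allclose(dissociated.p_s, paired.p_s, atol=1e-14)


class TestScreen:
    def test_toy_screen_structure(self, params, settings):
        library = toy_library(2, 2)
        profiles = {
            ion.abbreviation: generate_profile(
                ProfileSpec(
                    ion.abbreviation,
                    (PeakSpec(-0.005 if ion.is_cation else 0.015, 0.003,
                              50.0 + 10.0 * i),),
                )
            )
            for i, ion in enumerate(library.ions())
        }
        solute = generate_profile(
            ProfileSpec("solute", (PeakSpec(0.0, 0.003, 80.0),))
        )
        results = screen(solute, library, profiles, params, settings)
        assert len(results) == 4
        assert [r.rank for r in results] == [1, 2, 3, 4]
        caps = [r.capacity for r in results]
        assert caps == sorted(caps, reverse=True)
        for r in results:
            assert r.capacity == pytest.approx(1.0 / r.gamma_inf, rel=1e-12)

    def test_screen_is_deterministic(self, params, settings):
        library, profiles = dilution_family_library()
        solute = generate_profile(
            ProfileSpec("s", (PeakSpec(0.0, 0.003, 90.0), PeakSpec(-0.018, 0.0015, 12.0)))
        )
        first = screen(solute, library, profiles, params, settings)
        second = screen(solute, library, profiles, params, settings)
        assert [(r.il_label, r.gamma_inf, r.rank) for r in first] == [
            (r.il_label, r.gamma_inf, r.rank) for r in second
        ]


class TestRanking:
    def test_reported_log_capacities_reproduce_validated_order(self):
        order = rank_from_capacities(REPORTED_LOG_CAPACITIES)
        assert order == [
            "[TMAm][Cl]", "[EMIM][Cl]", "[BMIM][Cl]", "[EMPyr][Br]", "[EMPyrro][Br]",
        ]

    def test_empty_input(self):
        assert rank_from_capacities({}) == []

    def test_ties_break_lexicographically(self):
        assert rank_from_capacities({"b": 1.0, "a": 1.0, "c": 2.0}) == ["c", "a", "b"]

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValidationError):
            rank_from_capacities({"a": float("nan")})


def make_results(family_caps):
    """family_caps: {(cation, chain, anion): capacity}"""
    return [
        ScreeningResult(
            il_label=f"{cat}{anion}",
            cation_abbrev=cat,
            anion_abbrev=anion,
            gamma_inf=1.0 / cap,
            capacity=cap,
            log10_capacity=np.log10(cap),
            rank=None,
        )
        for (cat, chain, anion), cap in family_caps.items()
    ]


class TestChainLengthTrend:
    def test_strictly_falling_series_reports_decreasing(self):
        cations = [
            Ion(f"[C{n}]+", f"c{n}", +1, "imidazolium", alkyl_chain_length=n)
            for n in (2, 4, 6)
        ]
        anion = Ion("[A]-", "a", -1, "anion", anion_class="inorganic")
        library = IonLibrary(cations=cations, anions=[anion])
        results = make_results(
            {(f"[C{n}]+", n, "[A]-"): 10.0 - n for n in (2, 4, 6)}
        )
        report = chain_length_trend(results, library)["imidazolium"]
        assert report.per_anion_direction["[A]-"] == "decreasing"

    def test_single_member_family_is_undetermined(self):
        cation = Ion("[C2]+", "c", +1, "ammonium", alkyl_chain_length=2)
        anion = Ion("[A]-", "a", -1, "anion", anion_class="inorganic")
        library = IonLibrary(cations=[cation], anions=[anion])
        results = make_results({("[C2]+", 2, "[A]-"): 5.0})
        report = chain_length_trend(results, library)["ammonium"]
        assert report.per_anion_direction["[A]-"] == "undetermined"

    def test_constant_capacities_are_non_monotone(self):
        cations = [
            Ion(f"[C{n}]+", f"c{n}", +1, "pyridinium", alkyl_chain_length=n)
            for n in (2, 4, 6)
        ]
        anion = Ion("[A]-", "a", -1, "anion", anion_class="inorganic")
        library = IonLibrary(cations=cations, anions=[anion])
        results = make_results({(f"[C{n}]+", n, "[A]-"): 3.0 for n in (2, 4, 6)})
        report = chain_length_trend(results, library)["pyridinium"]
        assert report.per_anion_direction["[A]-"] == "non-monotone"

    def test_charge_dilution_family_shows_decreasing_capacity(
        self, dha, params, settings
    ):
        """Adding neutral tail surface to the cation (charge dilution) lowers
        the computed capacity for every acceptor solvent in the family."""
        library, profiles = dilution_family_library()
        results = screen(dha, library, profiles, params, settings)
        report = chain_length_trend(results, library)["imidazolium"]
        assert set(report.per_anion_direction.values()) == {"decreasing"}


class TestAnionConcordance:
    def test_identical_order_gives_unit_tau(self):
        order = ["[SO4]-", "[Cl]-", "[NO3]-", "[Br]-"]
        assert anion_concordance(order, list(HOFMEISTER_ANION_ORDER)) == pytest.approx(1.0)

    def test_reversed_order_gives_negative_unit_tau(self):
        order = ["[Br]-", "[NO3]-", "[Cl]-", "[SO4]-"]
        assert anion_concordance(order, list(HOFMEISTER_ANION_ORDER)) == pytest.approx(-1.0)

    def test_observed_capacity_order_matches_pair_counting_oracle(self):
        # observed capacity ordering SO4 > Cl > Br > NO3 vs the Hofmeister
        # reference SO4 > Cl > NO3 > Br over the four shared anions
        observed = ["[SO4]-", "[Cl]-", "[Br]-", "[NO3]-"]
        tau = anion_concordance(observed, list(HOFMEISTER_ANION_ORDER))
        reference_ranks = [
            list(HOFMEISTER_ANION_ORDER).index(a) for a in observed
        ]
        expected = kendall_tau_pairs(list(range(4)), reference_ranks)
        assert tau == pytest.approx(expected)
        assert expected == pytest.approx(4 / 6)

    def test_too_few_common_elements_rejected(self):
        with pytest.raises(ValidationError):
            anion_concordance(["[Cl]-"], list(HOFMEISTER_ANION_ORDER))
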