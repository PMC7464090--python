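import math

import numpy as np
import pytest

from ilscreen import (
    PeakSpec,
    ProfileSpec,
    SegmentPotential,
    SigmaGrid,
    ValidationError,
    capacity,
    compound_chemical_potential,
    gamma_infinite_dilution,
    generate_profile,
    ln_gamma,
    mix_profiles,
)

from conftest import profile_on
from oracles import brute_force_ln_gamma


class TestCompoundChemicalPotential:
    def test_zero_area_solute_has_zero_potential(self, grid, params):
        with pytest.warns(UserWarning):
            empty = profile_on(grid, np.zeros(grid.n_bins))
        mu = SegmentPotential(grid, np.ones(grid.n_bins), True, 1, 0.0)
        assert compound_chemical_potential(empty, mu, params) == 0.0

    def test_flat_zero_potential_gives_zero(self, dha, params):
        mu = SegmentPotential(dha.grid, np.zeros(dha.grid.n_bins), True, 1, 0.0)
        assert compound_chemical_potential(dha, mu, params) == 0.0

    def test_three_bin_hand_sum(self, params):
        grid = SigmaGrid(-0.01, 0.01, 0.01)
        solute = profile_on(grid, [15.0, 30.0, 7.5])
        mu = SegmentPotential(grid, np.array([0.5, -0.25, 2.0]), True, 1, 0.0)
        expected = (15.0 * 0.5 + 30.0 * -0.25 + 7.5 * 2.0) / params.aeff
        assert compound_chemical_potential(solute, mu, params) == pytest.approx(expected)

    def test_grid_mismatch_rejected(self, dha, params):
        other_grid = SigmaGrid(-0.01, 0.01, 0.01)
        mu = SegmentPotential(other_grid, np.zeros(3), True, 1, 0.0)
        with pytest.raises(ValidationError):
            compound_chemical_potential(dha, mu, params)


class TestPureLimit:
    def test_solute_in_itself_has_unit_activity(self, dha, params, settings):
        result = ln_gamma(dha, mix_profiles([(dha, 1.0)]), params, settings)
        assert result.ln_gamma == pytest.approx(0.0, abs=1e-6)
        assert result.gamma == pytest.approx(1.0, abs=1e-6)

    def test_pure_limit_holds_for_all_library_profiles(
        self, library, ion_profiles, params, settings
    ):
        for ion in library.ions():
            prof = ion_profiles[ion.abbreviation]
            result = ln_gamma(prof, mix_profiles([(prof, 1.0)]), params, settings)
            assert result.ln_gamma == pytest.approx(0.0, abs=1e-6), ion.abbreviation

    def test_indistinguishable_species_have_unit_gamma_in_any_blend(
        self, dha, params, settings
    ):
        twin = profile_on(dha.grid, dha.areas.copy(), "twin", volume=dha.cavity_volume)
        blend = mix_profiles([(dha, 0.3), (twin, 0.7)])
        result = ln_gamma(dha, blend, params, settings)
        assert result.gamma == pytest.approx(1.0, abs=1e-6)


class TestAgainstBruteForce:
    def test_three_bin_toy_matches_literal_reimplementation(self, params, settings):
        grid = SigmaGrid(-0.01, 0.01, 0.01)
        solute = profile_on(grid, [12.0, 20.0, 4.0], "solute")
        solvent_profile = profile_on(grid, [2.0, 25.0, 13.0], "solvent")
        result = ln_gamma(
            solute, mix_profiles([(solvent_profile, 1.0)]), params, settings
        )
        expected = brute_force_ln_gamma(
            [12.0, 20.0, 4.0], [2.0, 25.0, 13.0],
            list(grid.centers()),
            params.aeff, params.alpha_prime, params.c_hb, params.sigma_hb, params.RT,
        )
        assert result.ln_gamma == pytest.approx(expected, abs=1e-6)


class TestInfiniteDilution:
    def test_exact_zero_fraction_matches_small_fraction_limit(
        self, params, settings
    ):
        grid = SigmaGrid(-0.01, 0.01, 0.01)
        solute = profile_on(grid, [10.0, 15.0, 5.0], "solute")
        solvent = profile_on(grid, [1.0, 20.0, 9.0], "solvent")
        exact = gamma_infinite_dilution(
            solute, mix_profiles([(solvent, 1.0)]), params, settings
        )
        eps = 1e-8
        nearly = ln_gamma(
            solute,
            mix_profiles([(solvent, 1.0 - eps), (solute, eps)]),
            params,
            settings,
        )
        assert exact.ln_gamma == pytest.approx(nearly.ln_gamma, abs=1e-5)

    def test_continuity_under_solvent_perturbation(self, params, settings):
        grid = SigmaGrid(-0.01, 0.01, 0.01)
        solute = profile_on(grid, [10.0, 15.0, 5.0], "solute")
        base_areas = np.array([1.0, 20.0, 9.0])
        values = []
        for eps in (0.0, 1e-4, 1e-3):
            solvent = profile_on(grid, base_areas + eps, "solvent")
            values.append(
                gamma_infinite_dilution(
                    solute, mix_profiles([(solvent, 1.0)]), params, settings
                ).ln_gamma
            )
        assert abs(values[1] - values[0]) < abs(values[2] - values[0])
        assert abs(values[2] - values[0]) < 0.05


class TestCombinatorialTerm:
    def test_requested_without_volumes_is_an_error(self, params, settings):
        grid = SigmaGrid(-0.01, 0.01, 0.01)
        solute = profile_on(grid, [10.0, 15.0, 5.0], "solute")
        solvent = mix_profiles([(profile_on(grid, [1.0, 20.0, 9.0], "solvent"), 1.0)])
        with pytest.raises(ValidationError):
            ln_gamma(solute, solvent, params, settings, combinatorial=True)

    def test_auto_mode_disables_without_volumes(self, params, settings):
        grid = SigmaGrid(-0.01, 0.01, 0.01)
        solute = profile_on(grid, [10.0, 15.0, 5.0], "solute")
        solvent = mix_profiles([(profile_on(grid, [1.0, 20.0, 9.0], "solvent"), 1.0)])
        result = ln_gamma(solute, solvent, params, settings)
        assert not result.combinatorial_included

    def test_auto_mode_enables_with_volumes(self, dha, params, settings):
        other = profile_on(
            dha.grid, dha.areas * 0.5, "half", volume=dha.cavity_volume * 0.5
        )
        result = ln_gamma(dha, mix_profiles([(other, 1.0)]), params, settings)
        assert result.combinatorial_included


class TestCapacity:
    @pytest.mark.parametrize("gamma,expected", [(1.0, 1.0), (4.0, 0.25), (0.5, 2.0)])
    def test_capacity_inverts_gamma(self, gamma, expected):
        result = capacity(gamma)
        assert result.c_inf == pytest.approx(expected)
        assert result.log10_c_inf == pytest.approx(math.log10(expected))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValidationError):
            capacity(0.0)

    def test_capacity_is_antitone_in_gamma(self):
        gammas = [0.1, 0.5, 1.0, 2.0, 10.0]
        caps = [capacity(g).c_inf for g in gammas]
        assert all(a > b for a, b in zip(caps, caps[1:]))


class TestModelProperties:
    def test_capacity_increases_with_solvent_acceptor_area(self, params, settings):
        """A hydrogen-donor solute is held better by solvents offering more
        acceptor surface: C_inf strictly increases along a one-parameter
        family of solvents differing only in acceptor-peak area."""
        solute = generate_profile(
            ProfileSpec(
                "donor-solute",
                (PeakSpec(0.0, 0.003, 100.0), PeakSpec(-0.018, 0.0015, 15.0)),
            )
        )
        caps = []
        for acceptor_area in (10.0, 25.0, 40.0, 55.0):
            solvent = generate_profile(
                ProfileSpec(
                    f"solvent-{acceptor_area}",
                    (
                        PeakSpec(0.0, 0.004, 300.0),
                        PeakSpec(0.016, 0.002, acceptor_area),
                    ),
                )
            )
            result = gamma_infinite_dilution(
                solute, mix_profiles([(solvent, 1.0)]), params, settings,
                combinatorial=False,
            )
            caps.append(capacity(result).c_inf)
        assert all(a < b for a, b in zip(caps, caps[1:]))
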