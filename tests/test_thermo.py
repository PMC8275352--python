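import math

import numpy as np
import pytest

from bimotif import BmfModel, EnergyTable, SpacerParams
from bimotif.sequences import kmer_to_index
from bimotif.thermo import (
    binding_probability,
    effective_concentration,
    enumerate_partition,
    forward_partition,
    nb_pmf,
)

from .conftest import random_model, random_seq


class TestEffectiveConcentration:
    def test_zero_scale_leaves_free_concentration(self):
        sp = SpacerParams.from_natural(r=2.0, p=0.3, scale=0.0)
        assert effective_concentration(0, sp) == 1.0
        assert effective_concentration(7, sp) == 1.0

    def test_nb_point_mass_closed_form(self):
        # NB pmf at d=0 is p^r; 1 + 10000 * 0.2 = 2001
        sp = SpacerParams.from_natural(r=1.0, p=0.2, scale=1e4)
        assert effective_concentration(0, sp) == pytest.approx(2001.0, rel=1e-12)

    def test_structured_component_is_normalized_pmf(self):
        sp = SpacerParams.from_natural(r=2.7, p=0.35, scale=123.0)
        d = np.arange(2000)
        total = np.sum((effective_concentration(d, sp) - 1.0) / sp.scale)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_non_integer_r_matches_scipy(self):
        from scipy.stats import nbinom

        d = np.arange(30)
        assert nb_pmf(d, 2.5, 0.3) == pytest.approx(nbinom.pmf(d, 2.5, 0.3), rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            effective_concentration(-1, SpacerParams.from_natural(1, 0.5, 1))


class TestForwardPartition:
    def test_sequence_shorter_than_core_is_unbound_only(self, rng):
        model = random_model(rng, 3)
        for seq in ("", "A", "GU"):
            assert forward_partition(seq, model).Z == 1.0

    def test_single_window_enumerates_three_configurations(self, rng):
        model = random_model(rng, 3)
        ea = model.core_a.energies[kmer_to_index("ACG")]
        eb = model.core_b.energies[kmer_to_index("ACG")]
        expected = 1.0 + math.exp(-ea) + math.exp(-eb)
        assert forward_partition("ACG", model).Z == pytest.approx(expected, rel=1e-12)

    def test_dp_result_identity_and_bounds(self, rng):
        model = random_model(rng, 3)
        seq = random_seq(rng, 25)
        res = forward_partition(seq, model)
        assert res.Z >= 1.0
        assert np.all(res.ZA >= 0) and np.all(res.ZB >= 0)
        assert res.Z == pytest.approx(res.ZB[-1] + res.ZA.sum(), rel=1e-12)

    def test_ambiguous_windows_contribute_zero_weight(self, rng):
        model = random_model(rng, 3)
        # every window covers the N -> only the unbound configuration remains
        assert forward_partition("ANG", model).Z == 1.0
        # windows away from the N still contribute
        z = forward_partition("ACGNACG", model).Z
        z_clean_parts = forward_partition("ACG", model).Z
        assert z > 1.0
        assert z >= z_clean_parts

    def test_dna_input_is_mapped_to_rna(self, rng):
        model = random_model(rng, 2)
        assert forward_partition("ACGT", model).Z == pytest.approx(
            forward_partition("ACGU", model).Z, rel=1e-15
        )

    def test_long_sequence_stays_finite_and_reports_capping(self, rng):
        model = random_model(rng, 3)
        model.core_a.energies[:] = np.abs(model.core_a.energies)
        model.core_b.energies[:] = np.abs(model.core_b.energies)
        seq = random_seq(rng, 10_000)
        with pytest.warns(RuntimeWarning, match="cap"):
            res = forward_partition(seq, model)
        assert np.isfinite(res.Z)
        assert res.capped

    def test_moderate_sequences_do_not_hit_the_cap(self, rng):
        model = random_model(rng, 3)
        res = forward_partition(random_seq(rng, 200), model)
        assert not res.capped and np.isfinite(res.Z)

    def test_monotone_in_energy_of_present_kmer(self, rng):
        model = random_model(rng, 3)
        seq = "ACGUACGU"
        z0 = forward_partition(seq, model).Z
        lowered = model.copy()
        lowered.core_a.energies[kmer_to_index("CGU")] -= 1.0
        assert forward_partition(seq, lowered).Z > z0
        absent = model.copy()
        absent.core_a.energies[kmer_to_index("UUU")] -= 5.0
        assert forward_partition(seq, absent).Z == pytest.approx(z0, rel=1e-15)

    def test_concentration_neutral_when_scale_is_zero(self, rng):
        seq = random_seq(rng, 20)
        base = random_model(rng, 2, scale=0.0)
        z0 = forward_partition(seq, base).Z
        for rho, pi in [(-1.0, 2.0), (1.5, -0.5)]:
            other = base.copy()
            other.spacer.rho, other.spacer.pi = rho, pi
            assert forward_partition(seq, other).Z == pytest.approx(z0, rel=1e-15)

    def test_vanishing_affinity_limit(self, rng):
        model = random_model(rng, 3)
        seq = random_seq(rng, 40)
        zs = []
        for shift in (5.0, 15.0, 30.0):
            m = model.copy()
            m.core_a.energies[:] = shift + np.abs(m.core_a.energies)
            m.core_b.energies[:] = shift + np.abs(m.core_b.energies)
            zs.append(forward_partition(seq, m).Z)
        assert zs[0] > zs[1] > zs[2]
        assert zs[-1] == pytest.approx(1.0, abs=1e-8)


class TestBindingProbability:
    def test_formula_and_bounds(self, rng):
        model = random_model(rng, 3)
        assert binding_probability("AA", model) == 0.0
        seq = random_seq(rng, 30)
        p = binding_probability(seq, model)
        z = forward_partition(seq, model).Z
        assert p == pytest.approx(1.0 - 1.0 / z, rel=1e-12)
        assert 0.0 <= p < 1.0


class TestEnumerationOracle:
    def test_refuses_long_sequences(self, rng):
        with pytest.raises(ValueError, match="enumeration limit"):
            enumerate_partition("A" * 30, random_model(rng, 2))

    def test_three_configuration_case(self, rng):
        model = random_model(rng, 3)
        assert enumerate_partition("ACG", model) == pytest.approx(
            forward_partition("ACG", model).Z, rel=1e-12
        )

    def test_contains_hand_enumerated_pair_terms(self):
        # Homogeneous energies E0 on "AAAAAAAA" (L=8, k=3).  The tethered
        # A-B pair configurations, enumerated by hand, are (A start, B
        # start) = (0,3) (0,4) (0,5) (1,4) (1,5) (2,5) with spacers
        # d = 0,1,2,0,1,0.  Subtracting the S=0 partition sum removes every
        # configuration without a tethered pair, and with E0 large the
        # remaining 3+-placement terms are O(e^{-3 E0}), so
        #   Z(S) - Z(0) ~= S e^{-2 E0} [3 NB(0) + 2 NB(1) + 1 NB(2)],
        # which includes the required cB(2) e^{-2 E0} pair (A at 0-2, B at
        # 5-7).
        e0 = 30.0
        r, p, scale = 1.5, 0.4, 1.0e4
        with_pairs = SpacerParams.from_natural(r=r, p=p, scale=scale)
        free_only = SpacerParams.from_natural(r=r, p=p, scale=0.0)
        tables = (EnergyTable(3, np.full(64, e0)), EnergyTable(3, np.full(64, e0)))
        z_s = enumerate_partition("AAAAAAAA", BmfModel(*tables, with_pairs))
        z_0 = enumerate_partition("AAAAAAAA", BmfModel(*tables, free_only))
        expected = scale * math.exp(-2 * e0) * float(
            3 * nb_pmf(0, r, p) + 2 * nb_pmf(1, r, p) + 1 * nb_pmf(2, r, p)
        )
        assert z_s - z_0 == pytest.approx(expected, rel=1e-9)

    def test_matches_dp_on_random_instances(self, rng):
        for _ in range(60):
            k = int(rng.integers(2, 4))
            L = int(rng.integers(0, 15))
            model = random_model(rng, k)
            seq = random_seq(rng, L)
            z_dp = forward_partition(seq, model).Z
            z_enum = enumerate_partition(seq, model)
            assert abs(z_dp - z_enum) <= 1e-9 * z_enum

    def test_matches_dp_with_ambiguous_bases(self, rng):
        for _ in range(10):
            model = random_model(rng, 2)
            chars = rng.choice(list("ACGUN"), size=10)
            seq = "".join(chars)
            assert forward_partition(seq, model).Z == pytest.approx(
                enumerate_partition(seq, model), rel=1e-9
            )
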