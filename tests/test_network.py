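"""Mass-action semantics, conservation and detailed-balance checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msnsig.network import (
    ConservedMoiety,
    MassActionReaction,
    NetworkModel,
    SpeciesDef,
    apply_scaling,
    detailed_balance_check,
    rate_vector,
)


def test_rate_vector_reversible_binding(binding_model):
    d = rate_vector(binding_model, {"A": 1.0, "B": 1.0, "AB": 0.0})
    assert d["AB"] == pytest.approx(1.0)
    assert d["A"] == pytest.approx(-1.0)
    assert d["B"] == pytest.approx(-1.0)


def test_rate_vector_zero_rates(binding_model):
    binding_model.reactions[0].kf = 0.0
    binding_model.reactions[0].kr = 0.0
    d = rate_vector(binding_model, {"A": 1.0, "B": 1.0, "AB": 0.5})
    assert all(v == 0.0 for v in d.values())


def test_rate_vector_irreversible_conversion():
    m = NetworkModel()
    m.species = [SpeciesDef("A", initial_concentration=3.0), SpeciesDef("B")]
    m.reactions = [MassActionReaction("c", [("A", 1)], [("B", 1)], 2.0)]
    d = rate_vector(m, {"A": 3.0, "B": 0.0})
    assert d["B"] == pytest.approx(6.0)
    assert d["A"] + d["B"] == pytest.approx(0.0)


def test_rate_vector_clamps_negatives_and_zeroes_inputs():
    m = NetworkModel()
    m.species = [
        SpeciesDef("Ca", "input", 0.06, is_clamped_input=True),
        SpeciesDef("X", initial_concentration=1.0),
        SpeciesDef("CaX"),
    ]
    m.reactions = [MassActionReaction("b", [("Ca", 1), ("X", 1)], [("CaX", 1)], 1.0, 1.0)]
    d = rate_vector(m, {"Ca": 0.06, "X": -1e-12, "CaX": 0.0})
    assert d["Ca"] == 0.0
    assert d["X"] == pytest.approx(0.0, abs=1e-15)  # negative X clamped to 0


def test_rate_vector_unknown_species_fails(binding_model):
    with pytest.raises(KeyError, match="Zz"):
        rate_vector(binding_model, {"A": 1, "B": 1, "AB": 0, "Zz": 1})


@given(kf=st.floats(0.01, 100), scale=st.floats(0.1, 10))
@settings(max_examples=25, deadline=None)
def test_rate_vector_linear_in_rate_constant(kf, scale):
    """Doubling kf exactly doubles the (irreversible) flux contribution."""
    m = NetworkModel()
    m.species = [SpeciesDef("A", initial_concentration=2.0), SpeciesDef("B")]
    m.reactions = [MassActionReaction("r", [("A", 1)], [("B", 1)], kf)]
    d1 = rate_vector(m, {"A": 2.0, "B": 0.0})
    m.reactions[0].kf = kf * scale
    d2 = rate_vector(m, {"A": 2.0, "B": 0.0})
    assert d2["B"] == pytest.approx(scale * d1["B"], rel=1e-12)


def test_moiety_derivative_sums_to_zero(wt_model, wt_basal):
    """Analytic conservation: summed derivatives of any moiety vanish."""
    d = rate_vector(wt_model, wt_basal)
    for m in wt_model.conserved_moieties:
        assert abs(sum(d[x] for x in m.members)) < 1e-12


def test_stoichiometry_above_two_rejected():
    with pytest.raises(ValueError, match="stoichiometry"):
        MassActionReaction("bad", [("A", 3)], [("B", 1)], 1.0)


def test_validate_catches_mismatched_moiety_total():
    m = NetworkModel()
    m.species = [SpeciesDef("A", initial_concentration=1.0)]
    m.conserved_moieties = [ConservedMoiety("A", ["A"], 2.0)]
    with pytest.raises(ValueError, match="total"):
        m.validate()


class TestDetailedBalance:
    def _loop(self, keqs):
        """Three reversible conversions A->B->C->A with given Keq values."""
        m = NetworkModel()
        m.species = [SpeciesDef(s, initial_concentration=1.0) for s in "ABC"]
        pairs = [("A", "B"), ("B", "C"), ("C", "A")]
        m.reactions = [
            MassActionReaction(f"r{i}", [(x, 1)], [(y, 1)], k, 1.0)
            for i, ((x, y), k) in enumerate(zip(pairs, keqs))
        ]
        return m

    def test_consistent_loop(self):
        m = self._loop([2.0, 3.0, 1.0 / 6.0])
        assert detailed_balance_check(m, ["r0", "r1", "r2"]) == pytest.approx(1.0)

    def test_broken_loop_detected(self):
        m = self._loop([2.0, 3.0, 1.0 / 6.0])
        m.reactions[2].kr = 2.0  # halves Keq of r2: loop ratio off by 2x
        assert detailed_balance_check(m, ["r0", "r1", "r2"]) == pytest.approx(0.5)
        # traversing the loop in the opposite orientation inverts the ratio
        rev = [("r2", -1), ("r1", -1), ("r0", -1)]
        assert detailed_balance_check(m, rev) == pytest.approx(2.0)

    def test_irreversible_reaction_rejected(self):
        m = self._loop([2.0, 3.0, 1.0 / 6.0])
        m.reactions[1].kr = 0.0
        with pytest.raises(ValueError, match="irreversible"):
            detailed_balance_check(m, ["r0", "r1", "r2"])

    def test_open_chain_rejected(self):
        m = self._loop([2.0, 3.0, 1.0 / 6.0])
        with pytest.raises(ValueError, match="close"):
            detailed_balance_check(m, ["r0", "r1"])

    def test_packaged_calmodulin_cycles_balance(self, wt_model):
        from msnsig.model import DETAILED_BALANCE_CYCLES

        for cycle in DETAILED_BALANCE_CYCLES.values():
            assert detailed_balance_check(wt_model, cycle) == pytest.approx(
                1.0, abs=1e-6
            )


class TestApplyScaling:
    def test_identity(self, binding_model):
        out = apply_scaling(binding_model, {"kf:bind": 1.0})
        assert out.get_reaction("bind").kf == binding_model.get_reaction("bind").kf

    def test_doubling_kf_doubles_flux(self, binding_model):
        out = apply_scaling(binding_model, {"kf:bind": 2.0})
        s = {"A": 1.0, "B": 1.0, "AB": 0.0}
        assert rate_vector(out, s)["AB"] == pytest.approx(
            2 * rate_vector(binding_model, s)["AB"]
        )

    def test_total_scaling_rescales_members(self):
        m = NetworkModel()
        m.species = [
            SpeciesDef("X", initial_concentration=3.0),
            SpeciesDef("Xp", initial_concentration=1.0),
        ]
        m.conserved_moieties = [ConservedMoiety("X", ["X", "Xp"], 4.0)]
        out = apply_scaling(m, {"total:X": 0.5})
        assert out.get_species("X").initial_concentration == pytest.approx(1.5)
        assert out.get_species("Xp").initial_concentration == pytest.approx(0.5)
        assert out.conserved_moieties[0].total == pytest.approx(2.0)
        out.validate()

    def test_unknown_parameter_fails(self, binding_model):
        with pytest.raises(KeyError):
            apply_scaling(binding_model, {"kf:nope": 2.0})

    def test_nonpositive_multiplier_fails(self, binding_model):
        with pytest.raises(ValueError):
            apply_scaling(binding_model, {"kf:bind": 0.0})
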