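"""Striatal model assembly: variants, observables, structural invariants."""

import numpy as np
import pytest

from msnsig.model import (
    VariantSpec,
    basal_state,
    build_model,
    extract_subnetwork,
    observables,
)


@pytest.fixture(scope="module")
def variants():
    return {v: build_model(v) for v in ("WT", "NO_ARPP21", "D32T34A", "A21S55A")}


def test_wt_builds_and_validates(wt_model):
    wt_model.validate()
    assert len(wt_model.species) > 50
    assert len(wt_model.reactions) > 50


def test_arpp21_total_is_20_uM(wt_model):
    m = {x.name: x for x in wt_model.conserved_moieties}["ARPP21"]
    assert m.total == pytest.approx(20.0)


def test_no_arpp21_differs_only_by_arpp21_species(variants):
    wt = set(variants["WT"].species_names())
    na = set(variants["NO_ARPP21"].species_names())
    assert na < wt
    dropped = wt - na
    assert all("A21" in s for s in dropped)


def test_t34a_removes_thr34_phosphorylation(variants):
    """The T34A knock-down removes exactly the PKA -> Thr-34 reaction pair."""
    wt_ids = {r.id for r in variants["WT"].reactions}
    mut_ids = {r.id for r in variants["D32T34A"].reactions}
    assert wt_ids - mut_ids == {"pka_d32_bind", "pka_d32_cat"}
    # no reaction in the mutant produces Thr-34-phosphorylated DARPP-32 de novo
    producers = [
        r.id
        for r in variants["D32T34A"].reactions
        if any(n == "D32p34" for n, _ in r.products) and r.id != "pp1_p34"
    ]
    assert producers == []


def test_a21s55a_removes_ser55_phosphorylation(variants):
    wt_ids = {r.id for r in variants["WT"].reactions}
    mut_ids = {r.id for r in variants["A21S55A"].reactions}
    assert wt_ids - mut_ids == {"pka_a21_bind", "pka_a21_cat"}


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        VariantSpec("T34A_TYPO")


def test_observables_are_unit_coefficient_species_sums(wt_model):
    names = set(wt_model.species_names())
    obs = observables(wt_model)
    for members in obs.values():
        assert set(members) <= names
        assert len(set(members)) == len(members)
    assert "pARPP21_S55" in obs
    assert "pARPP21_S55" not in observables(build_model("NO_ARPP21"))


def test_cam_overexpression_scales_cam_total():
    from msnsig.model import CAM_OVEREXPRESSION_FACTOR

    wt = build_model("WT")
    ov = build_model("CAM_OVEREXPRESS")
    wt_cam = {x.name: x for x in wt.conserved_moieties}["CaM"].total
    ov_cam = {x.name: x for x in ov.conserved_moieties}["CaM"].total
    assert ov_cam == pytest.approx(CAM_OVEREXPRESSION_FACTOR * wt_cam)


def test_variant_scale_factors_applied():
    m = build_model(VariantSpec("WT", scale_factors={"kf:cam_ca1": 2.0}))
    base = build_model("WT")
    assert m.get_reaction("cam_ca1").kf == pytest.approx(
        2 * base.get_reaction("cam_ca1").kf
    )


def test_missing_parameter_fails_with_name():
    from msnsig.model import load_parameters

    params = load_parameters()
    del params["rate_constants"]["pka_d32"]
    with pytest.raises(KeyError, match="pka_d32"):
        build_model("WT", params=params)


def test_extract_subnetwork_keeps_only_internal_reactions(wt_model):
    sub = extract_subnetwork(
        wt_model, {"PKA", "PKA_cAMP", "PKA_cAMP2", "PKAr", "PKAc"}, clamp={"cAMP"}
    )
    assert {r.id for r in sub.reactions} == {"pka_bind1", "pka_bind2", "pka_release"}
    assert sub.get_species("cAMP").is_clamped_input


class TestBasalState:
    def test_basal_pARPP21_stays_flat_without_dopamine(self, wt_model, wt_basal):
        """Without a dopamine transient pARPP-21 remains at basal (<5% dev)."""
        from msnsig.engine import simulate
        from msnsig.model import observable_trace
        from msnsig.stimulus import CalciumTrain, StimulusProtocol, TrialSchedule

        proto = StimulusProtocol(
            calcium=CalciumTrain(onset=2.0), dopamine=None,
            schedule=TrialSchedule(), total_duration=45.0,
        )
        res = simulate(wt_model, proto, t_end=40.0, initial_state=wt_basal,
                       max_step=0.05)
        pa = observable_trace(res, "pARPP21_S55", wt_model)
        assert np.max(np.abs(pa / pa[0] - 1.0)) < 0.05

    def test_active_pp1_flat_under_calcium_alone(self, wt_model, wt_basal):
        from msnsig.engine import simulate
        from msnsig.model import observable_trace
        from msnsig.stimulus import CalciumTrain, StimulusProtocol, TrialSchedule

        proto = StimulusProtocol(
            calcium=CalciumTrain(onset=2.0), dopamine=None,
            schedule=TrialSchedule(), total_duration=65.0,
        )
        res = simulate(wt_model, proto, t_end=60.0, initial_state=wt_basal,
                       max_step=0.05)
        pp1 = observable_trace(res, "active_PP1", wt_model)
        assert np.max(np.abs(pp1 / pp1[0] - 1.0)) < 0.05

    def test_pp1_transiently_inhibited_with_dopamine(self, wt_model):
        from msnsig.experiments import run_trial
        from msnsig.model import observable_trace

        res = run_trial(wt_model, 1.0, window=40.0)
        pp1 = observable_trace(res, "active_PP1", wt_model)
        assert pp1.min() / pp1[0] < 0.5

    def test_camkii_deactivation_tau_in_range(self, wt_model, wt_basal):
        """Monoexponential deactivation time constant within 4-9 s."""
        from msnsig.engine import simulate
        from msnsig.model import observable_trace
        from msnsig.phenotypes import fit_monoexponential
        from msnsig.stimulus import CalciumTrain, StimulusProtocol, TrialSchedule

        proto = StimulusProtocol(
            calcium=CalciumTrain(onset=2.0), dopamine=None,
            schedule=TrialSchedule(), total_duration=65.0,
        )
        res = simulate(wt_model, proto, t_end=60.0, initial_state=wt_basal,
                       max_step=0.05)
        k, _ = fit_monoexponential(
            res.time, observable_trace(res, "active_CaMKII", wt_model)
        )
        assert 4.0 < 1.0 / k < 9.0
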