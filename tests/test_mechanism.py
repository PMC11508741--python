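"""Mechanism model, file dialect and parameter updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from basalcal.mechanism import (
    Mechanism,
    MechanismError,
    RateCoefficient,
    Reaction,
    SpeciesDef,
    mechanism_from_dict,
    parse_equation,
    parse_mechanism,
    set_log_parameters,
    write_mechanism,
)

MINI = """
name: mini
species:
  - id: ATG5T
  - id: BCL2
  - id: ATG5_BCL2
    complex: true
reactions:
  - index: 73
    equation: ATG5T + BCL2 -> ATG5_BCL2
    log10_k: 6.50
    f_prior: 4.0
"""


def test_parse_bimolecular_association(tmp_path):
    p = tmp_path / "mini.yaml"
    p.write_text(MINI)
    mech = parse_mechanism(p)
    rxn = mech.reaction_by_index(73)
    assert rxn.reactants == {"ATG5T": 1, "BCL2": 1}
    assert rxn.products == {"ATG5_BCL2": 1}
    assert rxn.molecularity == 2
    assert rxn.rate.k == pytest.approx(10 ** 6.50)


def test_empty_reaction_list_is_valid():
    mech = mechanism_from_dict({"species": ["A", "B"], "reactions": []})
    assert mech.n_reactions == 0
    assert mech.n_species == 2


def test_termolecular_rejected():
    with pytest.raises(MechanismError, match="molecularity"):
        mechanism_from_dict(
            {"species": ["A", "B", "C", "D"],
             "reactions": [{"index": 1, "equation": "A + B + C -> D", "log10_k": 0.0}]}
        )


@pytest.mark.parametrize("text,expected", [
    ("BAX -> 0", ({"BAX": 1}, {})),
    ("BAX -> ⌀", ({"BAX": 1}, {})),
    ("2 A -> A + B", ({"A": 2}, {"A": 1, "B": 1})),
    ("X -> X + Y", ({"X": 1}, {"X": 1, "Y": 1})),
])
def test_equation_parsing(text, expected):
    assert parse_equation(text) == expected


def test_validation_errors():
    with pytest.raises(MechanismError, match="undeclared"):
        mechanism_from_dict(
            {"species": ["A"], "reactions": [{"index": 1, "equation": "A -> Z", "log10_k": 0}]}
        )
    with pytest.raises(MechanismError, match="duplicate reaction index"):
        mechanism_from_dict(
            {"species": ["A", "B"],
             "reactions": [{"index": 1, "equation": "A -> B", "log10_k": 0},
                            {"index": 1, "equation": "B -> A", "log10_k": 0}]}
        )
    with pytest.raises(MechanismError, match="duplicate species"):
        Mechanism(species=[SpeciesDef("A"), SpeciesDef("A")], reactions=[])
    with pytest.raises(MechanismError, match="not symmetric"):
        mechanism_from_dict(
            {"species": ["A", "B"],
             "reactions": [{"index": 1, "equation": "A -> B", "log10_k": 0, "reverse_of": 2},
                            {"index": 2, "equation": "B -> A", "log10_k": 0}]}
        )


def test_buffered_complex_contradiction():
    with pytest.raises(MechanismError):
        SpeciesDef("REF", role="buffered", is_complex=True)


@pytest.mark.parametrize("which", ["truth", "standin"])
def test_round_trip_is_lossless(which, truth, standin, tmp_path, request):
    mech = truth.mechanism if which == "truth" else standin[0]
    p = tmp_path / "out.yaml"
    write_mechanism(mech, p)
    back = parse_mechanism(p)
    assert back.n_species == mech.n_species
    assert back.n_reactions == mech.n_reactions
    for a, b in zip(mech.species, back.species):
        assert (a.id, a.role, a.is_complex, a.monitored) == (b.id, b.role, b.is_complex, b.monitored)
    for a, b in zip(mech.reactions, back.reactions):
        assert a.index == b.index
        assert a.reactants == b.reactants and a.products == b.products
        assert a.reverse_of == b.reverse_of
        assert b.rate.log10_k == pytest.approx(a.rate.log10_k, abs=1e-12)
        assert b.rate.f_prior == pytest.approx(a.rate.f_prior, abs=1e-12)


def test_standin_contains_published_reaction_indices(standin):
    mech, _ = standin
    published = [8, 9, 10, 18, 28, 29, 30, 34, 43, 44, 45, 54, 63, 69, 71, 73, 102, 104, 109]
    indices = {r.index for r in mech.reactions}
    assert set(published) <= indices
    # the pro-apoptotic production/degradation arm
    assert mech.reaction_by_index(6).equation == "P53A -> P53A + BAX"
    assert mech.reaction_by_index(12).equation == "BAX -> 0"


def test_reaction_count_decomposition(standin):
    mech, _ = standin
    in_pairs = sum(1 for r in mech.reactions if r.reverse_of is not None)
    one_way = sum(1 for r in mech.reactions if r.reverse_of is None)
    assert mech.reversible_pair_count == 14
    assert in_pairs == 28 and one_way == 85
    assert in_pairs + one_way == mech.n_reactions == 113


def test_set_log_parameters(standin):
    mech, _ = standin
    m2 = set_log_parameters(mech, {73: 4.79})
    assert m2.reaction_by_index(73).rate.k == pytest.approx(10 ** 4.79)
    assert mech.reaction_by_index(73).rate.log10_k == pytest.approx(6.50)  # copy
    # identity update
    m3 = set_log_parameters(mech, {73: mech.reaction_by_index(73).rate.log10_k0})
    assert m3.reaction_by_index(73).rate.log10_k == mech.reaction_by_index(73).rate.log10_k
    with pytest.raises(MechanismError, match="unknown reaction"):
        set_log_parameters(mech, {99999: 0.0})


def test_clipping_to_prior_band(standin):
    mech, _ = standin
    # nominal exponent 6.50, f_prior 4: request 11.0 -> clamp to 10.50, flag
    m2 = set_log_parameters(mech, {73: 11.0}, clip=True)
    r = m2.reaction_by_index(73)
    assert r.rate.log10_k == pytest.approx(10.50)
    assert r.rate.pinned
    with pytest.raises(MechanismError, match="outside prior band"):
        set_log_parameters(mech, {73: 11.0}, clip=False)


@settings(max_examples=50, deadline=None)
@given(value=st.floats(-30, 30), k0=st.floats(-10, 10), f=st.floats(0, 6))
def test_clip_never_leaves_band(value, k0, f):
    mech = mechanism_from_dict(
        {"species": ["A"],
         "reactions": [{"index": 1, "equation": "A -> 0", "log10_k": k0, "f_prior": f}]}
    )
    m2 = set_log_parameters(mech, {1: value}, clip=True)
    r = m2.reaction_by_index(1)
    assert abs(r.rate.log10_k - r.rate.log10_k0) <= f + 1e-12


def test_temperature_parameters_fixed_at_zero():
    rc = RateCoefficient(log10_k=1.0)
    assert rc.n_exp == 0.0 and rc.E_act == 0.0 and rc.A == pytest.approx(10.0)
    with pytest.raises(MechanismError):
        RateCoefficient(log10_k=1.0, n_exp=1.0)
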