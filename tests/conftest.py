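import numpy as np
import pytest

from basalcal.ranges import sample_initial_conditions
from basalcal.synthetic import build_standin_model, make_fixture_mechanism


@pytest.fixture(scope="session")
def truth():
    """Small synthetic ground-truth network (basal-stable)."""
    return make_fixture_mechanism(seed=0)


@pytest.fixture(scope="session")
def truth_blowup():
    return make_fixture_mechanism(seed=0, blow_up=True)


@pytest.fixture(scope="session")
def conditions(truth):
    """Frozen 20-condition ensemble for the fixture network."""
    return sample_initial_conditions(truth.ranges, truth.mechanism, 20, seed=100)


@pytest.fixture(scope="session")
def standin():
    return build_standin_model()


def random_mass_action_network(rng, n_species=6, n_reactions=8):
    """Small random uni/bimolecular network for oracle comparisons."""
    from basalcal.mechanism import Mechanism, RateCoefficient, Reaction, SpeciesDef

    ids = [f"S{i}" for i in range(n_species)]
    species = [SpeciesDef(sid) for sid in ids]
    reactions = []
    for r in range(n_reactions):
        order = rng.integers(1, 3)
        reactants: dict[str, int] = {}
        for sid in rng.choice(ids, size=order, replace=True):
            reactants[sid] = reactants.get(sid, 0) + 1
        products: dict[str, int] = {}
        for sid in rng.choice(ids, size=rng.integers(0, 3), replace=True):
            products[sid] = products.get(sid, 0) + 1
        reactions.append(
            Reaction(r + 1, reactants, products,
                     RateCoefficient(log10_k=float(rng.uniform(-2, 2))))
        )
    return Mechanism(species=species, reactions=reactions, name="random")


def brute_force_rhs(mech, state):
    """Independent term-by-term mass-action derivative (test oracle)."""
    ids = [s.id for s in mech.species if not s.buffered]
    buffered = {s.id: s.activity for s in mech.species if s.buffered}
    index = {sid: i for i, sid in enumerate(ids)}
    deriv = np.zeros(len(ids))
    for rxn in mech.reactions:
        flux = rxn.rate.k
        for sid, coef in rxn.reactants.items():
            conc = buffered[sid] if sid in buffered else state[index[sid]]
            for _ in range(coef):
                flux *= conc
        # net stoichiometric change per species (a catalyst nets zero exactly)
        net: dict[str, int] = {}
        for sid, coef in rxn.reactants.items():
            net[sid] = net.get(sid, 0) - coef
        for sid, coef in rxn.products.items():
            net[sid] = net.get(sid, 0) + coef
        for sid, coef in net.items():
            if sid in index and coef != 0:
                deriv[index[sid]] += coef * flux
    return deriv
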