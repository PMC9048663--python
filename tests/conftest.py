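import pathlib

import pytest

import pathcurator as pc
from pathcurator.retrieval import cache_path


@pytest.fixture
def chain_model():
    """3-step capacitated chain with exchanges, seed 7 (caps 10, 7, 7)."""
    return pc.generate_toy_model(3, with_exchanges=True, seed=7)


@pytest.fixture
def dead_end_model():
    """Same chain but reaction R1 excretes the dead-end byproduct d_c."""
    return pc.generate_toy_model(3, with_exchanges=True, dead_end_at=1,
                                 seed=7)


@pytest.fixture
def fixture_cache(tmp_path, chain_model) -> pathlib.Path:
    """On-disk record cache for the chain model, in all three dialects."""
    cache = tmp_path / "cache"
    for (src, kind, ident), text in \
            pc.generate_fixture_records(chain_model).items():
        p = cache_path(cache, src, kind, ident)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text)
    return cache


@pytest.fixture
def provider(chain_model):
    return pc.fixture_provider(chain_model)


def make_simple_model(*reactions, formulas=None, charges=None):
    """Model from (rid, stoich, lb, ub[, direction]) tuples; metabolites
    are created as needed with optional formulas/charges by id."""
    formulas = formulas or {}
    charges = charges or {}
    model = pc.Model("test")
    model.compartments["c"] = "c"
    for spec in reactions:
        rid, stoich, lb, ub = spec[:4]
        direction = spec[4] if len(spec) > 4 else pc.Direction.UNSPECIFIED
        for mid in stoich:
            if mid not in model.metabolites:
                f = formulas.get(mid)
                model.add_metabolite(pc.Metabolite(
                    id=mid, compartment=mid.rsplit("_", 1)[1],
                    formula=pc.parse_formula(f) if f else None,
                    charge=charges.get(mid),
                ))
        model.add_reaction(pc.Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            declared_direction=direction,
        ))
    return model
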