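import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from pairmint.model_core import MetabolicModel, Metabolite, Reaction
from pairmint.orchestrator import RunConfig
from pairmint.synthetic_fixtures import FIXTURE_KINDS, make_toy_pair, make_toy_study

STUDY_SEED = 1


def linear_chain_model(model_id: str = "toy", cap: float = 10.0) -> MetabolicModel:
    """S_e →(exchange, uptake cap)→ S_e →(T)→ X_c →(biomass)→ ∅."""
    m = MetabolicModel(id=model_id)
    m.add_metabolite(Metabolite("S_e", compartment="e"))
    m.add_metabolite(Metabolite("X_c", compartment="c"))
    m.add_reaction(Reaction("EX_S", {"S_e": -1.0}, -cap, 1000.0))
    m.add_reaction(Reaction("T", {"S_e": -1.0, "X_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(
        Reaction("BIO", {"X_c": -1.0}, 0.0, 1000.0, objective_coefficient=1.0)
    )
    m.biomass_reaction_id = "BIO"
    return m


@pytest.fixture
def chain_model() -> MetabolicModel:
    return linear_chain_model()


@pytest.fixture(scope="session")
def toy_pairs():
    """kind -> (model_a, model_b, pair diet, FixtureSpec) for all six kinds."""
    return {kind: make_toy_pair(kind, seed=STUDY_SEED) for kind in FIXTURE_KINDS}


@pytest.fixture(scope="session")
def toy_study_dir(tmp_path_factory) -> Path:
    return make_toy_study(seed=STUDY_SEED, outdir=tmp_path_factory.mktemp("study") / "toy")


def study_config(study_dir: Path, out: Path, **overrides) -> RunConfig:
    kwargs = dict(
        associations=study_dir / "associations.tsv",
        sequences=study_dir / "queries.fasta",
        reference=study_dir / "reference.fasta",
        models_dir=study_dir / "models",
        diet=study_dir / "diets" / "complete.tsv",
        out=out,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def toy_run_dir(toy_study_dir, tmp_path_factory) -> Path:
    """One full pipeline run on the toy study, shared across tests."""
    from pairmint.orchestrator import run_all

    out = tmp_path_factory.mktemp("run") / "out"
    run_all(study_config(toy_study_dir, out))
    return out
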