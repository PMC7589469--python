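import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lifespan_epistasis.records import (  # noqa: E402
    ExperimentGroup,
    GeneIntervention,
    LifespanObservation,
    MutantModel,
    group_observations,
)


def make_model(genes, organism="C. elegans", itype="loss-of-function mutation"):
    return MutantModel(
        organism=organism,
        interventions=frozenset(GeneIntervention(g, itype) for g in genes),
    )


def make_obs(genes, lifespan, organism="C. elegans", study="S1", temp=20.0, diet="NGM"):
    return LifespanObservation(
        model=make_model(genes, organism=organism),
        lifespan_days=lifespan,
        temperature_c=temp,
        diet=diet,
        study_id=study,
    )


def make_group(lifespans, organism="C. elegans", study="S1", temp=20.0, diet="NGM"):
    """Build one ExperimentGroup from {gene-tuple: lifespan_days}.

    Use the empty tuple for wild type; a list value emits replicate cohorts.
    """
    observations = []
    for genes, value in lifespans.items():
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            observations.append(
                make_obs(tuple(genes), v, organism=organism, study=study, temp=temp, diet=diet)
            )
    (group,) = group_observations(observations)
    return group


@pytest.fixture
def double_mutant_group():
    """WT + two singles + double, one experiment, clean positive effects."""
    return make_group({(): 20.0, ("g1",): 26.0, ("g2",): 24.0, ("g1", "g2"): 32.0})


@pytest.fixture
def triple_family_group():
    """A fully assayed 3-gene family: singles +10/+20/+30, pairs +35/+45/+55,
    triple +90 — fully synergistic (every bipartition sums to 65 < 90)."""
    return make_group(
        {
            (): 20.0,
            ("g1",): 22.0,
            ("g2",): 24.0,
            ("g3",): 26.0,
            ("g1", "g2"): 27.0,
            ("g1", "g3"): 29.0,
            ("g2", "g3"): 31.0,
            ("g1", "g2", "g3"): 38.0,
        }
    )
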