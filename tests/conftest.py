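import numpy as np
import pytest

from p53combo.network import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    build_network,
)


@pytest.fixture(scope="session")
def network():
    """The nominal p53-pathway network (phenotype-free), built once."""
    return build_network()


@pytest.fixture(scope="session")
def compiled(network):
    return network.compile()


def _pk_species():
    # every network needs the drug pools + the infusion channel so the
    # engines can schedule protocol events against it
    return [
        Species("INH_depot", "drug-pool", 0.0),
        Species("INH_blood", "drug-pool", 0.0),
    ]


def _pk_reactions():
    return [
        Reaction("pk_liberation", (("INH_depot", 1),), (("INH_blood", 1),),
                 "d_r1"),
        Reaction("pk_elimination", (("INH_blood", 1),), (), "d_r2"),
        Reaction("pk_infusion", (), (("INH_blood", 1),), "k_inf",
                 mass_action=()),
    ]


@pytest.fixture(scope="session")
def birth_death_network():
    """Birth-death fixture: X born at rate b, dies at rate d*X; stationary
    law is Poisson(b/d).  Carries the species the engines expect."""
    species = [
        Species("X", "protein", 0.0, scalable=True),
        Species("DSB", "damage-lesion", 0.0, scalable=False),
        Species("Caspase", "protein", 0.0, scalable=False),
        *_pk_species(),
    ]
    reactions = [
        Reaction("birth", (), (("X", 1),), "b", mass_action=()),
        Reaction("death", (("X", 1),), (), "d"),
        *_pk_reactions(),
    ]
    params = ParameterSet(dict(
        b=2.0, d=0.02, k_inf=0.0, dsb_per_gy=35.0,
        d_r1=1.0 / 3600.0, d_r2=0.25 / 3600.0,
    ))
    return ReactionNetwork(species, reactions, params)


@pytest.fixture(scope="session")
def burst_commit_network():
    """Reduced commitment fixture for scaled-vs-exact comparison.

    A slow two-state gene drives bursts of an abundant protein X; the
    'Caspase' species integrates X and latches commitment when it crosses
    the threshold.  Gene switching is the only low-copy noise source, so
    the scaled and exact paths must agree in distribution.
    """
    species = [
        Species("G_off", "DNA-state", 2.0, scalable=False),
        Species("G_on", "DNA-state", 0.0, scalable=False),
        Species("X", "protein", 0.0, scalable=True),
        Species("Caspase", "protein", 0.0, scalable=True),
        Species("DSB", "damage-lesion", 0.0, scalable=False),
        *_pk_species(),
    ]
    reactions = [
        Reaction("g_on", (("G_off", 1),), (("G_on", 1),), "q_on"),
        Reaction("g_off", (("G_on", 1),), (("G_off", 1),), "q_off"),
        Reaction("x_synth", (), (("X", 1),), "sx", mass_action=("G_on",)),
        Reaction("x_decay", (("X", 1),), (), "dx"),
        Reaction("cas_gain", (), (("Caspase", 1),), "kc", mass_action=("X",)),
        Reaction("cas_loss", (("Caspase", 1),), (), "dc"),
        *_pk_reactions(),
    ]
    params = ParameterSet(dict(
        q_on=2.0e-4, q_off=4.0e-4, sx=2.0, dx=2.0e-3, kc=1.0e-3, dc=2.0e-4,
        k_inf=0.0, dsb_per_gy=35.0, d_r1=1.0 / 3600.0, d_r2=0.25 / 3600.0,
    ))
    return ReactionNetwork(species, reactions, params)
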