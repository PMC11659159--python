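import numpy as np
import pytest

from pocketdiff.diffusion import fit_size_model
from pocketdiff.egnn import EGNNDenoiser, EgnnConfig
from pocketdiff.molsys import AtomPointCloud
from pocketdiff.schedule import build_schedule
from pocketdiff.synthdata import TEMPLATES, ToyTemplate, make_toy_complexes

#: toy training geometry: small pocket shell + wide ligand-pocket cutoff so a
#: ligand drawn from the prior is always connected to its pocket context
TOY_CUTOFFS = {"LL": 5.0, "LP": 7.0, "PP": 5.0}
TOY_TETRA = (ToyTemplate("tetra", ("C", "N", "O", "F", "C"), TEMPLATES[0].coords, 4.0),)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_cloud(rng):
    return AtomPointCloud(rng.normal(0, 2, (8, 3)), rng.normal(0, 1, (8, 10)))


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained 2-layer denoiser with a short schedule (random weights)."""
    systems, _ = make_toy_complexes(30, templates=TOY_TETRA, seed=11,
                                    jitter_sd=0.05, cutoffs=TOY_CUTOFFS)
    size_model = fit_size_model([(s.ligand.n_atoms, s.pocket.n_atoms) for s in systems])
    return EGNNDenoiser(
        config=EgnnConfig(n_layers=2, hidden_dim=32),
        d_pocket=20,
        schedule=build_schedule(30),
        size_model=size_model,
        cutoffs=TOY_CUTOFFS,
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_systems():
    systems, _ = make_toy_complexes(1000, templates=TOY_TETRA, seed=1,
                                    jitter_sd=0.05, cutoffs=TOY_CUTOFFS)
    return systems


@pytest.fixture(scope="session")
def trained_model(toy_systems):
    """2-layer width-64 conditional model trained on the toy tetra corpus.

    Shared by the inpainting, optimizer and acceptance tests; training takes
    a few minutes on one CPU.
    """
    from pocketdiff.app import train

    size_model = fit_size_model(
        [(s.ligand.n_atoms, s.pocket.n_atoms) for s in toy_systems])
    model = EGNNDenoiser(
        config=EgnnConfig(n_layers=2, hidden_dim=64),
        d_pocket=20,
        schedule=build_schedule(100),
        size_model=size_model,
        cutoffs=TOY_CUTOFFS,
        seed=0,
    )
    _, opt = train(toy_systems, model, 6000, seed=0, lr=2e-3)
    opt.lr = 5e-4
    train(toy_systems, model, 2000, seed=0, optimizer=opt, start_step=6000)
    return model
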