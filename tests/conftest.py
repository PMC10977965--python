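import numpy as np
import pytest

from hxdiff.chains import ProteinChain
from hxdiff.forward import (
    BackExchangeSpec,
    ExchangeModel,
    Peptide,
    PeptideMap,
    SimulationConfig,
    simulate_fd_reference,
    simulate_peptide_uptake,
    sliding_window_map,
)
from hxdiff.intrinsic import default_intrinsic_rates

PAPER_TIMEPOINTS = (10.0, 100.0, 300.0, 1000.0, 3000.0)


def make_chain(sequence: str, chain_id: str = "X", first: int = 1) -> ProteinChain:
    return ProteinChain(chain_id, sequence, first)


def make_uniform_model(
    chain: ProteinChain,
    states=("free", "droplet"),
    protected: dict | None = None,
    f_D2O: float = 0.75,
) -> ExchangeModel:
    """Uniform-rate model; ``protected`` maps state -> (start, end, pf)."""
    k = default_intrinsic_rates(chain, model="uniform")
    pf = {s: np.ones(len(chain)) for s in states}
    for state, (start, end, value) in (protected or {}).items():
        lo, hi = chain.index_of(start), chain.index_of(end)
        pf[state][lo : hi + 1] = value
    return ExchangeModel(chain, k, pf, f_D2O)


def single_chain_world(
    seed: int = 0,
    noise_sd: float = 0.05,
    protected=("droplet", (30, 47, 50.0)),
    n_replicates: int = 3,
    back_exchange=BackExchangeSpec("uniform", 0.10, 0.26),
    length: int = 58,
):
    """A 58-mer chain with droplet-state protection: model, map, config.

    The default emulates the design of the droplet-vs-free comparison:
    five timepoints, triplicates, 75% D2O, localized protection on the
    C-terminal half of the helix.
    """
    rng = np.random.default_rng(12345)  # sequence fixed across seeds
    aas = list("ACDEFGHIKLMNQRSTVWY")
    seq = "".join(rng.choice(aas, size=length))
    chain = make_chain(seq, "INCENP")
    prot = {protected[0]: protected[1]} if protected else None
    model = make_uniform_model(chain, protected=prot)
    pmap = sliding_window_map([chain], seed=seed)
    config = SimulationConfig(
        timepoints=PAPER_TIMEPOINTS,
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        back_exchange=back_exchange,
        random_seed=seed,
    )
    return model, pmap, config


@pytest.fixture
def world_factory():
    return single_chain_world


@pytest.fixture
def simple_peptide_map():
    chain = make_chain("GASTKLEVNDQRFYW" * 2, "X")
    return chain, PeptideMap(
        [
            Peptide("X_1_10", "X", 1, 10, chain.subsequence(1, 10), (2,)),
            Peptide("X_5_15", "X", 5, 15, chain.subsequence(5, 15), (2, 3)),
            Peptide("X_12_25", "X", 12, 25, chain.subsequence(12, 25), (2,)),
        ]
    )


def simulate_world(model, pmap, config):
    uptake = simulate_peptide_uptake(model, pmap, config)
    fd = simulate_fd_reference(model, pmap, config)
    return uptake, fd
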