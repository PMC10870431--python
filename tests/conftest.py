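"""Shared fixtures: the tiny noise-free basecalling task and a trained model.

The study task used throughout: a k=1 pore model (4 distinct current
levels), deterministic dwell of 4 samples per base, no added noise, reads of
300-500 bases cut into 240-sample chunks with 40 overlap.  Deterministic
dwell makes the task fully identifiable (with memoryless dwell, homopolymer
run lengths are not decodable from the signal alone), so it probes network
capability rather than an identifiability floor.
"""

import pytest

from picocall.arch import build_network, chain_spec
from picocall.pipeline import ChunkingConfig
from picocall.simulate import SimParams, make_pore_model, simulate_dataset, \
    simulate_reads
from picocall.training import TrainConfig, ctc_train

CHUNKING = ChunkingConfig(chunk=240, overlap=40)


def tiny_pore():
    return make_pore_model(1, 1.0, seed=7)


def tiny_params():
    return SimParams(dwell_mean=4.0, dwell_law="fixed", noise_sd=0.0,
                     read_length_law=("uniform", 300, 500), seed=11)


@pytest.fixture(scope="session")
def tiny_task():
    pore = tiny_pore()
    params = tiny_params()
    dataset = simulate_dataset(120, pore, params, CHUNKING)
    return {"pore": pore, "params": params, "chunking": CHUNKING,
            "dataset": dataset}


@pytest.fixture(scope="session")
def tiny_reads(tiny_task):
    return simulate_reads(20, tiny_task["pore"], tiny_task["params"], seed=99)


@pytest.fixture(scope="session")
def trained_net(tiny_task):
    """A 4-conv-layer network trained on the tiny task (shared, read-only)."""
    net = build_network(chain_spec([16, 32, 32, 32], kernel=9), seed=3)
    ctc_train(net, tiny_task["dataset"],
              TrainConfig(epochs=8, batch_size=32, seed=5))
    return net
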