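"""Shared fixtures: tiny synthetic references, packs and trained models.

Everything is generated programmatically at test time; session scope keeps
the expensive pieces (trained toy models) shared across tests.

The basecaller sanity substrate is a noiseless, unit-dwell, k=1 dataset on
a homopolymer-free reference: every base emits exactly one sample at one
of four distinct levels, so signal segmentation is unambiguous and a
converged model should approach perfect identity.
"""

from __future__ import annotations

import pytest

from sigfilter.siggen import (
    LengthLaw,
    build_pore_model,
    generate_dataset,
    random_reference,
)

TOY_READ_LEN = 200


@pytest.fixture(scope="session")
def small_reference() -> str:
    return random_reference(10_000, seed=7)


@pytest.fixture(scope="session")
def target_refs() -> dict[str, str]:
    return {"target": random_reference(60_000, seed=101)}


@pytest.fixture(scope="session")
def offtarget_refs() -> dict[str, str]:
    return {"decoy": random_reference(60_000, seed=202)}


@pytest.fixture(scope="session")
def pore_model_k1():
    return build_pore_model(k=1, seed=42, level_sd=0.0)


@pytest.fixture(scope="session")
def pore_model_k6():
    return build_pore_model(k=6, seed=42, level_sd=0.15)


@pytest.fixture(scope="session")
def toy_reference() -> str:
    return random_reference(5000, seed=7, homopolymer_free=True)


@pytest.fixture(scope="session")
def toy_records(pore_model_k1, toy_reference):
    """200 noiseless unit-dwell k=1 reads of 200 bp."""
    return generate_dataset(
        {"toy": toy_reference}, None, 200, 1.0, pore_model_k1,
        length_law=LengthLaw.constant(TOY_READ_LEN), seed=42, mean_dwell=1.0,
    )


@pytest.fixture(scope="session")
def toy_held_out(pore_model_k1, toy_reference):
    return generate_dataset(
        {"toy": toy_reference}, None, 30, 1.0, pore_model_k1,
        length_law=LengthLaw.constant(TOY_READ_LEN), seed=99, mean_dwell=1.0,
    )


def toy_model_config():
    from sigfilter.lightcall import ModelConfig

    return ModelConfig(n_blocks=3, width=32, kernel=9, stem_kernel=9,
                       stem_stride=1, name="toy")


def toy_train_config(**overrides):
    from sigfilter.lightcall import TrainConfig

    defaults = dict(learning_rate=4e-3, epochs=40, seed=42,
                    chunk_len=TOY_READ_LEN, batch_size=32, val_fraction=0.1)
    defaults.update(overrides)
    return TrainConfig(**defaults)


@pytest.fixture(scope="session")
def toy_trained(toy_records):
    """A converged toy model on the noiseless set (shared, seeded)."""
    from sigfilter.lightcall import train_model

    model, history = train_model(toy_model_config(), toy_train_config(),
                                 toy_records)
    return model, history
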