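"""Train a small basecaller on noiseless unit-dwell k=1 signals.

This is the package's calibration task: one sample per base at four
distinct levels on a homopolymer-free reference, so segmentation is
unambiguous and a converged model approaches perfect identity. Prints the
per-epoch CTC loss (should fall steadily) and the held-out median
identity (should exceed 0.9).
"""

import numpy as np

from sigfilter.lightcall import (
    ModelConfig,
    TrainConfig,
    basecall_read,
    train_model,
)
from sigfilter.metrics import read_identity
from sigfilter.siggen import (
    LengthLaw,
    build_pore_model,
    generate_dataset,
    random_reference,
)

pore = build_pore_model(k=1, seed=42, level_sd=0.0)
ref = random_reference(5000, seed=7, homopolymer_free=True)
law = LengthLaw.constant(200)
train = generate_dataset({"toy": ref}, None, 200, 1.0, pore,
                         length_law=law, seed=42, mean_dwell=1.0)
held = generate_dataset({"toy": ref}, None, 30, 1.0, pore,
                        length_law=law, seed=99, mean_dwell=1.0)

config = ModelConfig(n_blocks=3, width=32, kernel=9, stem_kernel=9,
                     stem_stride=1, name="toy")
train_cfg = TrainConfig(learning_rate=4e-3, epochs=40, seed=42,
                        chunk_len=200, batch_size=32)
model, history = train_model(config, train_cfg, train)
for entry in history[::8]:
    print(f"epoch {entry['epoch']:2d}  loss {entry['loss']:8.2f}  "
          f"val identity {entry['val_identity']:.3f}")

idents = [read_identity(basecall_read(model, r, chunk_len=200).sequence,
                        r.truth_seq) for r in held]
print(f"held-out median identity: {np.median(idents):.3f}")
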