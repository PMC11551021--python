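"""Simulate a ground-truthed signal pack from synthetic references.

Builds a k=6 pore model, draws a 70/30 on-/off-target read mixture, and
writes a signal pack (manifest + int16 blob + truth FASTA). The printed
numbers are the dataset composition and the mean samples-per-base, which
should sit near the configured mean dwell of 9.
"""

import tempfile
from pathlib import Path

from sigfilter.siggen import (
    LengthLaw,
    build_additive_pore_model,
    generate_dataset,
    random_reference,
)

out = Path(tempfile.mkdtemp()) / "pack"
# the additive table carries the positional structure real pores have;
# see docs/methods.md for why that matters for training
pore = build_additive_pore_model(k=6, seed=42, level_sd=0.15)
records = generate_dataset(
    target_refs={"virus": random_reference(40_000, seed=1)},
    offtarget_refs={"host": random_reference(200_000, seed=2)},
    n_reads=200,
    target_fraction=0.7,
    model=pore,
    length_law=LengthLaw.lognormal(median=1000),
    seed=42,
    out_dir=out,
)

n_on = sum(r.truth_label == "on_target" for r in records)
samples = sum(r.samples.size for r in records)
bases = sum(len(r.truth_seq) for r in records)
print(f"wrote {len(records)} reads to {out}")
print(f"on-target reads: {n_on} (expected exactly 140 = round(200 * 0.7))")
print(f"samples per base: {samples / bases:.2f} (dwell law mean is 9)")
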