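"""Score a filter run: precision/recall, identity, RA deviation.

Uses hand-built label tables so the arithmetic is transparent. The
relative-abundance deviation sums, over species, the absolute percentage
change of each species' read share after filtering; losing reads uniformly
leaves it near zero, losing one species' reads inflates it.
"""

from sigfilter.metrics import (
    precision_recall,
    ra_deviation,
    read_identity,
    relative_abundance,
)

labels = {f"r{i}": ("on_target" if i < 55 else "off_target") for i in range(100)}
truth = {f"r{i}": ("on_target" if i < 50 else "off_target") for i in range(100)}
counts, precision, recall = precision_recall(labels, truth)
print(f"confusion TP={counts.tp} FP={counts.fp} FN={counts.fn} TN={counts.tn}")
print(f"precision {precision:.3f} (50 of 55 accepted reads are truly on-target)")
print(f"recall    {recall:.3f} (all 50 on-target reads were kept)")

print(f"identity('ACGT','AGGT') = {read_identity('ACGT', 'AGGT'):.2f} "
      "(3 matching columns of 4)")

benchmark = relative_abundance({**{f"a{i}": "speciesA" for i in range(50)},
                                **{f"b{i}": "speciesB" for i in range(50)}})
filtered = relative_abundance({**{f"a{i}": "speciesA" for i in range(48)},
                               **{f"b{i}": "speciesB" for i in range(32)}})
dev = ra_deviation(filtered, benchmark)
print(f"RA deviation after biased filtering: {dev:.1f}% "
      "(speciesB lost proportionally more reads)")
print(f"RA deviation of the benchmark vs itself: "
      f"{ra_deviation(benchmark, benchmark):.1f}%")
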