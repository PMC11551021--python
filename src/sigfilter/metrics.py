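"""Evaluation metrics for pre-basecalling filtering.

Filtering quality is scored as precision and recall with the on-target
class positive; basecalling quality as the median per-read identity from a
unit-cost global alignment of the noisy read against its truth; and the
downstream effect of filtering as the relative-abundance (RA) deviation

    RA deviation = sum_i 100 * |TC_RA_i - B_RA_i| / B_RA_i

where ``B_RA_i`` is species i's share of reads in the benchmark
(unfiltered) pipeline and ``TC_RA_i`` its share after filtering.

Undefined ratios (empty denominators) are reported as ``None`` and
serialised as ``"NA"`` rather than 0, so degenerate inputs cannot silently
inflate results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping

import edlib
import numpy as np

__all__ = [
    "ConfusionCounts", "EvalReport",
    "precision_recall", "read_identity", "median_identity",
    "relative_abundance", "ra_deviation",
]

ON, OFF = "on_target", "off_target"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    precision: float | None
    recall: float | None
    median_identity: float | None
    ra_deviation: float | None
    confusion: ConfusionCounts

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("precision", "recall", "median_identity", "ra_deviation"):
            if d[key] is None:
                d[key] = "NA"
        return json.dumps(d, indent=2)


def precision_recall(
    labels: Mapping[str, str],
    truth: Mapping[str, str],
) -> tuple[ConfusionCounts, float | None, float | None]:
    """Confusion counts plus precision and recall (positive = on_target).

    ``labels`` maps read_id -> predicted label, ``truth`` maps read_id ->
    true label. Every labelled read must have a truth entry.
    """
    missing = sorted(set(labels) - set(truth))
    if missing:
        raise ValueError(f"reads missing from truth: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    tp = fp = fn = tn = 0
    for rid, lab in labels.items():
        is_pos = lab == ON
        truly_pos = truth[rid] == ON
        if is_pos and truly_pos:
            tp += 1
        elif is_pos:
            fp += 1
        elif truly_pos:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return counts, precision, recall


def read_identity(called: str, truth: str) -> float:
    """matches / alignment-columns from a unit-cost global alignment.

    An empty called sequence scores 0 by decision (the read conveys no
    usable sequence).
    """
    if not called or not truth:
        return 0.0
    res = edlib.align(called, truth, mode="NW", task="path")
    cols = 0
    for n, _op in _cigar_ops(res["cigar"]):
        cols += n
    # each non-match column (X, I, D) contributes exactly 1 to the edit
    # distance under unit costs, so matches = columns - distance
    return (cols - res["editDistance"]) / cols


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def median_identity(
    called: Mapping[str, str],
    truth: Mapping[str, str],
) -> float:
    """Median per-read identity over reads paired by read_id."""
    unpaired = sorted(set(called) - set(truth))
    if unpaired:
        raise ValueError(f"reads missing truth sequences: {unpaired[:10]}")
    if not called:
        raise ValueError("no reads to evaluate")
    idents = [read_identity(seq, truth[rid]) for rid, seq in called.items()]
    return float(np.median(idents))


def relative_abundance(assignments: Mapping[str, str]) -> dict[str, float]:
    """Per-species read proportions from a read_id -> species table."""
    if not assignments:
        raise ValueError("no assigned reads")
    counts: dict[str, int] = {}
    for sp in assignments.values():
        counts[sp] = counts.get(sp, 0) + 1
    total = sum(counts.values())
    return {sp: c / total for sp, c in sorted(counts.items())}


def ra_deviation(tc: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Summed absolute percentage deviation of relative abundances.

    Species absent from ``tc`` count as abundance 0 (contributing 100);
    a species present in ``tc`` with benchmark abundance 0 is an error,
    since its summand would divide by zero.
    """
    species = sorted(set(tc) | set(b))
    dev = 0.0
    for sp in species:
        b_ra = b.get(sp, 0.0)
        tc_ra = tc.get(sp, 0.0)
        if b_ra == 0.0:
            if tc_ra == 0.0:
                continue
            raise ValueError(
                f"species {sp!r} has zero benchmark abundance; its deviation "
                "is undefined"
            )
        dev += 100.0 * abs(tc_ra - b_ra) / b_ra
    return dev
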