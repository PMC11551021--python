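"""End-to-end pre-basecalling filter orchestration.

Every raw signal in a pack is basecalled once by LightCall, classified
once by the Similarity Check, and routed: on-target signals go to an
accepted sub-pack (and optionally on to a downstream basecaller command),
off-target signals are dropped. Noisy reads (FASTQ) and labels (TSV) are
persisted so classification can be rerun against a new target reference
without re-basecalling. Processing follows manifest order in bounded
batches; given a fixed checkpoint and inputs the run is deterministic.
"""

from __future__ import annotations

import json
import logging
import subprocess
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import signalpack, simcheck
from .lightcall import LightCallModel, basecall_read, load_checkpoint

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "run_filter", "downstream_hook"]


@dataclass
class FilterReport:
    """Per-read labels plus aggregate accept/reject counts."""

    rows: list[dict] = field(default_factory=list)
    total: int = 0
    accepted: int = 0
    rejected: int = 0

    def add(self, read_id: str, noisy_len: int, label: str, engine: str,
            n_anchors: int) -> None:
        self.rows.append({
            "read_id": read_id, "noisy_sequence_length": noisy_len,
            "label": label, "engine": engine, "n_anchors": n_anchors,
        })
        self.total += 1
        if label == "on_target":
            self.accepted += 1
        else:
            self.rejected += 1

    @property
    def labels(self) -> dict[str, str]:
        return {r["read_id"]: r["label"] for r in self.rows}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "report.json").write_text(self.to_json())
        lines = ["read_id\tlabel\tengine\tnoisy_sequence_length\tn_anchors"]
        lines += [
            "\t".join(str(r[c]) for c in
                      ("read_id", "label", "engine", "noisy_sequence_length",
                       "n_anchors"))
            for r in self.rows
        ]
        (out / "labels.tsv").write_text("\n".join(lines) + "\n")


def _write_fastq(path: Path, reads: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'!' * len(seq)}\n")


def run_filter(
    model: LightCallModel | str | Path,
    pack_dir: str | Path,
    target_refs,
    out_dir: str | Path,
    engine: str = "builtin",
    chunk_len: int = 4000,
    k: int = simcheck.DEFAULT_K,
    w: int = simcheck.DEFAULT_W,
    max_occ: int = simcheck.DEFAULT_MAX_OCC,
    min_chain: int = simcheck.DEFAULT_MIN_CHAIN,
    max_gap: int = simcheck.DEFAULT_MAX_GAP,
    downstream_cmd: str | None = None,
) -> FilterReport:
    """Basecall, classify and route every read of a signal pack.

    Writes into ``out_dir``: ``noisy.fastq`` (all noisy reads, placeholder
    quality), ``labels.tsv`` and ``report.json``, ``mappings.paf`` (builtin
    engine) and an ``accepted/`` sub-pack holding exactly the on-target
    signals, byte-identical to the input records.
    """
    if not isinstance(model, LightCallModel):
        model = load_checkpoint(model)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report = FilterReport()
    noisy: list[tuple[str, str]] = []
    paf_lines: list[str] = []

    if engine == "builtin":
        index = simcheck.build_index(target_refs, k=k, w=w, max_occ=max_occ)
        for rec in signalpack.iter_records(pack_dir):
            called = basecall_read(model, rec, chunk_len=chunk_len)
            noisy.append((rec.read_id, called.sequence))
            result = simcheck.map_read(index, called.sequence,
                                       read_id=rec.read_id,
                                       min_chain=min_chain, max_gap=max_gap)
            lab = simcheck.classify(result)
            line = simcheck.paf_line(result, index)
            if line:
                paf_lines.append(line)
            report.add(rec.read_id, len(called.sequence), lab.label,
                       lab.engine, result.n_anchors)
    elif engine == "external":
        for rec in signalpack.iter_records(pack_dir):
            called = basecall_read(model, rec, chunk_len=chunk_len)
            noisy.append((rec.read_id, called.sequence))
        _write_fastq(out / "noisy.fastq", noisy)
        ref_path = target_refs
        if not isinstance(target_refs, (str, Path)):
            ref_path = out / "target.fasta"
            with open(ref_path, "w") as fh:
                for rid, seq in target_refs.items():
                    fh.write(f">{rid}\n{seq}\n")
        paf = simcheck.run_minimap2(ref_path, out / "noisy.fastq",
                                    out / "mappings.paf")
        labels = simcheck.labels_from_paf(paf, [r for r, _ in noisy])
        lens = {rid: len(seq) for rid, seq in noisy}
        for lab in labels:
            report.add(lab.read_id, lens[lab.read_id], lab.label,
                       lab.engine, 0)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    _write_fastq(out / "noisy.fastq", noisy)
    if paf_lines:
        (out / "mappings.paf").write_text("\n".join(paf_lines) + "\n")
    report.write(out)

    accepted_ids = [r["read_id"] for r in report.rows if r["label"] == "on_target"]
    signalpack.write_subpack(pack_dir, accepted_ids, out / "accepted")
    logger.info("filter: %d total, %d accepted, %d rejected",
                report.total, report.accepted, report.rejected)

    if downstream_cmd is not None:
        downstream_hook(out / "accepted", downstream_cmd)
    return report


def downstream_hook(subpack_dir: str | Path, command: str | None = None
                    ) -> dict:
    """Hand the accepted sub-pack to a downstream basecaller command.

    ``command`` may contain ``{dir}``, replaced by the sub-pack path. With
    no command configured the sub-pack is simply left in place. The
    sub-pack is never altered; the invocation record (command, exit
    status, captured output) is returned and written alongside the pack.
    """
    subpack_dir = Path(subpack_dir)
    if not subpack_dir.exists():
        raise FileNotFoundError(f"accepted sub-pack {subpack_dir} does not exist")
    record: dict = {"subpack": str(subpack_dir), "command": command,
                    "executed": False, "returncode": None}
    if command:
        cmd = command.format(dir=str(subpack_dir))
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        record.update(executed=True, returncode=proc.returncode,
                      stdout=proc.stdout[-10000:], stderr=proc.stderr[-10000:])
        if proc.returncode != 0:
            logger.error("downstream command failed (rc=%d): %s",
                         proc.returncode, proc.stderr[-2000:])
    (subpack_dir.parent / "downstream.json").write_text(
        json.dumps(record, indent=2))
    return record
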