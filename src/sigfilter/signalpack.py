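"""Signal pack I/O: a plain-text manifest plus little-endian int16 blobs.

A pack directory holds:

``manifest.tsv``
    columns ``read_id, blob_file, byte_offset, n_samples, scale, offset,
    truth_label, truth_source, truth_start, truth_end, truth_strand``
``signals.bin``
    all samples as little-endian int16, concatenated in manifest order
``truth.fasta``
    ground-truth sequences keyed by read_id (absent for packs without truth)
``dwells.tsv``
    per-read comma-separated per-k-mer dwell counts (optional; written by
    the simulator so training can assign bases to chunks exactly)

Real values are recovered as ``stored * scale + offset``; quantisation
error is at most one digitisation step per sample.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .siggen import SignalRecord, digitisation_params

MANIFEST_COLUMNS = [
    "read_id", "blob_file", "byte_offset", "n_samples", "scale", "offset",
    "truth_label", "truth_source", "truth_start", "truth_end", "truth_strand",
]

_NA = "."


def quantize(samples: np.ndarray, scale: float, offset: float) -> np.ndarray:
    q = np.rint((np.asarray(samples, dtype=np.float64) - offset) / scale)
    return np.clip(q, -32768, 32767).astype("<i2")


def dequantize(stored: np.ndarray, scale: float, offset: float) -> np.ndarray:
    return stored.astype(np.float64) * scale + offset


def write_pack(records: Sequence[SignalRecord], out_dir: str | Path,
               blob_file: str = "signals.bin") -> Path:
    """Write records to a pack directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    seen: set[str] = set()
    blob = io.BytesIO()
    truth_fa: list[str] = []
    dwell_rows: list[str] = []
    for rec in records:
        if rec.read_id in seen:
            raise ValueError(f"duplicate read_id {rec.read_id!r}")
        seen.add(rec.read_id)
        scale, offset = rec.scale, rec.offset
        if scale is None or offset is None:
            scale, offset = digitisation_params(rec.samples)
        stored = quantize(rec.samples, scale, offset)
        start = blob.tell()
        blob.write(stored.tobytes())
        locus = rec.truth_locus or (None, None)
        rows.append({
            "read_id": rec.read_id,
            "blob_file": blob_file,
            "byte_offset": start,
            "n_samples": stored.size,
            "scale": scale,
            "offset": offset,
            "truth_label": rec.truth_label or _NA,
            "truth_source": rec.truth_source or _NA,
            "truth_start": _NA if locus[0] is None else locus[0],
            "truth_end": _NA if locus[1] is None else locus[1],
            "truth_strand": rec.truth_strand or _NA,
        })
        if rec.truth_seq is not None:
            truth_fa.append(f">{rec.read_id}\n{rec.truth_seq}\n")
        if rec.dwells is not None:
            dwell_rows.append(
                rec.read_id + "\t" + ",".join(str(int(d)) for d in rec.dwells)
            )
    (out / blob_file).write_bytes(blob.getvalue())
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )
    if truth_fa:
        (out / "truth.fasta").write_text("".join(truth_fa))
    if dwell_rows:
        (out / "dwells.tsv").write_text("\n".join(dwell_rows) + "\n")
    return out


def read_manifest(pack_dir: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(pack_dir) / "manifest.tsv", sep="\t",
                     dtype={"read_id": str}, keep_default_na=False,
                     na_values=[])
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def _read_truth(pack_dir: Path) -> dict[str, str]:
    fa = pack_dir / "truth.fasta"
    if not fa.exists():
        return {}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fa), "fasta")}


def _read_dwells(pack_dir: Path) -> dict[str, np.ndarray]:
    path = pack_dir / "dwells.tsv"
    if not path.exists():
        return {}
    out = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        rid, vals = line.split("\t")
        out[rid] = np.array([int(v) for v in vals.split(",")], dtype=np.int64)
    return out


def iter_records(pack_dir: str | Path,
                 read_ids: Iterable[str] | None = None):
    """Yield :class:`SignalRecord` objects in manifest order.

    Fails fast, naming the offending read, if a blob record is truncated.
    """
    pack_dir = Path(pack_dir)
    df = read_manifest(pack_dir)
    truth = _read_truth(pack_dir)
    dwells = _read_dwells(pack_dir)
    wanted = None if read_ids is None else set(read_ids)
    blobs: dict[str, bytes] = {}
    for row in df.itertuples(index=False):
        if wanted is not None and row.read_id not in wanted:
            continue
        if row.blob_file not in blobs:
            path = pack_dir / row.blob_file
            if not path.exists():
                raise FileNotFoundError(
                    f"blob file {row.blob_file!r} (needed by read "
                    f"{row.read_id!r}) is missing from {pack_dir}"
                )
            blobs[row.blob_file] = path.read_bytes()
        raw = blobs[row.blob_file]
        start = int(row.byte_offset)
        end = start + 2 * int(row.n_samples)
        if end > len(raw):
            raise ValueError(
                f"manifest/blob mismatch for read {row.read_id!r}: "
                f"record extends past the end of {row.blob_file!r}"
            )
        stored = np.frombuffer(raw[start:end], dtype="<i2")
        locus = None
        if str(row.truth_start) != _NA and str(row.truth_end) != _NA:
            locus = (int(row.truth_start), int(row.truth_end))
        yield SignalRecord(
            read_id=row.read_id,
            samples=dequantize(stored, float(row.scale), float(row.offset)),
            scale=float(row.scale),
            offset=float(row.offset),
            truth_seq=truth.get(row.read_id),
            truth_source=None if str(row.truth_source) == _NA else str(row.truth_source),
            truth_locus=locus,
            truth_strand=None if str(row.truth_strand) == _NA else str(row.truth_strand),
            truth_label=None if str(row.truth_label) == _NA else str(row.truth_label),
            dwells=dwells.get(row.read_id),
        )


def read_pack(pack_dir: str | Path) -> list[SignalRecord]:
    return list(iter_records(pack_dir))


def write_subpack(pack_dir: str | Path, read_ids: Sequence[str],
                  out_dir: str | Path) -> Path:
    """Copy the named records to a new pack, samples byte-identical.

    Records are re-emitted with their original int16 payloads, scales and
    offsets; only blob offsets are recomputed.
    """
    pack_dir = Path(pack_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = read_manifest(pack_dir)
    keep = df[df["read_id"].isin(set(read_ids))]
    blob = io.BytesIO()
    rows = []
    blobs: dict[str, bytes] = {}
    for row in keep.itertuples(index=False):
        if row.blob_file not in blobs:
            blobs[row.blob_file] = (pack_dir / row.blob_file).read_bytes()
        start = int(row.byte_offset)
        payload = blobs[row.blob_file][start:start + 2 * int(row.n_samples)]
        new_row = row._asdict()
        new_row["blob_file"] = "signals.bin"
        new_row["byte_offset"] = blob.tell()
        blob.write(payload)
        rows.append(new_row)
    (out / "signals.bin").write_bytes(blob.getvalue())
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )
    truth = _read_truth(pack_dir)
    kept_ids = list(keep["read_id"])
    fa = [f">{rid}\n{truth[rid]}\n" for rid in kept_ids if rid in truth]
    if fa:
        (out / "truth.fasta").write_text("".join(fa))
    dwells = _read_dwells(pack_dir)
    dw = [rid + "\t" + ",".join(str(int(d)) for d in dwells[rid])
          for rid in kept_ids if rid in dwells]
    if dw:
        (out / "dwells.tsv").write_text("\n".join(dw) + "\n")
    return out
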