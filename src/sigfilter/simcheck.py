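"""Similarity Check: on-/off-target classification of noisy reads.

A read is labelled on-target iff it maps to the target reference. The
built-in engine is a reduced-scale minimizer seed-and-chain mapper: it
sketches reference and read with (k, w) canonical minimizers, collects
shared minimizers as anchors grouped by (reference, strand), and keeps the
best co-linear chain under a per-anchor gap bound. No base-level alignment
extension is performed — the label depends only on whether a sufficiently
long chain exists, mirroring the mapped/unmapped rule.

An external-engine mode consumes mappings produced by any aligner (PAF or
SAM; a helper runs minimap2 when it is on PATH), labelling a read
on-target iff it has at least one primary, non-unmapped record.

The minimizer hash is fixed bit-exactly so indexes are reproducible across
platforms: k-mers are 2-bit packed (A=0, C=1, G=2, T=3, first base most
significant), the canonical form is the lexicographic minimum of the k-mer
and its reverse complement, and the packed 64-bit canonical code is mixed
with the splitmix64 finalizer::

    x ^= x >> 30;  x *= 0xBF58476D1CE4E5B9
    x ^= x >> 27;  x *= 0x94D049BB133111EB
    x ^= x >> 31

(all operations modulo 2^64; every step is invertible).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .siggen import load_references

__all__ = [
    "MinimizerIndex", "MappingResult", "FilterLabel",
    "extract_minimizers", "build_index", "map_read", "classify",
    "paf_line", "labels_from_paf", "labels_from_sam", "run_minimap2",
    "DEFAULT_K", "DEFAULT_W", "DEFAULT_MAX_OCC", "DEFAULT_MIN_CHAIN",
    "DEFAULT_MAX_GAP",
]

DEFAULT_K = 15
DEFAULT_W = 10
DEFAULT_MAX_OCC = 500
DEFAULT_MIN_CHAIN = 5
DEFAULT_MAX_GAP = 500

_U64 = np.uint64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = x.astype(_U64, copy=True)
    with np.errstate(over="ignore"):
        x ^= x >> _U64(30)
        x *= _U64(0xBF58476D1CE4E5B9)
        x ^= x >> _U64(27)
        x *= _U64(0x94D049BB133111EB)
        x ^= x >> _U64(31)
    return x


def _encode_acgt(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(forward, reverse-complement, valid) packed codes of all k-mers."""
    n = codes.size - k + 1
    win = sliding_window_view(codes, k).astype(np.uint64)
    valid = ~(win == 255).any(axis=1)
    win_masked = np.where(win == 255, 0, win)
    shifts = (_U64(2) * np.arange(k - 1, -1, -1, dtype=_U64))
    with np.errstate(over="ignore"):
        fwd = (win_masked << shifts[None, :]).sum(axis=1, dtype=_U64)
        rc_win = (_U64(3) - win_masked)[:, ::-1]
        rc = (rc_win << shifts[None, :]).sum(axis=1, dtype=_U64)
    return fwd, rc, valid


def extract_minimizers(seq: str, k: int = DEFAULT_K, w: int = DEFAULT_W
                       ) -> list[tuple[int, int, str]]:
    """(hash, position, strand) minimizers of every w-k-mer window.

    For each window of ``w`` consecutive k-mers the k-mer with the minimal
    hash of its canonical form is reported once; ties within a window keep
    the leftmost occurrence. The strand records whether the forward
    (``+``) or reverse-complement (``-``) form was canonical. Sequences
    shorter than ``k`` yield an empty list; sequences with fewer than ``w``
    k-mers use a single window covering all of them.
    """
    codes = _encode_acgt(seq)
    if codes.size < k:
        return []
    fwd, rc, valid = _kmer_codes(codes, k)
    canonical = np.minimum(fwd, rc)
    strand_fwd = fwd <= rc
    hashes = _splitmix64(canonical)
    hashes[~valid] = np.iinfo(np.uint64).max
    m = hashes.size
    if m <= w:
        picks = np.array([int(np.argmin(hashes))])
    else:
        windows = sliding_window_view(hashes, w)
        picks = np.unique(windows.argmin(axis=1) + np.arange(m - w + 1))
    out = []
    for p in picks:
        p = int(p)
        if not valid[p]:
            continue
        out.append((int(hashes[p]), p, "+" if strand_fwd[p] else "-"))
    return out


@dataclass
class MinimizerIndex:
    """Minimizer sketch of a reference set.

    ``table`` maps canonical hash -> sorted list of (reference id,
    position, strand); hashes occurring more than ``max_occ`` times in
    total are masked (absent).
    """

    k: int
    w: int
    max_occ: int
    table: dict[int, list[tuple[str, int, str]]]
    ref_lengths: dict[str, int] = field(default_factory=dict)


def build_index(refs, k: int = DEFAULT_K, w: int = DEFAULT_W,
                max_occ: int = DEFAULT_MAX_OCC) -> MinimizerIndex:
    """Index all minimizers of a FASTA (path) or {id: seq} mapping."""
    seqs = load_references(refs)
    if not seqs:
        raise ValueError("no reference sequences to index")
    table: dict[int, list[tuple[str, int, str]]] = {}
    ref_lengths = {}
    for rid, seq in seqs.items():
        ref_lengths[rid] = len(seq)
        for h, pos, strand in extract_minimizers(seq, k, w):
            table.setdefault(h, []).append((rid, pos, strand))
    table = {h: sorted(v) for h, v in table.items() if len(v) <= max_occ}
    return MinimizerIndex(k=k, w=w, max_occ=max_occ, table=table,
                          ref_lengths=ref_lengths)


@dataclass
class MappingResult:
    """Best co-linear anchor chain of a read against the index."""

    read_id: str
    mapped: bool
    n_anchors: int = 0
    ref_id: str | None = None
    ref_span: tuple[int, int] | None = None
    read_span: tuple[int, int] | None = None
    strand: str | None = None
    read_length: int = 0


@dataclass(frozen=True)
class FilterLabel:
    read_id: str
    label: str  # on_target | off_target
    engine: str = "builtin"


def _best_chain(qpos: np.ndarray, rpos: np.ndarray, max_gap: int) -> tuple[int, np.ndarray]:
    """Longest co-linear chain by quadratic DP with a per-anchor gap bound.

    Anchors must be pre-sorted by (qpos, rpos); returns (length, member
    indices of one optimal chain).
    """
    n = qpos.size
    f = np.ones(n, dtype=np.int64)
    back = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        dq = qpos[i] - qpos[:i]
        dr = rpos[i] - rpos[:i]
        ok = (dq > 0) & (dr > 0) & (dq <= max_gap) & (dr <= max_gap)
        if ok.any():
            cand = np.where(ok, f[:i], 0)
            j = int(np.argmax(cand))
            if cand[j] > 0:
                f[i] = cand[j] + 1
                back[i] = j
    best = int(np.argmax(f))
    chain = []
    i = best
    while i != -1:
        chain.append(i)
        i = int(back[i])
    return int(f[best]), np.array(chain[::-1], dtype=np.int64)


def map_read(index: MinimizerIndex, read: str, read_id: str = "read",
             min_chain: int = DEFAULT_MIN_CHAIN,
             max_gap: int = DEFAULT_MAX_GAP,
             max_anchors_per_group: int = 5000) -> MappingResult:
    """Seed-and-chain the read against the index.

    Anchors are shared minimizers grouped by (reference, relative strand);
    within each group the longest chain of co-linear anchors (monotone in
    both coordinates, per-step gaps bounded by ``max_gap``) is found and
    the highest-anchor-count chain wins. ``mapped`` is true iff that chain
    has at least ``min_chain`` anchors (inclusive boundary). Unmappable
    reads are returned with ``mapped=False``, never as an error.
    """
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h, qpos, qstrand in extract_minimizers(read, index.k, index.w):
        for rid, rpos, rstrand in index.table.get(h, ()):
            rel = "+" if qstrand == rstrand else "-"
            groups.setdefault((rid, rel), []).append((qpos, rpos))

    best = MappingResult(read_id=read_id, mapped=False, read_length=len(read))
    for (rid, rel), anchors in sorted(groups.items()):
        anchors = anchors[:max_anchors_per_group]
        qpos = np.array([a[0] for a in anchors])
        rpos = np.array([a[1] for a in anchors])
        if rel == "-":
            # on the minus strand reference positions decrease along the read
            order = np.lexsort((-rpos, qpos))
            n, chain = _best_chain(qpos[order], -rpos[order], max_gap)
        else:
            order = np.lexsort((rpos, qpos))
            n, chain = _best_chain(qpos[order], rpos[order], max_gap)
        if n > best.n_anchors:
            members = order[chain]
            r_lo = int(rpos[members].min())
            r_hi = int(rpos[members].max()) + index.k
            q_lo = int(qpos[members].min())
            q_hi = int(qpos[members].max()) + index.k
            best = MappingResult(
                read_id=read_id, mapped=False, n_anchors=n, ref_id=rid,
                ref_span=(r_lo, r_hi), read_span=(q_lo, q_hi), strand=rel,
                read_length=len(read),
            )
    if best.n_anchors >= min_chain:
        best.mapped = True
    else:
        best = MappingResult(read_id=read_id, mapped=False,
                             n_anchors=best.n_anchors, read_length=len(read))
    return best


def classify(result: MappingResult, engine: str = "builtin") -> FilterLabel:
    """on_target iff the read mapped; any qualifying mapping suffices."""
    label = "on_target" if result.mapped else "off_target"
    return FilterLabel(read_id=result.read_id, label=label, engine=engine)


# ---------------------------------------------------------------------------
# interchange formats / external engine
# ---------------------------------------------------------------------------

def paf_line(result: MappingResult, index: MinimizerIndex) -> str | None:
    """Render a mapped result as one PAF line (placeholder quality 255)."""
    if not result.mapped:
        return None
    q_lo, q_hi = result.read_span
    r_lo, r_hi = result.ref_span
    block = max(q_hi - q_lo, r_hi - r_lo)
    return "\t".join(str(x) for x in (
        result.read_id, result.read_length, q_lo, q_hi, result.strand,
        result.ref_id, index.ref_lengths.get(result.ref_id, 0), r_lo, r_hi,
        result.n_anchors, block, 255,
    ))


def labels_from_paf(paf: str | Path, read_ids: Iterable[str]) -> list[FilterLabel]:
    """A read is on-target iff it has >= 1 mapping line in the PAF."""
    mapped: set[str] = set()
    for line in Path(paf).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) >= 12 and fields[5] != "*":
            mapped.add(fields[0])
    return [FilterLabel(rid, "on_target" if rid in mapped else "off_target",
                        engine="external") for rid in read_ids]


def labels_from_sam(sam: str | Path, read_ids: Iterable[str]) -> list[FilterLabel]:
    """A read is on-target iff it has >= 1 primary, non-unmapped record."""
    import pysam

    mapped: set[str] = set()
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mapped.add(rec.query_name)
    return [FilterLabel(rid, "on_target" if rid in mapped else "off_target",
                        engine="external") for rid in read_ids]


def run_minimap2(ref_fasta: str | Path, reads_fastq: str | Path,
                 out_paf: str | Path, preset: str = "map-ont") -> Path:
    """Run minimap2 (must be on PATH) and return the PAF path."""
    exe = shutil.which("minimap2")
    if exe is None:
        raise RuntimeError("minimap2 not found on PATH; use the builtin engine")
    with open(out_paf, "w") as fh:
        subprocess.run([exe, "-x", preset, str(ref_fasta), str(reads_fastq)],
                       stdout=fh, stderr=subprocess.DEVNULL, check=True)
    return Path(out_paf)
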