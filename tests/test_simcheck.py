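"""Minimizer extraction, indexing, mapping and classification."""

import shutil

import numpy as np
import pytest

from sigfilter import simcheck as sc
from sigfilter.siggen import random_reference, reverse_complement


def brute_force_minimizers(seq, k, w):
    """Independent all-windows scan using the same hash primitive."""
    if len(seq) < k:
        return []
    hashes = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        canon = min(kmer, reverse_complement(kmer))
        code = 0
        for ch in canon:
            code = code * 4 + "ACGT".index(ch)
        h = int(sc._splitmix64(np.array([code], dtype=np.uint64))[0])
        hashes.append((h, i, "+" if kmer <= reverse_complement(kmer) else "-"))
    m = len(hashes)
    picked = set()
    if m <= w:
        picked.add(min(range(m), key=lambda i: (hashes[i][0], i)))
    else:
        for start in range(m - w + 1):
            window = range(start, start + w)
            picked.add(min(window, key=lambda i: (hashes[i][0], i)))
    return sorted(hashes[i] for i in picked)


def corrupt(seq, rate, rng):
    """i.i.d. substitution/insertion/deletion noise at the given total rate."""
    out = []
    for ch in seq:
        u = rng.random()
        if u < rate * 0.4:
            continue
        if u < rate * 0.7:
            out.append("ACGT"[rng.integers(4)])
        elif u < rate:
            out.append(ch)
            out.append("ACGT"[rng.integers(4)])
        else:
            out.append(ch)
    return "".join(out)


class TestExtractMinimizers:
    def test_sequence_of_length_k_yields_single_minimizer_at_origin(self):
        mins = sc.extract_minimizers("ACGTTGCACGTAGCA", k=15, w=10)
        assert len(mins) == 1
        assert mins[0][1] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_window_scan(self, seed):
        seq = random_reference(200, seed=seed)
        ours = sorted(sc.extract_minimizers(seq, k=15, w=10))
        assert ours == brute_force_minimizers(seq, 15, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_hash_set_is_strand_symmetric(self, seed):
        seq = random_reference(300, seed=seed)
        fwd = {h for h, _, _ in sc.extract_minimizers(seq)}
        rev = {h for h, _, _ in sc.extract_minimizers(reverse_complement(seq))}
        assert fwd == rev

    def test_too_short_sequence_yields_empty_list(self):
        assert sc.extract_minimizers("ACGT", k=15, w=10) == []


class TestBuildIndex:
    def test_poly_a_reference_is_fully_masked(self):
        idx = sc.build_index({"polyA": "A" * 5000}, max_occ=10)
        assert idx.table == {}

    def test_every_reference_minimizer_is_retrievable(self):
        ref = random_reference(5000, seed=3)
        idx = sc.build_index({"r": ref})
        for h, pos, strand in sc.extract_minimizers(ref):
            assert ("r", pos, strand) in idx.table[h]

    def test_positions_carry_reference_ids(self):
        refs = {"a": random_reference(3000, seed=1),
                "b": random_reference(3000, seed=2)}
        idx = sc.build_index(refs)
        rids = {rid for hits in idx.table.values() for rid, _, _ in hits}
        assert rids == {"a", "b"}

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            sc.build_index({})


@pytest.fixture(scope="module")
def index():
    return sc.build_index({"tgt": random_reference(50_000, seed=5)})


class TestMapRead:

    def test_exact_substring_maps_to_true_locus(self, index):
        ref = random_reference(50_000, seed=5)
        res = sc.map_read(index, ref[10_000:11_000])
        assert res.mapped and res.strand == "+"
        lo, hi = res.ref_span
        assert abs(lo - 10_000) <= index.k - 1
        assert abs(hi - 11_000) <= index.k - 1

    def test_reverse_complement_maps_to_same_locus_minus_strand(self, index):
        ref = random_reference(50_000, seed=5)
        res = sc.map_read(index, reverse_complement(ref[10_000:11_000]))
        assert res.mapped and res.strand == "-"
        lo, hi = res.ref_span
        assert abs(lo - 10_000) <= index.k - 1
        assert abs(hi - 11_000) <= index.k - 1

    def test_random_read_does_not_map(self, index):
        for seed in range(20):
            res = sc.map_read(index, random_reference(1000, seed=1000 + seed))
            assert not res.mapped

    def test_sensitivity_on_clean_500bp_reads(self, index):
        ref = random_reference(50_000, seed=5)
        rng = np.random.default_rng(0)
        n = 200
        starts = rng.integers(0, len(ref) - 500, size=n)
        mapped = sum(
            sc.map_read(index, ref[s:s + 500]).mapped for s in starts)
        assert mapped == n

    def test_sensitivity_with_10pct_errors_at_1kb(self, index):
        ref = random_reference(50_000, seed=5)
        rng = np.random.default_rng(7)
        n = 100
        ok = 0
        for _ in range(n):
            s = rng.integers(0, len(ref) - 1000)
            ok += sc.map_read(index, corrupt(ref[s:s + 1000], 0.10, rng)).mapped
        assert ok / n >= 0.95

    def test_specificity_against_unrelated_reference(self):
        idx = sc.build_index({"t": random_reference(100_000, seed=21)})
        decoy = random_reference(1_000_000, seed=22)
        rng = np.random.default_rng(1)
        n = 200
        starts = rng.integers(0, len(decoy) - 800, size=n)
        fp = sum(sc.map_read(idx, decoy[s:s + 800]).mapped for s in starts)
        assert fp / n < 0.01


class TestClassify:
    def test_unmapped_is_off_target(self):
        res = sc.MappingResult(read_id="r", mapped=False)
        assert sc.classify(res).label == "off_target"

    def test_min_chain_boundary_is_inclusive(self):
        ref = random_reference(50_000, seed=5)
        idx = sc.build_index({"t": ref})
        res = sc.map_read(idx, ref[500:2000])
        assert res.mapped
        # exactly min_chain anchors must classify on-target
        res_exact = sc.map_read(idx, ref[500:2000],
                                min_chain=res.n_anchors)
        assert sc.classify(res_exact).label == "on_target"
        res_above = sc.map_read(idx, ref[500:2000],
                                min_chain=res.n_anchors + 1)
        assert sc.classify(res_above).label == "off_target"


class TestExternalEngine:
    def test_paf_line_has_twelve_fields(self):
        ref = random_reference(20_000, seed=9)
        idx = sc.build_index({"t": ref})
        res = sc.map_read(idx, ref[2000:3000], read_id="q1")
        line = sc.paf_line(res, idx)
        fields = line.split("\t")
        assert len(fields) == 12
        assert fields[0] == "q1" and fields[5] == "t" and fields[4] == "+"

    def test_sam_labels_use_primary_non_unmapped_records(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@SQ\tSN:t\tLN:1000\n"
            "r1\t0\tt\t100\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"      # primary
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"          # unmapped
            "r3\t256\tt\t200\t0\t10M\t*\t0\t0\tACGTACGTAC\t*\n"    # secondary only
        )
        labels = {l.read_id: l.label
                  for l in sc.labels_from_sam(sam, ["r1", "r2", "r3"])}
        assert labels == {"r1": "on_target", "r2": "off_target",
                          "r3": "off_target"}

    @pytest.mark.skipif(shutil.which("minimap2") is None,
                        reason="minimap2 not on PATH")
    def test_external_and_builtin_engines_agree(self, tmp_path):
        rng = np.random.default_rng(11)
        target = random_reference(80_000, seed=31)
        decoy = random_reference(80_000, seed=32)
        reads, truth = [], []
        for i in range(60):
            src = target if i % 2 == 0 else decoy
            s = rng.integers(0, len(src) - 900)
            reads.append((f"r{i}", corrupt(src[s:s + 900], 0.10, rng)))
            truth.append(i % 2 == 0)
        ref_fa = tmp_path / "t.fasta"
        ref_fa.write_text(f">t\n{target}\n")
        fq = tmp_path / "reads.fastq"
        with open(fq, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'!' * len(seq)}\n")
        paf = sc.run_minimap2(ref_fa, fq, tmp_path / "out.paf")
        ext = {l.read_id: l.label
               for l in sc.labels_from_paf(paf, [r for r, _ in reads])}
        idx = sc.build_index({"t": target})
        builtin = {rid: sc.classify(sc.map_read(idx, seq, read_id=rid)).label
                   for rid, seq in reads}
        agree = sum(ext[r] == builtin[r] for r in ext) / len(ext)
        assert agree >= 0.95
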