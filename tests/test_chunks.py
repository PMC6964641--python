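"""Map-phase machinery: sorted spills, recursive merging, the global merge."""

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xrefdb import chunks as ch
from xrefdb.model import EntryPayload, encode_value, merge_payload_lists


def P(ident: str, ds: int = 1, **attrs) -> EntryPayload:
    return EntryPayload(ds, ident, dict(attrs))


def rows_of(chunk):
    return list(ch.read_chunk(chunk))


def naive_scan_min_merge(chunk_list):
    """Independent oracle: repeatedly take the minimum head across runs."""
    streams = [list(ch.read_chunk(c)) for c in chunk_list]
    out = []
    while any(streams):
        key = min(s[0][0] for s in streams if s)
        payloads = []
        for s in streams:
            while s and s[0][0] == key:
                payloads = merge_payload_lists(payloads, s.pop(0)[1])
        out.append((key, payloads))
    return out


def in_memory_reference(pairs):
    """Sort + merge wholly in memory, independent of the chunk code path."""
    by_key = {}
    for key, payload in pairs:
        by_key.setdefault(key, []).append(payload)
    return [(k, merge_payload_lists(by_key[k])) for k in sorted(by_key)]


def random_pairs(rng, n, key_space=200):
    return [
        (f"K{rng.randrange(key_space):04d}", P(f"ID{rng.randrange(key_space)}", rng.randint(1, 3), v=rng.randint(0, 9)))
        for _ in range(n)
    ]


class TestSpill:
    def test_sort_and_same_key_merge(self, tmp_path):
        p1, p2, p3 = P("b1"), P("a1", v=1), P("a2")
        chunk = ch.spill_chunk([("B", p1), ("A", p2), ("A", p3)], str(tmp_path))
        rows = rows_of(chunk)
        assert [r[0] for r in rows] == ["A", "B"]
        assert rows[0][1] == merge_payload_lists([p2, p3])
        assert (chunk.min_key, chunk.max_key, chunk.record_count) == ("A", "B", 2)

    def test_single_record(self, tmp_path):
        chunk = ch.spill_chunk([("X", P("x"))], str(tmp_path))
        assert chunk.min_key == chunk.max_key == "X"

    def test_empty_buffer_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            ch.spill_chunk([], str(tmp_path))

    def test_50k_against_in_memory_sort(self, tmp_path):
        rng = random.Random(5)
        pairs = random_pairs(rng, 50_000, key_space=5_000)
        chunk = ch.spill_chunk(pairs, str(tmp_path))
        assert rows_of(chunk) == in_memory_reference(pairs)


class TestMerge:
    def test_interleave(self, tmp_path):
        c1 = ch.spill_chunk([("A", P("a")), ("C", P("c"))], str(tmp_path))
        c2 = ch.spill_chunk([("B", P("b"))], str(tmp_path))
        merged = ch.merge_chunks([c1, c2], str(tmp_path))
        assert [r[0] for r in rows_of(merged)] == ["A", "B", "C"]
        assert merged.generation == 1

    def test_identity(self, tmp_path):
        pairs = [("A", P("a")), ("B", P("b"))]
        before = rows_of(ch.spill_chunk(pairs, str(tmp_path)))
        merged = ch.merge_chunks([ch.spill_chunk(pairs, str(tmp_path))], str(tmp_path))
        assert rows_of(merged) == before

    def test_eight_chunks_vs_oracles(self, tmp_path):
        rng = random.Random(17)
        all_pairs = []
        chunk_list = []
        for _ in range(8):
            pairs = random_pairs(rng, 400)
            all_pairs.extend(pairs)
            chunk_list.append(ch.spill_chunk(pairs, str(tmp_path)))
        scan_min = naive_scan_min_merge(chunk_list)
        merged = ch.merge_chunks(chunk_list, str(tmp_path))
        rows = rows_of(merged)
        assert rows == in_memory_reference(all_pairs)
        assert rows == scan_min

    def test_unsorted_chunk_detected(self, tmp_path):
        chunk = ch.spill_chunk([("A", P("a")), ("B", P("b"))], str(tmp_path))
        lines = open(chunk.path).read().splitlines()
        lines[1], lines[2] = lines[2], lines[1]
        open(chunk.path, "w").write("\n".join(lines) + "\n")
        with pytest.raises(ch.ChunkCorruptionError) as err:
            list(ch.read_chunk(chunk))
        assert chunk.path in str(err.value)


class TestGlobalMerge:
    def test_cross_chunk_key_merge(self, tmp_path):
        c1 = ch.spill_chunk([("A", P("x1")), ("B", P("x2"))], str(tmp_path))
        c2 = ch.spill_chunk([("A", P("x3", 2)), ("C", P("x4"))], str(tmp_path))
        rows = list(ch.global_merge([c1, c2]))
        assert [r[0] for r in rows] == ["A", "B", "C"]
        assert rows[0][1] == merge_payload_lists([P("x1"), P("x3", 2)])

    def test_empty(self):
        assert list(ch.global_merge([])) == []

    @settings(max_examples=25)
    @given(data=st.data())
    def test_permutation_invariance(self, data, tmp_path_factory):
        """Any partition into buffers, merged in any order, yields the same
        byte stream after value encoding."""
        rng = random.Random(data.draw(st.integers(0, 10**6)))
        pairs = random_pairs(rng, 120, key_space=25)
        reference = [(k, encode_value(v)) for k, v in in_memory_reference(pairs)]
        for _ in range(3):
            tmp = str(tmp_path_factory.mktemp("perm"))
            shuffled = pairs[:]
            rng.shuffle(shuffled)
            cuts = sorted(rng.sample(range(1, len(shuffled)), k=rng.randint(1, 5)))
            buffers = [shuffled[i:j] for i, j in zip([0] + cuts, cuts + [len(shuffled)])]
            chunk_list = [ch.spill_chunk(b, tmp) for b in buffers if b]
            rng.shuffle(chunk_list)
            got = [(k, encode_value(v)) for k, v in ch.global_merge(chunk_list)]
            assert got == reference

    def test_recursive_fan2_equals_flat_merge(self, tmp_path):
        rng = random.Random(99)
        pairs = random_pairs(rng, 3_000, key_space=300)
        flat_dir = tmp_path / "flat"
        rec_dir = tmp_path / "rec"
        flat_dir.mkdir(), rec_dir.mkdir()
        mgr_flat = ch.ChunkManager(str(flat_dir), buffer_size=100,
                                   plan=ch.MergePlan(fan_in=10**6, worker_count=1))
        mgr_rec = ch.ChunkManager(str(rec_dir), buffer_size=100,
                                  plan=ch.MergePlan(fan_in=2, worker_count=1))
        for key, payload in pairs:
            mgr_flat.add(key, payload)
            mgr_rec.add(key, payload)
        flat = [(k, encode_value(v)) for k, v in mgr_flat.stream()]
        rec = [(k, encode_value(v)) for k, v in mgr_rec.stream()]
        assert mgr_rec.merges_done > 0
        assert flat == rec == [(k, encode_value(v)) for k, v in in_memory_reference(pairs)]


class TestChunkManager:
    def test_buffer_bound_and_spill_count(self, tmp_path):
        mgr = ch.ChunkManager(str(tmp_path), buffer_size=50)
        for i in range(500):
            mgr.add(f"K{i:04d}", P(f"id{i}"))
        mgr.finalize()
        assert mgr.peak_buffered_records <= 50
        assert mgr.chunks_spilled == 10

    def test_worker_counts_agree(self, tmp_path):
        rng = random.Random(3)
        pairs = random_pairs(rng, 4_000, key_space=400)
        results = []
        for workers, sub in ((1, "w1"), (4, "w4")):
            mgr = ch.ChunkManager(str(tmp_path / sub), buffer_size=200,
                                  plan=ch.MergePlan(fan_in=3, worker_count=workers))
            for key, payload in pairs:
                mgr.add(key, payload)
            results.append([(k, encode_value(v)) for k, v in mgr.stream()])
        assert results[0] == results[1]

    def test_conservation_of_keys_and_xrefs(self, tmp_path):
        rng = random.Random(11)
        pairs = []
        for i in range(2_000):
            p = EntryPayload(1, f"ID{i % 350}", {}, [("go", f"GO:{i:04d}")])
            pairs.append((f"K{i % 350:03d}", p))
        mgr = ch.ChunkManager(str(tmp_path), buffer_size=128)
        for key, payload in pairs:
            mgr.add(key, payload)
        rows = list(mgr.stream())
        assert {r[0] for r in rows} == {k for k, _ in pairs}
        emitted = {(k, x) for k, p in pairs for x in p.xrefs}
        stored = {(k, x) for k, ps in rows for p in ps for x in p.xrefs}
        assert stored == emitted
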