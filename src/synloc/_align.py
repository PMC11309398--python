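"""Ungapped (Hamming) full-length read alignment with pigeonhole seeding.

Junction-spanning reads in the simulation model are exact substrings of a
reference with i.i.d. substitution errors, so alignment is ungapped by
construction: a read maps at offset p of a reference sequence iff the two
strings agree at all but at most ``max_mismatch`` positions over the full
read length. Both orientations of the read are tried.

Seeding uses the pigeonhole principle: a read split into ``max_mismatch + 1``
disjoint chunks must have at least one chunk that matches the reference
exactly, so candidate offsets come from an exact k-mer index and are verified
with a vectorized Hamming comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class Hit:
    """One qualifying alignment of a read against a reference sequence."""

    ref_id: str
    pos: int
    strand: str  # '+' read as given, '-' reverse complement
    mismatches: int


class UngappedIndex:
    """Exact k-mer index over a set of reference sequences.

    Parameters
    ----------
    refs
        Mapping of reference id to nucleotide string (A/C/G/T/N).
    """

    def __init__(self, refs: Mapping[str, str]):
        self._ids = list(refs)
        self._seqs = {rid: str(refs[rid]) for rid in self._ids}
        self._arrs = {rid: _encode(s) for rid, s in self._seqs.items()}
        self._kmer_index: dict[int, dict[bytes, list[tuple[str, int]]]] = {}

    @property
    def ref_ids(self) -> list[str]:
        return list(self._ids)

    def ref_length(self, ref_id: str) -> int:
        return len(self._seqs[ref_id])

    def max_ref_length(self) -> int:
        return max((len(s) for s in self._seqs.values()), default=0)

    def _index_for(self, k: int) -> dict[bytes, list[tuple[str, int]]]:
        if k not in self._kmer_index:
            idx: dict[bytes, list[tuple[str, int]]] = defaultdict(list)
            for rid, seq in self._seqs.items():
                b = seq.encode("ascii")
                for pos in range(len(b) - k + 1):
                    idx[b[pos : pos + k]].append((rid, pos))
            self._kmer_index[k] = dict(idx)
        return self._kmer_index[k]

    def _candidates(self, read: str, max_mismatch: int) -> set[tuple[str, int]]:
        length = len(read)
        n_chunks = max_mismatch + 1
        k = length // n_chunks
        if k < 1:
            # degenerate: read shorter than chunk count; scan every offset
            return {
                (rid, pos)
                for rid, seq in self._seqs.items()
                for pos in range(len(seq) - length + 1)
            }
        idx = self._index_for(k)
        b = read.encode("ascii")
        cands: set[tuple[str, int]] = set()
        for i in range(n_chunks):
            off = i * k
            for rid, pos in idx.get(b[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + length <= len(self._seqs[rid]):
                    cands.add((rid, start))
        return cands

    def search(
        self, read: str, max_mismatch: int, both_strands: bool = True
    ) -> list[Hit]:
        """All full-length ungapped alignments with <= max_mismatch mismatches.

        Hits are deduplicated on (ref_id, pos, strand) and returned sorted by
        (mismatches, ref_id, pos, strand) so the best hit comes first.
        """
        hits: list[Hit] = []
        orientations = [("+", read)]
        if both_strands:
            orientations.append(("-", reverse_complement(read)))
        for strand, oriented in orientations:
            arr = _encode(oriented)
            for rid, start in self._candidates(oriented, max_mismatch):
                ref = self._arrs[rid]
                mm = int((ref[start : start + len(arr)] != arr).sum())
                if mm <= max_mismatch:
                    hits.append(Hit(rid, start, strand, mm))
        hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.pos, h.strand))
        return hits

    def has_hit(self, read: str, max_mismatch: int, both_strands: bool = True) -> bool:
        """True iff the read has at least one full-length alignment."""
        if len(read) > self.max_ref_length():
            return False
        for strand, oriented in (
            [("+", read), ("-", reverse_complement(read))]
            if both_strands
            else [("+", read)]
        ):
            arr = _encode(oriented)
            for rid, start in self._candidates(oriented, max_mismatch):
                ref = self._arrs[rid]
                if int((ref[start : start + len(arr)] != arr).sum()) <= max_mismatch:
                    return True
        return False
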