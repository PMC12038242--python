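"""Exact k-mer index over a set of named sequences.

Sequences are 2-bit encoded and every k-mer code is kept in one sorted
array, so a lookup is two binary searches (forward code and
reverse-complement code).  This is the only alignment data structure the
pipeline uses: detectors and the quantifier both work by exact-seed lookup
followed by full-length mismatch verification against the stored
sequences.  k is capped at 31 so a code fits a 64-bit integer.
"""

from __future__ import annotations

import numpy as np

from .synth.genome import revcomp

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Sequence -> uint8 array of 2-bit base codes (255 for non-ACGT)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class KmerIndex:
    """Sorted-array index of all k-mers of a collection of sequences.

    ``lookup`` returns hits as ``(seq_name, position, strand)`` where
    strand '+' means the query matches the stored sequence as-is and '-'
    means the reverse complement of the query matches at that position.
    """

    def __init__(self, sequences: dict[str, str], k: int):
        if not 4 <= k <= 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.sequences = dict(sequences)
        self.names = list(sequences)
        self._encoded = {n: encode_seq(s) for n, s in sequences.items()}

        codes_parts: list[np.ndarray] = []
        pos_parts: list[np.ndarray] = []
        sid_parts: list[np.ndarray] = []
        for sid, name in enumerate(self.names):
            b = self._encoded[name]
            n = b.size - k + 1
            if n <= 0:
                continue
            valid = np.ones(n, dtype=bool)
            bad = np.nonzero(b == 255)[0]
            for p in bad:
                valid[max(0, p - k + 1) : p + 1] = False
            c = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                c = (c << np.uint64(2)) | b[j : j + n].astype(np.uint64)
            codes_parts.append(c[valid])
            pos_parts.append(np.nonzero(valid)[0].astype(np.int64))
            sid_parts.append(np.full(int(valid.sum()), sid, dtype=np.int32))
        if codes_parts:
            codes = np.concatenate(codes_parts)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_parts)[order]
            self._sid = np.concatenate(sid_parts)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._pos = np.empty(0, dtype=np.int64)
            self._sid = np.empty(0, dtype=np.int32)

    def _encode_query(self, kmer: str) -> int | None:
        b = encode_seq(kmer)
        if b.size != self.k or (b == 255).any():
            return None
        code = 0
        for v in b:
            code = (code << 2) | int(v)
        return code

    def _find(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._codes, np.uint64(code), side="left")
        hi = np.searchsorted(self._codes, np.uint64(code), side="right")
        return self._pos[lo:hi], self._sid[lo:hi]

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All exact placements of ``kmer`` on both strands."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        hits: list[tuple[str, int, str]] = []
        code = self._encode_query(kmer)
        if code is not None:
            pos, sid = self._find(code)
            hits.extend((self.names[s], int(p), "+") for p, s in zip(pos, sid))
        rc_code = self._encode_query(revcomp(kmer))
        if rc_code is not None and rc_code != code:
            pos, sid = self._find(rc_code)
            hits.extend((self.names[s], int(p), "-") for p, s in zip(pos, sid))
        elif rc_code is not None and rc_code == code:  # palindromic k-mer
            pos, sid = self._find(rc_code)
            hits.extend((self.names[s], int(p), "-") for p, s in zip(pos, sid))
        return hits

    def lookup_forward(self, kmer: str) -> list[tuple[str, int]]:
        """Placements where the query matches the stored strand as-is."""
        code = self._encode_query(kmer)
        if code is None:
            return []
        pos, sid = self._find(code)
        return [(self.names[s], int(p)) for p, s in zip(pos, sid)]

    def mismatch_profile(self, name: str, pos: int, query_codes: np.ndarray) -> np.ndarray | None:
        """Boolean mismatch vector of an encoded query laid at ``pos``.

        Returns None when the placement runs outside the sequence.
        """
        ref = self._encoded[name]
        if pos < 0 or pos + query_codes.size > ref.size:
            return None
        return ref[pos : pos + query_codes.size] != query_codes

    def count_mismatches(self, name: str, pos: int, query: str) -> int | None:
        prof = self.mismatch_profile(name, pos, encode_seq(query))
        return None if prof is None else int(prof.sum())
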