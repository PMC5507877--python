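"""Adapter scanning and read deconcatenation.

The scanner slides a fixed-length window (the adapter length, 30 bp by
default) along each read and computes the unit-cost Levenshtein distance
between the window and the adapter in both orientations.  Semantics are
greedy and leftmost: at position ``p`` the window ``read[p:p+w]`` is tested;
if the smaller of the forward/reverse-complement distances is at most
``max_edits`` the scanner probes the next ``max_edits`` positions, keeps
the window with the smallest distance (leftmost on ties — a window that
overlaps the true occurrence by ``e`` bases already scores ``2e``, so
acceptance without this refinement would fire up to ``max_edits // 2``
bases early), emits a hit covering exactly that window and resumes at the
window end; otherwise ``p`` advances by one.  On an exact distance tie the
forward orientation wins.  Hit coordinates are always the fixed window
coordinates, so adapter hits and the fragments between them partition the
read exactly.

Near the right end of a read, windows shorter than the adapter are compared
against the adapter *prefix* of matching length (in both orientations,
which covers truncated adapters on either strand) with the edit threshold
scaled proportionally, ``ceil(max_edits * m / w)`` for a length-``m``
window; windows shorter than 10 bases are not tested.  Reads shorter than
10 bases are emitted as a single fragment without scanning.  Truncated
adapters at the read *start* are left in place here and picked up by
:func:`concatseq.classify.detect_partial_adapter`.

Candidate windows are pre-screened with a sound pigeonhole filter: a window
within ``k <= 4`` edits of a 30 bp adapter must share an exact 6-mer with it
(4 edit events split >= 26 matched bases into <= 5 runs, the longest of
which is >= 6).  Only windows passing the filter are scored with edlib.
The filter is disabled automatically whenever the guaranteed shared-word
length drops below 6 (e.g. the relaxed 6-edit rescan).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Tuple

import edlib
import numpy as np

from .archmodel import AdapterSpec
from .seqio import (FORWARD, REVCOMP, SeqRecord, read_fastx,
                    reverse_complement, write_fastx)

MIN_SCAN_LEN = 10

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes A,C,G,T -> 0..3; anything else -> 4."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScanParams:
    """Adapter-scan settings (defaults: 4 edits, 6 for the relaxed rescan)."""

    adapter: AdapterSpec
    max_edits: int = 4
    relaxed_max_edits: int = 6
    window_len: Optional[int] = None

    def __post_init__(self) -> None:
        w = self.window
        if not 0 <= self.max_edits <= self.relaxed_max_edits < w:
            raise ValueError(
                "need 0 <= max_edits <= relaxed_max_edits < window length")

    @property
    def window(self) -> int:
        return self.window_len if self.window_len is not None else len(self.adapter)

    def relaxed(self) -> "ScanParams":
        return replace(self, max_edits=self.relaxed_max_edits)


@dataclass(frozen=True)
class AdapterHit:
    """One adapter occurrence (0-based half-open read coordinates)."""

    read_id: str
    start: int
    end: int
    orientation: str  # FORWARD / REVCOMP
    distance: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class FragmentRecord:
    """A maximal non-adapter interval of a read."""

    read_id: str
    index: int
    start: int
    end: int
    seq: str
    at_read_start: bool = False
    at_read_end: bool = False
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment interval must be non-empty")
        if len(self.seq) != self.end - self.start:
            raise ValueError("fragment sequence length != interval length")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# window distance machinery


def _nw_distance(a: str, b: str, k: int) -> Optional[int]:
    """Global Levenshtein distance of ``a`` vs ``b``, or None if > ``k``."""
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    return None if d < 0 else d


def _guaranteed_word(window: int, k: int) -> int:
    """Longest exact word every <=k-edit window must share with the adapter."""
    if k >= window:
        return 0
    return math.ceil((window - k) / (k + 1))


_KMER = 6


def _kmer_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes and their validity (no N inside)."""
    n = len(codes) - k + 1
    km = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        km = km * 4 + codes[i : n + i]
        valid &= codes[i : n + i] != 4
    return km, valid


@functools.lru_cache(maxsize=16)
def _adapter_kmers(adapter_seq: str) -> np.ndarray:
    km, valid = _kmer_codes(encode(adapter_seq), _KMER)
    return np.unique(km[valid])


def _candidate_mask(codes: np.ndarray, adapter_kmers: np.ndarray, window: int) -> np.ndarray:
    """True at window starts that may be within k<=4 edits of the adapter."""
    n_windows = len(codes) - window + 1
    if len(codes) < _KMER or n_windows <= 0:
        return np.zeros(max(n_windows, 0), dtype=bool)
    km, valid = _kmer_codes(codes, _KMER)
    hit = np.isin(km, adapter_kmers) & valid
    span = window - _KMER + 1  # k-mer start offsets inside one window
    csum = np.concatenate(([0], np.cumsum(hit)))
    upper = np.minimum(np.arange(n_windows) + span, len(hit))
    return (csum[upper] - csum[:n_windows]) > 0


def scan_adapters(read: SeqRecord, params: ScanParams) -> List[AdapterHit]:
    """Greedy left-to-right adapter scan of one read (both orientations)."""
    seq = read.seq
    L = len(seq)
    w = params.window
    k = params.max_edits
    if L < MIN_SCAN_LEN:
        return []
    adapter_fw = params.adapter.sequence
    adapter_rc = reverse_complement(adapter_fw)
    use_filter = _guaranteed_word(w, k) >= _KMER
    if L >= w:
        if use_filter:
            codes = encode(seq)
            fw_cand = _candidate_mask(codes, _adapter_kmers(adapter_fw), w)
            rc_cand = _candidate_mask(codes, _adapter_kmers(adapter_rc), w)
        else:
            fw_cand = rc_cand = np.ones(L - w + 1, dtype=bool)

    def window_distance(p: int) -> Optional[Tuple[int, str]]:
        """Best (distance, orientation) of window p, or None if > k."""
        if not (fw_cand[p] or rc_cand[p]):
            return None
        window = seq[p : p + w]
        d_fw = _nw_distance(window, adapter_fw, k) if fw_cand[p] else None
        d_rc = _nw_distance(window, adapter_rc, k) if rc_cand[p] else None
        best: Optional[Tuple[int, str]] = None
        if d_fw is not None:
            best = (d_fw, FORWARD)
        if d_rc is not None and (best is None or d_rc < best[0]):
            best = (d_rc, REVCOMP)
        return best

    hits: List[AdapterHit] = []
    p = 0
    while p <= L - w:
        best = window_distance(p)
        if best is not None:
            # local refinement: a window overlapping the true occurrence by
            # e bases already scores 2e <= k, so the first qualifying
            # position can sit up to k//2 bases early; probe the next k
            # positions and keep the minimum distance (leftmost on ties)
            best_p = p
            for q in range(p + 1, min(p + k, L - w) + 1):
                if best[0] == 0:
                    break
                cand = window_distance(q)
                if cand is not None and cand[0] < best[0]:
                    best, best_p = cand, q
            hits.append(AdapterHit(read.id, best_p, best_p + w, best[1], best[0]))
            p = best_p + w
            continue
        p += 1
    # right-terminal short windows: adapter prefixes, scaled threshold
    def terminal_distance(p: int) -> Optional[Tuple[int, str]]:
        m = L - p
        t = math.ceil(k * m / w)
        d_fw = _nw_distance(seq[p:], adapter_fw[:m], t)
        d_rc = _nw_distance(seq[p:], adapter_rc[:m], t)
        best: Optional[Tuple[int, str]] = None
        if d_fw is not None:
            best = (d_fw, FORWARD)
        if d_rc is not None and (best is None or d_rc < best[0]):
            best = (d_rc, REVCOMP)
        return best

    while max(0, L - w + 1) <= p <= L - MIN_SCAN_LEN:
        best = terminal_distance(p)
        if best is not None:
            best_p = p
            for q in range(p + 1, min(p + k, L - MIN_SCAN_LEN) + 1):
                if best[0] == 0:
                    break
                cand = terminal_distance(q)
                if cand is not None and cand[0] < best[0]:
                    best, best_p = cand, q
            hits.append(AdapterHit(read.id, best_p, L, best[1], best[0]))
            break
        p += 1
    return hits


def deconcatenate(read: SeqRecord,
                  hits: List[AdapterHit]) -> Tuple[List[FragmentRecord], List[AdapterHit]]:
    """Split a read into the fragments between (sorted, disjoint) hits."""
    L = len(read.seq)
    prev_end = 0
    for h in hits:
        if h.start < prev_end:
            raise ValueError(f"overlapping/unsorted adapter hits in {read.id}")
        if h.end > L:
            raise ValueError(f"adapter hit beyond read end in {read.id}")
        prev_end = h.end
    fragments: List[FragmentRecord] = []
    boundaries = [(h.start, h.end) for h in hits]
    cursor = 0
    for (s, e) in boundaries + [(L, L)]:
        if s > cursor:
            fragments.append(FragmentRecord(
                read_id=read.id, index=len(fragments), start=cursor, end=s,
                seq=read.seq[cursor:s],
                at_read_start=(cursor == 0), at_read_end=(s == L),
                qual=read.qual[cursor:s] if read.qual is not None else None))
        cursor = e
    return fragments, hits


def deconcat_read(read: SeqRecord,
                  params: ScanParams) -> Tuple[List[FragmentRecord], List[AdapterHit]]:
    return deconcatenate(read, scan_adapters(read, params))


# ---------------------------------------------------------------------------
# file-level driver

#: fragment FASTQ id layout: <read_id>|<index>|<start>-<end>|<flags>, where
#: flags are 'S' (at read start) and 'E' (at read end), '-' otherwise.


def fragment_name(frag: FragmentRecord) -> str:
    flags = ("S" if frag.at_read_start else "-") + ("E" if frag.at_read_end else "-")
    return f"{frag.read_id}|{frag.index}|{frag.start}-{frag.end}|{flags}"


def parse_fragment_name(name: str) -> Tuple[str, int, int, int, bool, bool]:
    try:
        read_id, index, span, flags = name.rsplit("|", 3)
        start, end = span.split("-")
        return (read_id, int(index), int(start), int(end),
                flags[0] == "S", flags[1] == "E")
    except (ValueError, IndexError) as exc:
        raise ValueError(f"unparseable fragment name {name!r}") from exc


def fragment_to_record(frag: FragmentRecord) -> SeqRecord:
    qual = frag.qual if frag.qual is not None else "I" * len(frag.seq)
    return SeqRecord(id=fragment_name(frag), seq=frag.seq, qual=qual)


def record_to_fragment(rec: SeqRecord) -> FragmentRecord:
    read_id, index, start, end, at_start, at_end = parse_fragment_name(rec.id)
    return FragmentRecord(read_id=read_id, index=index, start=start, end=end,
                          seq=rec.seq, at_read_start=at_start,
                          at_read_end=at_end, qual=rec.qual)


ADAPTER_TSV_HEADER = "read_id\tstart\tend\torientation\tdistance"


def write_adapter_hits(hits: Iterable[AdapterHit], path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write(ADAPTER_TSV_HEADER + "\n")
        for h in hits:
            out.write(f"{h.read_id}\t{h.start}\t{h.end}\t{h.orientation}\t{h.distance}\n")
            n += 1
    return n


def read_adapter_hits(path) -> List[AdapterHit]:
    out: List[AdapterHit] = []
    with open(path) as fh:
        if fh.readline().rstrip("\n") != ADAPTER_TSV_HEADER:
            raise ValueError(f"unrecognized adapter table header in {path}")
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            out.append(AdapterHit(f[0], int(f[1]), int(f[2]), f[3], int(f[4])))
    return out


def deconcat_file(in_fastq, params: ScanParams, out_fragments_fastq,
                  out_adapters_tsv) -> Tuple[int, int, int]:
    """Scan and split every read of a FASTQ; returns (reads, fragments, adapters)."""
    n_reads = n_fragments = n_adapters = 0
    all_hits: List[AdapterHit] = []
    frag_records: List[SeqRecord] = []
    for read in read_fastx(in_fastq, "fastq"):
        fragments, hits = deconcat_read(read, params)
        n_reads += 1
        n_fragments += len(fragments)
        n_adapters += len(hits)
        all_hits.extend(hits)
        frag_records.extend(fragment_to_record(f) for f in fragments)
    write_fastx(frag_records, out_fragments_fastq, "fastq")
    write_adapter_hits(all_hits, out_adapters_tsv)
    return n_reads, n_fragments, n_adapters
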