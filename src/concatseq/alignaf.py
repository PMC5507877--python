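"""Fragment-to-panel alignment, hybrid confirmation, pileups and AFs.

Fragments (target plus flanking spacers) are aligned to a panel of
spacer-free amplicon references with a local (Smith-Waterman, affine-gap)
aligner, so the spacers fall off the alignment ends as soft clips.  The
best passing alignment of a fragment is its *primary*; query stretches not
covered by the primary are re-aligned to the whole panel and become
*secondary* alignments when they pass.  Role and orientation map onto the
SAM flags 0 (primary, forward), 16 (primary, reverse), 256 (secondary,
forward) and 272 (secondary, reverse).

A multi-aligned fragment is called a *hybrid* (two units fused without an
intervening adapter) when the relaxed 6-edit adapter rescan finds no
adapter between the aligned query intervals; when a heavily mutated adapter
(5-6 edits) is found there instead, the fragment is rescued, split at the
adapter and re-mapped.

Pileups count the query base (or a deletion) at every covered reference
position of primary alignments; insertions relative to the reference are
ignored, following standard pileup convention.  Allele frequencies are the
alternate-base count divided by depth at the variant position.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from Bio import Align

from .deconcat import FragmentRecord, ScanParams, encode, fragment_name
from .classify import relaxed_rescan
from .seqio import FORWARD, REVCOMP, read_fastx, reverse_complement

PRIMARY = "primary"
SECONDARY = "secondary"

_FLAG = {(PRIMARY, FORWARD): 0, (PRIMARY, REVCOMP): 16,
         (SECONDARY, FORWARD): 256, (SECONDARY, REVCOMP): 272}
_FLAG_INV = {v: k for k, v in _FLAG.items()}


def role_orientation_to_flag(role: str, orientation: str) -> int:
    return _FLAG[(role, orientation)]


def flag_to_role_orientation(flag: int) -> Tuple[str, str]:
    return _FLAG_INV[flag]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap local alignment scores (first gap base costs ``open_gap``)."""

    match: float = 2.0
    mismatch: float = -3.0
    open_gap: float = -5.0
    extend_gap: float = -2.0


DEFAULT_SCORING = Scoring()


@functools.lru_cache(maxsize=8)
def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.open_gap
    a.extend_gap_score = scoring.extend_gap
    return a


# ---------------------------------------------------------------------------
# panel


@dataclass(frozen=True)
class Amplicon:
    id: str
    seq: str
    spacer5_len: Optional[int] = None
    spacer3_len: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"amplicon {self.id!r} has empty sequence")


@dataclass(frozen=True)
class AmpliconPanel:
    amplicons: Tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        if not self.amplicons:
            raise ValueError("panel must contain at least one amplicon")
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate amplicon ids in panel")

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    @classmethod
    def from_targets(cls, pairs: Iterable[Tuple[str, str]]) -> "AmpliconPanel":
        return cls(tuple(Amplicon(i, s) for i, s in pairs))

    @classmethod
    def from_fasta(cls, path, meta_tsv=None) -> "AmpliconPanel":
        meta: Dict[str, Tuple[int, int]] = {}
        if meta_tsv is not None:
            with open(meta_tsv) as fh:
                header = fh.readline().rstrip("\n").split("\t")
                if header[:3] != ["amplicon", "spacer5_len", "spacer3_len"]:
                    raise ValueError(f"unrecognized panel meta header in {meta_tsv}")
                for raw in fh:
                    f = raw.rstrip("\n").split("\t")
                    meta[f[0]] = (int(f[1]), int(f[2]))
        amps = []
        for rec in read_fastx(path, "fasta"):
            s5, s3 = meta.get(rec.id, (None, None))
            amps.append(Amplicon(rec.id, rec.seq, s5, s3))
        return cls(tuple(amps))


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass(frozen=True)
class RawAlignment:
    """Local alignment of a query against one reference (aligned frame)."""

    score: float
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    blocks: Tuple[Tuple[Tuple[int, int], Tuple[int, int]], ...]  # ((ts,te),(qs,qe))
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_query_len(self) -> int:
        return self.query_end - self.query_start


def semiglobal_align(query: str, ref: str,
                     scoring: Scoring = DEFAULT_SCORING) -> Optional[RawAlignment]:
    """Best local-in-query alignment; query ends are clipped without penalty.

    Returns ``None`` when no positive-scoring alignment exists.  Traceback
    is the aligner's canonical first path, which is deterministic.
    """
    if not query or not ref:
        raise ValueError("query and ref must be non-empty")
    aligner = _aligner(scoring)
    if aligner.score(ref, query) <= 0:
        return None
    aln = aligner.align(ref, query)[0]
    tblocks, qblocks = aln.aligned
    blocks = tuple(((int(ts), int(te)), (int(qs), int(qe)))
                   for (ts, te), (qs, qe) in zip(tblocks, qblocks))
    matches = 0
    columns = 0
    prev_te = prev_qe = None
    for (ts, te), (qs, qe) in blocks:
        if prev_te is not None:
            columns += (ts - prev_te) + (qs - prev_qe)
        matches += sum(1 for a, b in zip(ref[ts:te], query[qs:qe]) if a == b)
        columns += te - ts
        prev_te, prev_qe = te, qe
    return RawAlignment(score=float(aln.score),
                        query_start=blocks[0][1][0], query_end=blocks[-1][1][1],
                        ref_start=blocks[0][0][0], ref_end=blocks[-1][0][1],
                        blocks=blocks, matches=matches, columns=columns)


@dataclass(frozen=True)
class AlignmentRecord:
    """A fragment-vs-amplicon alignment with its SAM-style role.

    ``query_start``/``query_end`` are in the original fragment frame
    (forward strand of the read); ``blocks`` and ``aligned_seq`` are in the
    aligned frame (the sequence as it was aligned, reverse-complemented for
    ``revcomp`` records, sub-segment only for secondaries).
    """

    fragment_id: str
    amplicon_id: str
    orientation: str
    role: str
    score: float
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    query_len: int
    identity: float
    blocks: Tuple[Tuple[Tuple[int, int], Tuple[int, int]], ...]
    aligned_seq: str

    @property
    def sam_flag(self) -> int:
        return role_orientation_to_flag(self.role, self.orientation)

    @property
    def clipped5(self) -> int:
        return self.query_start

    @property
    def clipped3(self) -> int:
        return self.query_len - self.query_end

    def cigar(self) -> str:
        """CIGAR in the aligned frame, soft clips for unaligned query ends."""
        ops: List[str] = []
        alen = len(self.aligned_seq)
        lead = self.blocks[0][1][0]
        if lead:
            ops.append(f"{lead}S")
        prev_te = prev_qe = None
        for (ts, te), (qs, qe) in self.blocks:
            if prev_te is not None:
                if qs > prev_qe:
                    ops.append(f"{qs - prev_qe}I")
                if ts > prev_te:
                    ops.append(f"{ts - prev_te}D")
            ops.append(f"{te - ts}M")
            prev_te, prev_qe = te, qe
        tail = alen - self.blocks[-1][1][1]
        if tail:
            ops.append(f"{tail}S")
        return "".join(ops)


def _passing(raw: Optional[RawAlignment], min_identity: float, min_len: int) -> bool:
    return (raw is not None and raw.identity >= min_identity
            and raw.aligned_query_len >= min_len)


#: exact-anchor length required before a sequence is aligned to the panel
#: (seed-and-extend convention; disabled for panels with references shorter
#: than the seed)
SEED_LEN = 12


@functools.lru_cache(maxsize=8)
def _panel_seeds(panel: AmpliconPanel) -> Optional[frozenset]:
    """All SEED_LEN-mers of the panel references and their reverse
    complements, or None when some reference is too short to seed."""
    if any(len(a.seq) < SEED_LEN for a in panel):
        return None
    words = set()
    for a in panel:
        for s in (a.seq, reverse_complement(a.seq)):
            for i in range(len(s) - SEED_LEN + 1):
                words.add(s[i : i + SEED_LEN])
    return frozenset(words)


def _has_seed(seq: str, panel: AmpliconPanel) -> bool:
    seeds = _panel_seeds(panel)
    if seeds is None:
        return True
    return any(seq[i : i + SEED_LEN] in seeds
               for i in range(len(seq) - SEED_LEN + 1))


def _exact_match(q: str, amp: Amplicon, scoring: Scoring) -> Optional[RawAlignment]:
    """Leftmost exact occurrence of the full reference inside the query."""
    i = q.find(amp.seq)
    if i < 0:
        return None
    r = len(amp.seq)
    return RawAlignment(score=scoring.match * r, query_start=i, query_end=i + r,
                        ref_start=0, ref_end=r,
                        blocks=(((0, r), (i, i + r)),), matches=r, columns=r)


def _best_passing(seq: str, panel: AmpliconPanel, scoring: Scoring,
                  min_identity: float, min_len: int
                  ) -> Optional[Tuple[str, Amplicon, RawAlignment]]:
    """Best passing (orientation, amplicon, alignment) for one sequence."""
    if len(seq) < min_len or not _has_seed(seq, panel):
        return None
    # fast path: an exact full-reference occurrence is an optimal local
    # alignment of that reference, and it beats every alignment to any
    # reference that is not longer
    max_len = max(len(a.seq) for a in panel)
    for orientation in (FORWARD, REVCOMP):
        q = seq if orientation == FORWARD else reverse_complement(seq)
        for amp in panel:
            if len(amp.seq) != max_len:
                continue
            raw = _exact_match(q, amp, scoring)
            if raw is not None and _passing(raw, min_identity, min_len):
                return (orientation, amp, raw)
    aligner = _aligner(scoring)
    floor = 0.5 * min_len  # conservative score pre-filter; below any passing score
    best: Optional[Tuple[str, Amplicon, RawAlignment]] = None
    for orientation in (FORWARD, REVCOMP):
        q = seq if orientation == FORWARD else reverse_complement(seq)
        for amp in panel:
            score = aligner.score(amp.seq, q)
            if score < floor:
                continue
            if best is not None and score <= best[2].score:
                continue
            raw = semiglobal_align(q, amp.seq, scoring)
            if not _passing(raw, min_identity, min_len):
                continue
            if best is None or raw.score > best[2].score:
                best = (orientation, amp, raw)
    return best


def _to_record(fragment_id: str, orientation: str, amp: Amplicon,
               raw: RawAlignment, role: str, aligned_seq: str,
               seg_start: int, seg_len: int, query_len: int) -> AlignmentRecord:
    """Map a segment alignment back to original fragment coordinates."""
    if orientation == FORWARD:
        q0 = seg_start + raw.query_start
        q1 = seg_start + raw.query_end
    else:
        q0 = seg_start + seg_len - raw.query_end
        q1 = seg_start + seg_len - raw.query_start
    return AlignmentRecord(
        fragment_id=fragment_id, amplicon_id=amp.id, orientation=orientation,
        role=role, score=raw.score, ref_start=raw.ref_start,
        ref_end=raw.ref_end, query_start=q0, query_end=q1,
        query_len=query_len, identity=raw.identity, blocks=raw.blocks,
        aligned_seq=aligned_seq)


def map_to_panel(fragment: FragmentRecord, panel: AmpliconPanel,
                 scoring: Scoring = DEFAULT_SCORING, min_identity: float = 0.8,
                 min_aligned: int = 50, min_secondary: int = 25,
                 max_secondaries: int = 8) -> List[AlignmentRecord]:
    """Align one fragment to the panel; primary plus disjoint secondaries.

    Returns an empty list for off-target fragments.  Secondary alignments
    are found by re-aligning the query stretches (>= ``min_secondary``
    bases) left uncovered by the alignments accepted so far.  Following
    seed-and-extend practice, a (sub)query is only aligned when it shares
    an exact 12-mer with the panel (either strand).
    """
    L = len(fragment.seq)
    fid = fragment_name(fragment)
    best = _best_passing(fragment.seq, panel, scoring, min_identity, min_aligned)
    if best is None:
        return []
    orientation, amp, raw = best
    aligned_seq = (fragment.seq if orientation == FORWARD
                   else reverse_complement(fragment.seq))
    primary = _to_record(fid, orientation, amp, raw, PRIMARY, aligned_seq,
                         seg_start=0, seg_len=L, query_len=L)
    records = [primary]
    segments = [(0, primary.query_start), (primary.query_end, L)]
    while segments and len(records) <= max_secondaries:
        a, b = segments.pop(0)
        if b - a < min_secondary:
            continue
        sub = fragment.seq[a:b]
        hit = _best_passing(sub, panel, scoring, min_identity, min_secondary)
        if hit is None:
            continue
        s_orient, s_amp, s_raw = hit
        s_aligned = sub if s_orient == FORWARD else reverse_complement(sub)
        rec = _to_record(fid, s_orient, s_amp, s_raw, SECONDARY, s_aligned,
                         seg_start=a, seg_len=b - a, query_len=L)
        records.append(rec)
        segments.append((a, rec.query_start))
        segments.append((rec.query_end, b))
    return [records[0]] + sorted(records[1:], key=lambda r: r.query_start)


# ---------------------------------------------------------------------------
# hybrid calling


@dataclass
class HybridCall:
    fragment_id: str
    is_hybrid: bool
    rescued: bool = False
    n_secondaries: int = 0
    rescue_hit: Optional[Tuple[int, int]] = None
    split_records: Tuple[AlignmentRecord, ...] = ()


def call_hybrids(fragments_with_alignments: Iterable[Tuple[FragmentRecord, List[AlignmentRecord]]],
                 params: ScanParams, panel: AmpliconPanel,
                 scoring: Scoring = DEFAULT_SCORING, min_identity: float = 0.8,
                 min_aligned: int = 50, min_secondary: int = 25,
                 junction_slack: int = 8) -> List[HybridCall]:
    """Confirm or rescue multi-aligned fragments.

    A fragment with secondary alignments is a hybrid unless the relaxed
    (6-edit) adapter rescan finds an adapter between the aligned query
    intervals, in which case the fragment is split at that adapter and its
    halves re-mapped.
    """
    calls: List[HybridCall] = []
    for fragment, records in fragments_with_alignments:
        fid = fragment_name(fragment)
        secondaries = [r for r in records if r.role == SECONDARY]
        if not secondaries:
            calls.append(HybridCall(fid, is_hybrid=False))
            continue
        intervals = sorted((r.query_start, r.query_end) for r in records)
        junctions = []
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            junctions.append((min(e1, s2) - junction_slack,
                              max(e1, s2) + junction_slack))
        relaxed_hits = relaxed_rescan(fragment, params)
        rescue = None
        for h in relaxed_hits:
            if any(h.start < je and h.end > js for js, je in junctions):
                rescue = h
                break
        if rescue is None:
            calls.append(HybridCall(fid, is_hybrid=True,
                                    n_secondaries=len(secondaries)))
            continue
        split_records: List[AlignmentRecord] = []
        pieces = [(0, rescue.start), (rescue.end, len(fragment.seq))]
        for i, (a, b) in enumerate(pieces):
            if b - a < 1:
                continue
            piece = FragmentRecord(
                read_id=fragment.read_id, index=fragment.index,
                start=fragment.start + a, end=fragment.start + b,
                seq=fragment.seq[a:b],
                at_read_start=fragment.at_read_start and a == 0,
                at_read_end=fragment.at_read_end and b == len(fragment.seq))
            split_records.extend(map_to_panel(piece, panel, scoring,
                                              min_identity, min_aligned,
                                              min_secondary))
        calls.append(HybridCall(fid, is_hybrid=False, rescued=True,
                                n_secondaries=len(secondaries),
                                rescue_hit=(rescue.start, rescue.end),
                                split_records=tuple(split_records)))
    return calls


# ---------------------------------------------------------------------------
# pileup and allele frequencies

_CHANNELS = "ACGT-"  # column order; '-' is the deletion channel


@dataclass
class PileupTable:
    """Per-position base counts for every amplicon (counts[amp][pos, ch])."""

    counts: Dict[str, np.ndarray]
    refs: Dict[str, str]

    def depth(self, amplicon_id: str, position: int) -> int:
        return int(self.counts[amplicon_id][position].sum())

    def base_count(self, amplicon_id: str, position: int, base: str) -> int:
        return int(self.counts[amplicon_id][position, _CHANNELS.index(base)])


def pileup(alignments: Iterable[AlignmentRecord], panel: AmpliconPanel) -> PileupTable:
    """Base counts over all primary alignments (insertions ignored)."""
    counts = {a.id: np.zeros((len(a.seq), 5), dtype=np.int64) for a in panel}
    for rec in alignments:
        if rec.role != PRIMARY:
            continue
        arr = counts[rec.amplicon_id]
        q = encode(rec.aligned_seq)
        prev_te = prev_qe = None
        for (ts, te), (qs, qe) in rec.blocks:
            if prev_te is not None and ts > prev_te:
                arr[prev_te:ts, 4] += 1  # deletion relative to the reference
            codes = q[qs:qe]
            valid = codes < 4
            np.add.at(arr, (np.arange(ts, te)[valid], codes[valid]), 1)
            prev_te, prev_qe = te, qe
    return PileupTable(counts=counts, refs={a.id: a.seq for a in panel})


@dataclass(frozen=True)
class VariantCall:
    amplicon_id: str
    position: int  # 0-based
    ref: str
    alt: str
    alt_count: int
    depth: int

    @property
    def af(self) -> Optional[float]:
        return self.alt_count / self.depth if self.depth > 0 else None


def extract_af(table: PileupTable,
               variants: Iterable[Tuple[str, int, str, str]]) -> List[VariantCall]:
    """Allele frequency of each (amplicon, 0-based position, ref, alt)."""
    calls: List[VariantCall] = []
    for amp_id, position, ref, alt in variants:
        if amp_id not in table.counts:
            raise ValueError(f"variant on unknown amplicon {amp_id!r}")
        if not 0 <= position < len(table.counts[amp_id]):
            raise ValueError(f"variant position {position} outside {amp_id}")
        depth = table.depth(amp_id, position)
        alt_count = table.base_count(amp_id, position, alt)
        calls.append(VariantCall(amp_id, position, ref, alt, alt_count, depth))
    return calls


def amplicon_coverage(alignments: Iterable[AlignmentRecord]) -> Dict[str, float]:
    """Fraction of primary alignments per amplicon; fractions sum to 1."""
    totals: Dict[str, int] = {}
    n = 0
    for rec in alignments:
        if rec.role == PRIMARY:
            totals[rec.amplicon_id] = totals.get(rec.amplicon_id, 0) + 1
            n += 1
    if n == 0:
        raise ValueError("no aligned fragments")
    return {amp: c / n for amp, c in sorted(totals.items())}


# ---------------------------------------------------------------------------
# serialization

ALIGN_TSV_HEADER = ("fragment_id\tamplicon_id\torientation\trole\tscore\t"
                    "ref_start\tref_end\tquery_start\tquery_end\tquery_len\t"
                    "identity\tcigar\taligned_seq")


def write_alignments_tsv(records: Iterable[AlignmentRecord], path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write(ALIGN_TSV_HEADER + "\n")
        for r in records:
            out.write(f"{r.fragment_id}\t{r.amplicon_id}\t{r.orientation}\t"
                      f"{r.role}\t{r.score:g}\t{r.ref_start}\t{r.ref_end}\t"
                      f"{r.query_start}\t{r.query_end}\t{r.query_len}\t"
                      f"{r.identity:.6f}\t{r.cigar()}\t{r.aligned_seq}\n")
            n += 1
    return n


_CIGAR_RE = re.compile(r"(\d+)([MIDS])")


def _blocks_from_cigar(cigar: str, ref_start: int
                       ) -> Tuple[Tuple[Tuple[int, int], Tuple[int, int]], ...]:
    blocks = []
    t = ref_start
    q = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "S":
            q += n
        elif op == "M":
            blocks.append(((t, t + n), (q, q + n)))
            t += n
            q += n
        elif op == "I":
            q += n
        elif op == "D":
            t += n
    return tuple(blocks)


def read_alignments_tsv(path) -> List[AlignmentRecord]:
    out: List[AlignmentRecord] = []
    with open(path) as fh:
        if fh.readline().rstrip("\n") != ALIGN_TSV_HEADER:
            raise ValueError(f"unrecognized alignment table header in {path}")
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            blocks = _blocks_from_cigar(f[11], int(f[5]))
            out.append(AlignmentRecord(
                fragment_id=f[0], amplicon_id=f[1], orientation=f[2], role=f[3],
                score=float(f[4]), ref_start=int(f[5]), ref_end=int(f[6]),
                query_start=int(f[7]), query_end=int(f[8]), query_len=int(f[9]),
                identity=float(f[10]), blocks=blocks, aligned_seq=f[12]))
    return out


def write_sam(records: Iterable[AlignmentRecord], panel: AmpliconPanel, path) -> int:
    """Minimal SAM: header plus one line per alignment record."""
    n = 0
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for amp in panel:
            out.write(f"@SQ\tSN:{amp.id}\tLN:{len(amp.seq)}\n")
        out.write("@PG\tID:concatseq\tPN:concatseq\n")
        for r in records:
            out.write("\t".join([
                r.fragment_id, str(r.sam_flag), r.amplicon_id,
                str(r.ref_start + 1), "255", r.cigar(), "*", "0", "0",
                r.aligned_seq, "*"]) + "\n")
            n += 1
    return n


def write_pileup_tsv(table: PileupTable, path) -> None:
    """Contingency table: amplicon, 1-based position, ref, A, C, G, T, del, depth."""
    with open(path, "w") as out:
        out.write("amplicon\tposition\tref\tA\tC\tG\tT\tdel\tdepth\n")
        for amp_id in sorted(table.counts):
            arr = table.counts[amp_id]
            ref = table.refs[amp_id]
            for i in range(len(arr)):
                row = arr[i]
                out.write(f"{amp_id}\t{i + 1}\t{ref[i]}\t" +
                          "\t".join(str(int(x)) for x in row) +
                          f"\t{int(row.sum())}\n")


def write_variant_calls(calls: Iterable[VariantCall], path) -> None:
    with open(path, "w") as out:
        out.write("amplicon\tposition\tref\talt\talt_count\tdepth\taf\n")
        for c in calls:
            af = f"{c.af:.6f}" if c.af is not None else "NA"
            out.write(f"{c.amplicon_id}\t{c.position + 1}\t{c.ref}\t{c.alt}\t"
                      f"{c.alt_count}\t{c.depth}\t{af}\n")
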