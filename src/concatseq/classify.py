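"""Fragment population classification and chimera pre-screening.

Deconcatenated fragments fall into the populations seen in real concatemer
libraries: single-base hairpin-ligation remnants at read termini, fragments
at (or very close to) the expected size, oversized terminal fragments that
still carry a truncated adapter the scanner could not see, and a remainder
of short fragments.  Only length-1 fragments are removed before alignment;
everything else is kept.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .archmodel import AdapterSpec
from .deconcat import FragmentRecord, ScanParams, _nw_distance, scan_adapters
from .seqio import FORWARD, REVCOMP, SeqRecord, reverse_complement

REMNANT_1BP = "remnant_1bp"
EXPECTED_SIZE = "expected_size"
OVERSIZED = "oversized"
UNDERSIZED_OTHER = "undersized_other"

LABELS = (REMNANT_1BP, EXPECTED_SIZE, OVERSIZED, UNDERSIZED_OTHER)

#: expected-size band from the library design: 187 bp nominal, 181-190 kept
DEFAULT_BAND = (181, 190)


@dataclass(frozen=True)
class PartialAdapter:
    """Evidence for a truncated adapter at a fragment terminus."""

    side: str  # "5p" | "3p"
    length: int
    distance: int
    orientation: str


@dataclass(frozen=True)
class FragmentClass:
    label: str
    evidence: Optional[PartialAdapter] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def filter_short(fragments: Sequence[FragmentRecord],
                 min_len: int = 2) -> Tuple[List[FragmentRecord], List[FragmentRecord]]:
    """Split fragments into (kept, removed) by minimum length, order kept."""
    kept: List[FragmentRecord] = []
    removed: List[FragmentRecord] = []
    for f in fragments:
        (kept if len(f) >= min_len else removed).append(f)
    return kept, removed


def classify_length(fragment: FragmentRecord, expected_len: int = 187,
                    band: Tuple[int, int] = DEFAULT_BAND) -> FragmentClass:
    """Length-based population label; the band must contain the expected size."""
    low, high = band
    if not low <= expected_len <= high:
        raise ValueError(f"band {band} does not contain expected length {expected_len}")
    n = len(fragment)
    if n == 1:
        return FragmentClass(REMNANT_1BP)
    if low <= n <= high:
        return FragmentClass(EXPECTED_SIZE)
    if n > high:
        return FragmentClass(OVERSIZED)
    return FragmentClass(UNDERSIZED_OTHER)


def detect_partial_adapter(fragment: FragmentRecord, adapter: AdapterSpec,
                           min_prefix: int = 8, max_edits: int = 4,
                           relaxed_max_edits: int = 6) -> Optional[PartialAdapter]:
    """Look for a truncated adapter at the read-facing end(s) of a fragment.

    A fragment at the read start may begin with the *suffix* of an adapter
    (the outer bases were lost); a fragment at the read end may end with an
    adapter *prefix*.  Both orientations are tested for every length from
    ``min_prefix`` up to the full adapter.  Stubs are held to the scanner's
    per-base stringency (``ceil(max_edits * m / len(adapter))``); a
    full-length terminal adapter — one the strict scan must have missed —
    is re-admitted at the relaxed threshold instead, mirroring
    :func:`relaxed_rescan`.  Returns the best-supported partial (lowest
    distance, then longest) or ``None``.  Stubs shorter than ``min_prefix``
    are below the detection floor.
    """
    a_fw = adapter.sequence
    a_rc = reverse_complement(a_fw)
    y = len(a_fw)
    seq = fragment.seq
    candidates: List[PartialAdapter] = []
    for m in range(min_prefix, min(y, len(seq)) + 1):
        t = relaxed_max_edits if m == y else math.ceil(max_edits * m / y)
        if fragment.at_read_start:
            for orientation, a in ((FORWARD, a_fw), (REVCOMP, a_rc)):
                d = _nw_distance(seq[:m], a[-m:], t)
                if d is not None:
                    candidates.append(PartialAdapter("5p", m, d, orientation))
        if fragment.at_read_end:
            for orientation, a in ((FORWARD, a_fw), (REVCOMP, a_rc)):
                d = _nw_distance(seq[-m:], a[:m], t)
                if d is not None:
                    candidates.append(PartialAdapter("3p", m, d, orientation))
    if not candidates:
        return None
    # lowest distance wins; prefer the longest supported stub, then 5' and
    # forward for reproducibility
    return min(candidates, key=lambda c: (c.distance, -c.length,
                                          c.side != "5p", c.orientation != FORWARD))


def relaxed_rescan(fragment: FragmentRecord, params: ScanParams):
    """Re-scan a fragment for adapters at the relaxed (6-edit) threshold."""
    pseudo = SeqRecord(id=fragment.read_id, seq=fragment.seq)
    return scan_adapters(pseudo, params.relaxed())


# ---------------------------------------------------------------------------
# table / histogram output


@dataclass(frozen=True)
class ClassifiedFragment:
    fragment_id: str
    length: int
    label: str
    partial: Optional[PartialAdapter] = None


def classify_fragments(fragments: Sequence[FragmentRecord],
                       adapter: AdapterSpec, expected_len: int = 187,
                       band: Tuple[int, int] = DEFAULT_BAND,
                       min_prefix: int = 8,
                       max_edits: int = 4) -> List[ClassifiedFragment]:
    """Label every fragment; oversized terminal fragments get partial-adapter
    evidence attached when detectable."""
    from .deconcat import fragment_name

    out: List[ClassifiedFragment] = []
    for f in fragments:
        cls = classify_length(f, expected_len, band)
        partial = None
        if cls.label == OVERSIZED and (f.at_read_start or f.at_read_end):
            partial = detect_partial_adapter(f, adapter, min_prefix, max_edits)
        out.append(ClassifiedFragment(fragment_name(f), len(f), cls.label, partial))
    return out


def length_histogram(lengths: Iterable[int], bin_width: int = 10) -> Dict[int, int]:
    """Counts per [b, b+bin_width) length bin, keyed by bin start."""
    counts: Counter = Counter()
    for n in lengths:
        counts[(n // bin_width) * bin_width] += 1
    return dict(sorted(counts.items()))


CLASSIFY_TSV_HEADER = "fragment_id\tlength\tlabel\tpartial_side\tpartial_len\tpartial_dist\tpartial_orientation"


def write_classification(rows: Sequence[ClassifiedFragment], path) -> None:
    with open(path, "w") as out:
        out.write(CLASSIFY_TSV_HEADER + "\n")
        for r in rows:
            if r.partial is None:
                p = "-\t-\t-\t-"
            else:
                p = f"{r.partial.side}\t{r.partial.length}\t{r.partial.distance}\t{r.partial.orientation}"
            out.write(f"{r.fragment_id}\t{r.length}\t{r.label}\t{p}\n")


def read_classification(path) -> List[ClassifiedFragment]:
    out: List[ClassifiedFragment] = []
    with open(path) as fh:
        if fh.readline().rstrip("\n") != CLASSIFY_TSV_HEADER:
            raise ValueError(f"unrecognized classification header in {path}")
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            partial = None
            if f[3] != "-":
                partial = PartialAdapter(f[3], int(f[4]), int(f[5]), f[6])
            out.append(ClassifiedFragment(f[0], int(f[1]), f[2], partial))
    return out


def write_histogram(hist: Dict[int, int], path, bin_width: int = 10) -> None:
    with open(path, "w") as out:
        out.write("bin_start\tbin_end\tcount\n")
        for start, count in sorted(hist.items()):
            out.write(f"{start}\t{start + bin_width}\t{count}\n")
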