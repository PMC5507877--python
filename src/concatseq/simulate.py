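"""Synthetic concatemer libraries with per-read ground truth.

The generator emits consensus-level reads (the input unit of
deconcatenation) built as an alternating backbone of adapters and
fragments::

    [remnant] adapter unit_1 adapter unit_2 ... adapter unit_n adapter [remnant]

Each unit is one panel amplicon flanked by the constant spacers; a unit is
reverse-complemented with probability ``orientation_prob`` together with its
flanking adapter context, so adapter orientation switches along the read
exactly as in real concatemers.  Structural artifacts reproduce what is seen
in real libraries: single A/T hairpin-ligation remnants outside the terminal
adapters, terminal adapters truncated to 1..y-1 bases, and rare "hybrid"
junctions where the adapter is replaced by a short homology-driven fusion
(the downstream fragment loses a 5-20 bp overlap and no adapter is
written).  Substitution/insertion/deletion errors are applied last; truth
coordinates always refer to the error-free read.

Determinism: one ``numpy.random.Generator`` stream per library, seeded from
``SimConfig.seed``.  Draw order per read: for each unit (amplicon index,
orientation, one uniform per variant on that amplicon); per internal
junction (hybrid?, overlap length if hybrid); 5' truncation (flag, kept
length); 3' truncation; leading remnant (flag, base); trailing remnant;
error batches (deletion mask, substitution mask, insertion mask,
substitution shifts, inserted bases).  Error draws are skipped entirely when
all three rates are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .archmodel import ArchitectureSpec
from .seqio import FORWARD, REVCOMP, SeqRecord, reverse_complement, write_fastx

_BASES = "ACGTN"
_ENCODE = {b: i for i, b in enumerate(_BASES)}

#: quality placeholder: constant Q30; no downstream stage consumes qualities
_QUAL_CHAR = chr(30 + 33)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_panel(n_amplicons: int, target_len: int = 120, seed: int = 0) -> List[Tuple[str, str]]:
    """A reproducible panel of random target sequences (no spacers)."""
    rng = np.random.default_rng([int(seed), 7])
    return [(f"amp{i:02d}", _random_seq(rng, target_len)) for i in range(n_amplicons)]


@dataclass(frozen=True)
class Variant:
    """A known SNV on a panel amplicon (0-based position in the reference)."""

    amplicon_id: str
    position: int
    ref: str
    alt: str
    af: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")
        if self.ref not in "ACGT" or self.alt not in "ACGT" or self.ref == self.alt:
            raise ValueError(f"invalid ref/alt pair {self.ref}>{self.alt}")


@dataclass(frozen=True)
class NmerDistribution:
    """Units-per-read law: ``fixed`` n, or geometric(mean) clipped at max_n."""

    kind: str = "geometric"
    n: int = 5
    max_n: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "geometric"):
            raise ValueError(f"unknown n-mer distribution kind {self.kind!r}")
        if self.n < 1 or self.max_n < self.n:
            raise ValueError("n-mer distribution requires 1 <= n <= max_n")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return self.n
        return int(min(rng.geometric(1.0 / self.n), self.max_n))

    def mean(self) -> float:
        """Exact expectation (accounts for clipping at ``max_n``)."""
        if self.kind == "fixed":
            return float(self.n)
        p = 1.0 / self.n
        return (1.0 - (1.0 - p) ** self.max_n) / p

    def var(self) -> float:
        """Exact variance of the clipped geometric (by direct summation)."""
        if self.kind == "fixed":
            return 0.0
        p = 1.0 / self.n
        ks = np.arange(1, self.max_n + 1)
        pmf = (1 - p) ** (ks - 1) * p
        pmf[-1] += (1 - p) ** self.max_n  # mass clipped onto max_n
        m = float(np.sum(ks * pmf))
        return float(np.sum((ks - m) ** 2 * pmf))


@dataclass
class SimConfig:
    """Study conditions for one synthetic library."""

    architecture: ArchitectureSpec
    panel: List[Tuple[str, str]]
    n_reads: int = 1000
    nmer: NmerDistribution = field(default_factory=NmerDistribution)
    orientation_prob: float = 0.5
    sub_rate: float = 0.006
    ins_rate: float = 0.002
    del_rate: float = 0.002
    hairpin_remnant_prob: float = 0.4
    end_truncation_prob: float = 0.3
    hybrid_prob: float = 0.005
    variants: Tuple[Variant, ...] = ()
    panel_weights: Optional[Sequence[float]] = None
    seed: int = 0
    spacer5: Optional[str] = None
    spacer3: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("panel must be non-empty")
        ids = [a for a, _ in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("panel amplicon ids must be unique")
        for aid, seq in self.panel:
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"panel amplicon {aid!r} must be non-empty ACGT")
        for name in ("orientation_prob", "sub_rate", "ins_rate", "del_rate",
                     "hairpin_remnant_prob", "end_truncation_prob", "hybrid_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.panel_weights is not None:
            w = np.asarray(self.panel_weights, dtype=float)
            if len(w) != len(self.panel) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("panel_weights must be non-negative, one per amplicon")
        # constant spacers: the design fixes them once; derive from the seed
        # if not given explicitly
        arch = self.architecture
        spacer_rng = np.random.default_rng([int(self.seed), 101])
        if self.spacer5 is None:
            self.spacer5 = _random_seq(spacer_rng, arch.spacer5_len)
        if self.spacer3 is None:
            self.spacer3 = _random_seq(spacer_rng, arch.spacer3_len)
        if len(self.spacer5) != arch.spacer5_len or len(self.spacer3) != arch.spacer3_len:
            raise ValueError("spacer sequences must match the architecture lengths")
        targets = dict(self.panel)
        for v in self.variants:
            if v.amplicon_id not in targets:
                raise ValueError(f"variant on unknown amplicon {v.amplicon_id!r}")
            t = targets[v.amplicon_id]
            if not 0 <= v.position < len(t):
                raise ValueError(f"variant position {v.position} outside {v.amplicon_id}")
            if t[v.position] != v.ref:
                raise ValueError(
                    f"variant ref {v.ref} != panel base {t[v.position]} at "
                    f"{v.amplicon_id}:{v.position}"
                )

    def variants_for(self, amplicon_id: str) -> List[Variant]:
        return [v for v in self.variants if v.amplicon_id == amplicon_id]


@dataclass(frozen=True)
class TruthUnit:
    amplicon_id: str
    orientation: str  # FORWARD / REVCOMP
    variants_applied: Tuple[str, ...] = ()


@dataclass(frozen=True)
class TruthInterval:
    kind: str  # "adapter" | "fragment" | "remnant"
    start: int
    end: int
    orientation: str = FORWARD
    unit_index: int = -1  # fragment intervals only; -1 otherwise
    truncated: bool = False


@dataclass
class TruthRecord:
    """Ground truth for one simulated read (error-free coordinates)."""

    read_id: str
    units: List[TruthUnit]
    intervals: List[TruthInterval]
    events: Dict[str, object] = field(default_factory=dict)

    def intervals_of(self, kind: str) -> List[TruthInterval]:
        return [iv for iv in self.intervals if iv.kind == kind]

    def hybrid_positions(self) -> List[int]:
        """Read coordinates of junctions fused without an adapter."""
        return [pos for (_, _, pos) in self.events.get("hybrid_junctions", [])]


def apply_errors(seq: str, sub_rate: float, ins_rate: float, del_rate: float,
                 rng: np.random.Generator) -> str:
    """Independent per-base substitution/insertion/deletion errors.

    A deleted base is dropped outright; otherwise a substitution replaces it
    with one of the three alternatives; an insertion adds one uniform base
    after the position.  ``N`` bases are never substituted.
    """
    for name, rate in (("sub", sub_rate), ("ins", ins_rate), ("del", del_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name}_rate={rate} outside [0, 1]")
    if not seq or (sub_rate == 0.0 and ins_rate == 0.0 and del_rate == 0.0):
        return seq
    L = len(seq)
    del_mask = rng.random(L) < del_rate
    sub_mask = rng.random(L) < sub_rate
    ins_mask = rng.random(L) < ins_rate
    sub_shift = rng.integers(1, 4, size=L)
    ins_base = rng.integers(0, 4, size=L)
    out: List[str] = []
    for i, base in enumerate(seq):
        if not del_mask[i]:
            if sub_mask[i] and base != "N":
                out.append("ACGT"[(_ENCODE[base] + sub_shift[i]) % 4])
            else:
                out.append(base)
        if ins_mask[i]:
            out.append("ACGT"[ins_base[i]])
    return "".join(out)


def simulate_read(config: SimConfig, n_units: int, rng: np.random.Generator,
                  read_id: str = "read") -> Tuple[SeqRecord, TruthRecord]:
    """One concatemer read plus its ground truth."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    arch = config.architecture
    adapter_fw = arch.adapter.sequence
    adapter_rc = reverse_complement(adapter_fw)
    y = len(adapter_fw)
    weights = None
    if config.panel_weights is not None:
        w = np.asarray(config.panel_weights, dtype=float)
        weights = w / w.sum()

    # --- unit composition ---------------------------------------------------
    units: List[TruthUnit] = []
    frag_seqs: List[str] = []
    for _ in range(n_units):
        if weights is None:
            idx = int(rng.integers(0, len(config.panel)))
        else:
            idx = int(rng.choice(len(config.panel), p=weights))
        amp_id, target = config.panel[idx]
        applied: List[str] = []
        for v in config.variants_for(amp_id):
            if rng.random() < v.af:
                target = target[: v.position] + v.alt + target[v.position + 1 :]
                applied.append(f"{v.position}{v.alt}")
        orientation = REVCOMP if rng.random() < config.orientation_prob else FORWARD
        frag = config.spacer5 + target + config.spacer3
        if orientation == REVCOMP:
            frag = reverse_complement(frag)
        units.append(TruthUnit(amp_id, orientation, tuple(applied)))
        frag_seqs.append(frag)

    # --- junction artifacts -------------------------------------------------
    hybrid_overlap: List[Optional[int]] = []
    for _ in range(n_units - 1):
        if rng.random() < config.hybrid_prob:
            hybrid_overlap.append(int(rng.integers(5, 21)))
        else:
            hybrid_overlap.append(None)

    trunc5 = trunc3 = None
    if rng.random() < config.end_truncation_prob:
        trunc5 = int(rng.integers(1, y))
    if rng.random() < config.end_truncation_prob:
        trunc3 = int(rng.integers(1, y))
    remnant_head = remnant_tail = None
    if rng.random() < config.hairpin_remnant_prob:
        remnant_head = "AT"[int(rng.integers(0, 2))]
    if rng.random() < config.hairpin_remnant_prob:
        remnant_tail = "AT"[int(rng.integers(0, 2))]

    # --- assembly -----------------------------------------------------------
    parts: List[str] = []
    intervals: List[TruthInterval] = []
    pos = 0

    def add(kind: str, seq: str, orientation: str = FORWARD,
            unit_index: int = -1, truncated: bool = False) -> None:
        nonlocal pos
        parts.append(seq)
        intervals.append(TruthInterval(kind, pos, pos + len(seq), orientation,
                                       unit_index, truncated))
        pos += len(seq)

    def adapter_seq(orientation: str) -> str:
        return adapter_fw if orientation == FORWARD else adapter_rc

    events: Dict[str, object] = {
        "remnant_head": remnant_head,
        "remnant_tail": remnant_tail,
        "trunc5": trunc5,
        "trunc3": trunc3,
        "hybrid_junctions": [],
    }

    if remnant_head is not None:
        add("remnant", remnant_head)
    lead = adapter_seq(units[0].orientation)
    if trunc5 is not None:
        lead = lead[-trunc5:]  # outer bases of the leading adapter are lost
    add("adapter", lead, units[0].orientation, truncated=trunc5 is not None)
    for j in range(n_units):
        frag = frag_seqs[j]
        if j > 0 and hybrid_overlap[j - 1] is not None:
            h = hybrid_overlap[j - 1]
            events["hybrid_junctions"].append((j - 1, h, pos))  # type: ignore[union-attr]
            frag = frag[h:]  # homology-driven chew into the downstream unit
        add("fragment", frag, units[j].orientation, unit_index=j)
        if j < n_units - 1 and hybrid_overlap[j] is None:
            add("adapter", adapter_seq(units[j + 1].orientation),
                units[j + 1].orientation)
    tail = adapter_seq(units[-1].orientation)
    if trunc3 is not None:
        tail = tail[:trunc3]
    add("adapter", tail, units[-1].orientation, truncated=trunc3 is not None)
    if remnant_tail is not None:
        add("remnant", remnant_tail)

    clean = "".join(parts)
    final = apply_errors(clean, config.sub_rate, config.ins_rate,
                         config.del_rate, rng)
    record = SeqRecord(id=read_id, seq=final, qual=_QUAL_CHAR * len(final))
    truth = TruthRecord(read_id=read_id, units=units, intervals=intervals,
                        events=events)
    return record, truth


def simulate_reads(config: SimConfig) -> Iterator[Tuple[SeqRecord, TruthRecord]]:
    """Generate ``config.n_reads`` reads; deterministic given the seed."""
    rng = np.random.default_rng([int(config.seed), 1])
    for r in range(config.n_reads):
        n = config.nmer.sample(rng)
        yield simulate_read(config, n, rng, read_id=f"read{r:06d}")


def simulate_library(config: SimConfig, out_fastq, out_truth=None) -> Dict[str, float]:
    """Write a library FASTQ plus a truth sidecar; returns summary counts."""
    records: List[SeqRecord] = []
    truths: List[TruthRecord] = []
    for rec, truth in simulate_reads(config):
        records.append(rec)
        truths.append(truth)
    write_fastx(records, out_fastq, "fastq")
    if out_truth is not None:
        write_truth(truths, out_truth)
    total_units = sum(len(t.units) for t in truths)
    total_bases = sum(len(r.seq) for r in records)
    return {
        "n_reads": len(records),
        "total_units": total_units,
        "mean_units_per_read": total_units / len(records) if records else math.nan,
        "total_bases": total_bases,
        "n_hybrid_junctions": sum(len(t.hybrid_positions()) for t in truths),
    }


# ---------------------------------------------------------------------------
# truth sidecar: tab-separated, 0-based half-open read coordinates

_TRUTH_HEADER = "read_id\trow\tindex\tfield1\tfield2\tfield3\tfield4\tfield5"


def write_truth(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as out:
        out.write(_TRUTH_HEADER + "\n")
        for t in truths:
            for i, u in enumerate(t.units):
                applied = ",".join(u.variants_applied) or "-"
                out.write(f"{t.read_id}\tunit\t{i}\t{u.amplicon_id}\t"
                          f"{u.orientation}\t{applied}\t-\t-\n")
            for i, iv in enumerate(t.intervals):
                out.write(f"{t.read_id}\tinterval\t{i}\t{iv.kind}\t{iv.start}\t"
                          f"{iv.end}\t{iv.orientation}\t"
                          f"{iv.unit_index}:{int(iv.truncated)}\n")
            for name in ("remnant_head", "remnant_tail", "trunc5", "trunc3"):
                val = t.events.get(name)
                if val is not None:
                    out.write(f"{t.read_id}\tevent\t0\t{name}\t{val}\t-\t-\t-\n")
            for (j, h, p) in t.events.get("hybrid_junctions", []):  # type: ignore[union-attr]
                out.write(f"{t.read_id}\tevent\t{j}\thybrid\t{h}\t{p}\t-\t-\n")


def read_truth(path) -> List[TruthRecord]:
    out: List[TruthRecord] = []
    current: Optional[TruthRecord] = None
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n") != _TRUTH_HEADER:
            raise ValueError(f"unrecognized truth sidecar header in {path}")
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            read_id, row = fields[0], fields[1]
            if current is None or current.read_id != read_id:
                current = TruthRecord(read_id, [], [], {"hybrid_junctions": []})
                out.append(current)
            if row == "unit":
                applied = () if fields[5] == "-" else tuple(fields[5].split(","))
                current.units.append(TruthUnit(fields[3], fields[4], applied))
            elif row == "interval":
                unit_index, truncated = fields[7].split(":")
                current.intervals.append(TruthInterval(
                    fields[3], int(fields[4]), int(fields[5]), fields[6],
                    int(unit_index), bool(int(truncated))))
            elif row == "event":
                if fields[3] == "hybrid":
                    current.events["hybrid_junctions"].append(  # type: ignore[union-attr]
                        (int(fields[2]), int(fields[4]), int(fields[5])))
                elif fields[3] in ("trunc5", "trunc3"):
                    current.events[fields[3]] = int(fields[4])
                else:
                    current.events[fields[3]] = fields[4]
            else:
                raise ValueError(f"unknown truth row type {row!r} in {path}")
    return out


def read_variants(path) -> List[Variant]:
    """Variant panel TSV: amplicon, position (1-based), ref, alt, af."""
    out: List[Variant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["amplicon", "position", "ref", "alt"]:
            raise ValueError(f"unrecognized variant table header in {path}")
        has_af = len(header) > 4 and header[4] == "af"
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            af = float(f[4]) if has_af and len(f) > 4 and f[4] != "-" else 0.0
            out.append(Variant(f[0], int(f[1]) - 1, f[2], f[3], af))
    return out


def config_from_file(path, seed: Optional[int] = None) -> SimConfig:
    """Build a :class:`SimConfig` from a plain ``key = value`` config file.

    ``panel`` is either a FASTA path (relative to the config file) or
    ``random:<n>`` for a reproducible random panel; ``nmer`` is
    ``fixed:<n>`` or ``geometric:<mean>[:<max>]``.  ``seed`` overrides the
    file's seed when given.
    """
    import os

    from .archmodel import architecture_from_config, read_keyvalue_config

    cfg = read_keyvalue_config(path)
    base = os.path.dirname(os.path.abspath(path))
    arch = architecture_from_config(cfg, base_dir=base)
    kwargs: Dict[str, object] = {"architecture": arch}
    use_seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    kwargs["seed"] = use_seed
    panel_value = cfg.get("panel", "random:4")
    if panel_value.startswith("random:"):
        kwargs["panel"] = random_panel(int(panel_value.split(":")[1]),
                                      arch.target_len, seed=use_seed)
    else:
        from .seqio import read_fastx
        panel_path = os.path.join(base, panel_value)
        kwargs["panel"] = [(r.id, r.seq) for r in read_fastx(panel_path, "fasta")]
    if "nmer" in cfg:
        parts = cfg["nmer"].split(":")
        if parts[0] == "fixed":
            kwargs["nmer"] = NmerDistribution("fixed", int(parts[1]), int(parts[1]))
        else:
            max_n = int(parts[2]) if len(parts) > 2 else 50
            kwargs["nmer"] = NmerDistribution("geometric", int(parts[1]), max_n)
    for key in ("orientation_prob", "sub_rate", "ins_rate", "del_rate",
                "hairpin_remnant_prob", "end_truncation_prob", "hybrid_prob"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    if "n_reads" in cfg:
        kwargs["n_reads"] = int(cfg["n_reads"])
    if "panel_weights" in cfg:
        kwargs["panel_weights"] = [float(x) for x in cfg["panel_weights"].split(",")]
    if "variants" in cfg:
        kwargs["variants"] = tuple(read_variants(os.path.join(base, cfg["variants"])))
    if "spacer5" in cfg:
        kwargs["spacer5"] = cfg["spacer5"]
    if "spacer3" in cfg:
        kwargs["spacer3"] = cfg["spacer3"]
    return SimConfig(**kwargs)  # type: ignore[arg-type]


def write_variants(variants: Sequence[Variant], path) -> None:
    with open(path, "w") as out:
        out.write("amplicon\tposition\tref\talt\taf\n")
        for v in variants:
            out.write(f"{v.amplicon_id}\t{v.position + 1}\t{v.ref}\t{v.alt}\t{v.af}\n")
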