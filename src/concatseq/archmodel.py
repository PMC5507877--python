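"""Library-geometry model of concatemer amplicon libraries.

A sequencing unit ("monomer") is a target amplicon flanked by constant
spacers and one copy of the concatenation adapter on each end:

    monomer length  x = target + spacer5 + spacer3 + 2*y
    fragment length f = target + spacer5 + spacer3        (x = f + 2*y)

where ``y`` is the adapter length.  Assembly merges the adjacent adapter
copies of neighbouring units, so a concatemer of ``n`` units (an "n-mer")
carries ``n`` fragments separated/flanked by ``n + 1`` adapters and has
expected length ``n*x - (n-1)*y``.

The default architecture is a 120 bp target with 33 + 34 bp of spacer
(fragment 187 bp) and a 30 bp adapter (monomer 247 bp).
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field
from typing import Dict, Optional

from .seqio import read_fastx

#: Bundled default adapter: 30 bp, GC fraction exactly 0.40 (12/30), no
#: homopolymer run longer than 2, edit distance 12 to its own reverse
#: complement (orientation calls stay unambiguous at any scan threshold <= 6).
DEFAULT_ADAPTER_SEQUENCE = "TAGCATACGTTCATGGATCAATGTTACGCA"


@dataclass(frozen=True)
class AdapterSpec:
    """A named concatenation-adapter sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("adapter sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"adapter contains non-ACGT characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def default_adapter() -> AdapterSpec:
    return AdapterSpec(name="concatseq-default", sequence=DEFAULT_ADAPTER_SEQUENCE)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    if not seq:
        return 0
    return max(len(m.group()) for m in re.finditer(r"(.)\1*", seq))


@dataclass(frozen=True)
class ArchitectureSpec:
    """Geometry of one library design (all lengths in bases)."""

    target_len: int = 120
    spacer5_len: int = 33
    spacer3_len: int = 34
    adapter: AdapterSpec = field(default_factory=default_adapter)

    def __post_init__(self) -> None:
        for name in ("target_len", "spacer5_len", "spacer3_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def fragment_len(self) -> int:
        """Target plus flanking spacers — the unit left after adapter removal."""
        return self.target_len + self.spacer5_len + self.spacer3_len

    @property
    def monomer_len(self) -> int:
        """Adapter-flanked unit length x = fragment + 2*len(adapter)."""
        return self.fragment_len + 2 * len(self.adapter)


def expected_nmer_length(n: int, x: int, y: int) -> int:
    """Expected length of an n-mer: ``n*x - (n-1)*y``.

    ``x`` is the monomer size and ``y`` the adapter size; each unit beyond
    the first adds ``x - y`` bases because adjacent adapter copies merge.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if x < 2 * y:
        raise ValueError(f"monomer size x={x} must be >= 2*y (y={y})")
    return n * x - (n - 1) * y


def with_adapters(core_len: int, y: int) -> int:
    """Length after appending one adapter of length ``y`` to each end."""
    if core_len < 0 or y < 0:
        raise ValueError("lengths must be >= 0")
    return core_len + 2 * y


def gc_fraction(seq: str) -> float:
    """Fraction of G or C bases; ambiguous bases are rejected."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous/invalid characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def scaleup_factor(fraction_retained: float) -> float:
    """Input-mass multiplier so a retained sub-population matches the library.

    If size selection keeps a fraction ``q`` of the reads (e.g. q = 0.079 for
    reads with 10+ fragments), ``1/q`` times more concatenated library must
    enter the selection step for the retained part alone to equal the
    original amount.
    """
    if not 0 < fraction_retained <= 1:
        raise ValueError("fraction_retained must be in (0, 1]")
    return 1.0 / fraction_retained


# ---------------------------------------------------------------------------
# plain key-value configuration files


def read_keyvalue_config(path) -> Dict[str, str]:
    """Parse a plain ``key = value`` config file ('#' starts a comment)."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def adapter_from_value(value: str, base_dir: Optional[str] = None) -> AdapterSpec:
    """An adapter given either literally or as a path to a 1-record FASTA."""
    if set(value) <= set("ACGT") and value:
        return AdapterSpec(name="adapter", sequence=value)
    path = value if base_dir is None else os.path.join(base_dir, value)
    records = list(read_fastx(path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"adapter FASTA {path} must contain exactly one record")
    return AdapterSpec(name=records[0].id, sequence=records[0].seq)


def architecture_from_config(cfg: Dict[str, str], base_dir: Optional[str] = None) -> ArchitectureSpec:
    """Build an :class:`ArchitectureSpec` from a parsed key-value config."""
    kwargs = {}
    for key in ("target_len", "spacer5_len", "spacer3_len"):
        if key in cfg:
            kwargs[key] = int(cfg[key])
    if "adapter" in cfg:
        kwargs["adapter"] = adapter_from_value(cfg["adapter"], base_dir)
    return ArchitectureSpec(**kwargs)


def check_design(adapter: AdapterSpec, expected_len: int = 30,
                 expected_gc: float = 0.40, max_run: int = 4) -> None:
    """Assert the assembly-efficiency design constraints on an adapter."""
    if len(adapter) != expected_len:
        raise ValueError(f"adapter length {len(adapter)} != {expected_len}")
    gc = gc_fraction(adapter.sequence)
    if not math.isclose(gc, expected_gc, abs_tol=1e-12):
        raise ValueError(f"adapter GC fraction {gc} != {expected_gc}")
    if max_homopolymer(adapter.sequence) > max_run:
        raise ValueError("adapter contains a homopolymer run longer than allowed")
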