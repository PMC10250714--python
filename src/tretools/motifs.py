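"""Degenerate direct-repeat motif patterns and the two-strand scanner.

Nuclear-receptor response elements are built from a hexameric halfsite
(canonically 5'-AGGTCA-3'); the thyroid-hormone receptor complex prefers a
direct repeat of two halfsites spaced by four bases (DR4).  Three search
patterns are built in:

``halfsite``
    ``[AG]-G-G-N-C-A``, no mismatches allowed.
``dr4``
    ``[AG]-[G]-G-N-C-A-N-N-N-N-[AG]-[G]-G-N-C-A`` — two halfsites with a
    fixed 4-base spacer, no mismatches.
``dr0_6``
    ``[AG]-[G]-G-[AT]-C-A-N(0,6)-[AG]-[G]-G-[AT]-C-A`` — spacer of 0-6
    bases, up to two mismatches counted jointly over both halfsites.

Mismatches are counted only at informative positions (spacer bases and
fully degenerate N positions contribute zero); an N residue in the sequence
never satisfies an informative position.  Both strands are scanned by
default; minus-strand matches are found on the reverse complement and
reported in forward coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GenomeSequence

__all__ = [
    "HalfsitePattern",
    "DirectRepeatPattern",
    "MotifHit",
    "compile_pattern",
    "count_mismatches",
    "scan_sequence",
    "scan_genome",
    "write_hits",
    "read_hits",
    "hits_to_frame",
    "reverse_complement",
    "builtin_patterns",
    "BASES",
]

BASES = "ACGT"
_ALL = frozenset(BASES)
_BASE_INDEX = {b: i for i, b in enumerate(BASES + "N")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENC[ord(_b)] = _i


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HalfsitePattern:
    """A positional pattern: one allowed-base set per position."""

    name: str
    positions: tuple[frozenset, ...]
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pattern must have at least one position")
        for s in self.positions:
            if not s or not s <= _ALL:
                raise ValueError(f"invalid allowed-base set {set(s)!r}")

    @property
    def length(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DirectRepeatPattern:
    """Two halfsites separated by an uninformative spacer of variable length."""

    name: str
    halfsite_a: HalfsitePattern
    halfsite_b: HalfsitePattern
    spacer_min: int
    spacer_max: int
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.spacer_min <= self.spacer_max:
            raise ValueError(
                f"need 0 <= spacer_min <= spacer_max, got "
                f"({self.spacer_min}, {self.spacer_max})"
            )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def length(self, spacer: int) -> int:
        return self.halfsite_a.length + spacer + self.halfsite_b.length

    def positions_at(self, spacer: int) -> tuple[frozenset, ...]:
        """Positional sets for a fixed spacer; spacer bases are fully degenerate."""
        if not self.spacer_min <= spacer <= self.spacer_max:
            raise ValueError(f"spacer {spacer} outside [{self.spacer_min}, {self.spacer_max}]")
        return (
            self.halfsite_a.positions + (_ALL,) * spacer + self.halfsite_b.positions
        )


Pattern = Union[HalfsitePattern, DirectRepeatPattern]


@dataclass(frozen=True)
class MotifHit:
    """One located match on a strand, in 0-based half-open forward coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    pattern_name: str
    spacer_len: int | None
    mismatches: int


_TOKEN = re.compile(r"^(?:([ACGTN])|\[([ACGT]+)\]|N\((\d+),(\d+)\))$")


def _parse_tokens(spec: str) -> list:
    out = []
    for tok in spec.strip().split("-"):
        m = _TOKEN.match(tok)
        if m is None:
            raise ValueError(f"malformed pattern token {tok!r}")
        if m.group(1):
            out.append(_ALL if m.group(1) == "N" else frozenset(m.group(1)))
        elif m.group(2):
            out.append(frozenset(m.group(2)))
        else:
            out.append((int(m.group(3)), int(m.group(4))))
    return out


def _fixed_spacer_split(sets: list[frozenset]) -> tuple[int, int] | None:
    # Longest interior run of fully degenerate positions leaving equal-length
    # flanks; such a run is a fixed spacer between two halfsites.
    best = None
    i = 0
    n = len(sets)
    while i < n:
        if sets[i] == _ALL and 0 < i:
            j = i
            while j < n and sets[j] == _ALL:
                j += 1
            if j < n and i == n - j and (best is None or j - i > best[1] - best[0]):
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def compile_pattern(spec: str, name: str = "custom", max_mismatches: int = 0) -> Pattern:
    """Compile a bracket-notation pattern string.

    Tokens are single bases (``G``), allowed-base sets (``[AG]``), ``N``
    (any base) and one optional spacer token ``N(min,max)``.  A pattern with
    a spacer token — or with a central run of plain ``N`` tokens flanked by
    equal-length halfsites — compiles to a :class:`DirectRepeatPattern`;
    anything else is a :class:`HalfsitePattern`.
    """
    tokens = _parse_tokens(spec)
    spacer_idx = [i for i, t in enumerate(tokens) if isinstance(t, tuple)]
    if len(spacer_idx) > 1:
        raise ValueError("at most one N(min,max) spacer token is allowed")
    if spacer_idx:
        i = spacer_idx[0]
        if i == 0 or i == len(tokens) - 1:
            raise ValueError("spacer token must be interior")
        a = tuple(tokens[:i])
        b = tuple(tokens[i + 1 :])
        lo, hi = tokens[i]
        return DirectRepeatPattern(
            name,
            HalfsitePattern(f"{name}_a", a),
            HalfsitePattern(f"{name}_b", b),
            lo,
            hi,
            max_mismatches,
        )
    split = _fixed_spacer_split(tokens)
    if split is not None:
        i, j = split
        return DirectRepeatPattern(
            name,
            HalfsitePattern(f"{name}_a", tuple(tokens[:i])),
            HalfsitePattern(f"{name}_b", tuple(tokens[j:])),
            j - i,
            j - i,
            max_mismatches,
        )
    return HalfsitePattern(name, tuple(tokens), max_mismatches)


def builtin_patterns() -> dict[str, Pattern]:
    """The three search patterns with their standard mismatch allowances."""
    return {
        "halfsite": compile_pattern("[AG]-G-G-N-C-A", "halfsite", 0),
        "dr4": compile_pattern(
            "[AG]-[G]-G-N-C-A-N-N-N-N-[AG]-[G]-G-N-C-A", "dr4", 0
        ),
        "dr0_6": compile_pattern(
            "[AG]-[G]-G-[AT]-C-A-N(0,6)-[AG]-[G]-G-[AT]-C-A", "dr0_6", 2
        ),
    }


def _position_sets(pattern: Pattern, spacer: int | None) -> tuple[frozenset, ...]:
    if isinstance(pattern, HalfsitePattern):
        return pattern.positions
    if spacer is None:
        raise ValueError("direct-repeat pattern requires a fixed spacer")
    return pattern.positions_at(spacer)


def count_mismatches(window: str, pattern: Pattern, spacer: int | None = None) -> int:
    """Mismatch count of ``window`` against a pattern at a fixed spacer.

    Only informative positions count; an N residue at an informative
    position is a mismatch.
    """
    sets = _position_sets(pattern, spacer)
    if len(window) != len(sets):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(sets)}"
        )
    mm = 0
    for base, allowed in zip(window.upper(), sets):
        if allowed == _ALL:
            continue
        if base not in allowed:
            mm += 1
    return mm


def _miss_rows(positions: Sequence[frozenset]) -> np.ndarray:
    """(n_positions, 5) bool array: True where residue code mismatches."""
    rows = np.ones((len(positions), 5), dtype=bool)
    for i, allowed in enumerate(positions):
        for b in allowed:
            rows[i, _BASE_INDEX[b]] = False
        # residue N satisfies only fully degenerate positions
        rows[i, 4] = allowed != _ALL
    return rows


def _mismatch_profile(code: np.ndarray, rows: np.ndarray) -> np.ndarray:
    m = rows.shape[0]
    n = code.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for j in range(m):
        miss = rows[j]
        if miss.any():
            mm += miss[code[j : j + n]]
    return mm


def _scan_one_strand(code: np.ndarray, pattern: Pattern):
    """Yield (start, length, spacer, mismatches) on the given encoded strand."""
    if isinstance(pattern, HalfsitePattern):
        mm = _mismatch_profile(code, _miss_rows(pattern.positions))
        for s in np.flatnonzero(mm <= pattern.max_mismatches):
            yield int(s), pattern.length, None, int(mm[s])
        return
    rows_a = _miss_rows(pattern.halfsite_a.positions)
    rows_b = _miss_rows(pattern.halfsite_b.positions)
    mm_a = _mismatch_profile(code, rows_a)
    mm_b = _mismatch_profile(code, rows_b)
    la = pattern.halfsite_a.length
    for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
        length = pattern.length(spacer)
        n = code.size - length + 1
        if n <= 0:
            continue
        total = mm_a[:n] + mm_b[la + spacer : la + spacer + n]
        for s in np.flatnonzero(total <= pattern.max_mismatches):
            yield int(s), length, spacer, int(total[s])


def scan_sequence(
    seq: GenomeSequence, pattern: Pattern, both_strands: bool = True
) -> list[MotifHit]:
    """Scan one sequence for a pattern, over all spacer lengths and strands.

    Minus-strand matching runs on the reverse complement with intervals
    mapped back to forward coordinates.  Hits identical in
    (seq_id, start, end, strand, pattern) are merged keeping the lowest
    mismatch count; overlapping but distinct hits are all retained.
    """
    L = len(seq.residues)
    best: dict[tuple, MotifHit] = {}

    def _collect(code: np.ndarray, strand: str) -> None:
        for s, length, spacer, mm in _scan_one_strand(code, pattern):
            if strand == "+":
                start, end = s, s + length
            else:
                start, end = L - s - length, L - s
            key = (start, end, strand)
            prev = best.get(key)
            if prev is None or mm < prev.mismatches:
                best[key] = MotifHit(
                    seq.seq_id, start, end, strand, pattern.name, spacer, mm
                )

    fwd = _ENC[np.frombuffer(seq.residues.encode(), dtype=np.uint8)]
    _collect(fwd, "+")
    if both_strands:
        rc = _ENC[np.frombuffer(reverse_complement(seq.residues).encode(), dtype=np.uint8)]
        _collect(rc, "-")
    return sorted(best.values(), key=lambda h: (h.start, h.end, h.strand))


def scan_genome(
    seqs: Iterable[GenomeSequence],
    patterns: Iterable[Pattern],
    both_strands: bool = True,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for seq in seqs:
        for pattern in patterns:
            hits.extend(scan_sequence(seq, pattern, both_strands))
    return hits


_HIT_COLUMNS = ["seq_id", "start", "end", "strand", "pattern", "spacer", "mismatches"]


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.seq_id, h.start, h.end, h.strand, h.pattern_name, h.spacer_len, h.mismatches)
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )


def write_hits(
    hits: Sequence[MotifHit], path: str | Path, bed_path: str | Path | None = None
) -> None:
    """Write hits as CSV (and optionally BED6 with the pattern name)."""
    hits_to_frame(hits).to_csv(path, index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for h in hits:
                fh.write(
                    f"{h.seq_id}\t{h.start}\t{h.end}\t{h.pattern_name}\t"
                    f"{h.mismatches}\t{h.strand}\n"
                )


def read_hits(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        spacer = None if pd.isna(row.spacer) else int(row.spacer)
        out.append(
            MotifHit(
                str(row.seq_id), int(row.start), int(row.end), str(row.strand),
                str(row.pattern), spacer, int(row.mismatches),
            )
        )
    return out
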