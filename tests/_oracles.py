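"""Independent brute-force oracles, deliberately naive.

These re-derive expected results position by position with plain Python,
sharing no scanning or counting code with the package.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def brute_mismatches(window: str, sets: list[set]) -> int:
    """Position-by-position mismatch count; N residue fails non-degenerate sets."""
    assert len(window) == len(sets)
    mm = 0
    for base, allowed in zip(window, sets):
        if allowed == {"A", "C", "G", "T"}:
            continue
        if base not in allowed:
            mm += 1
    return mm


def brute_scan(
    residues: str,
    half_a: list[set],
    half_b: list[set] | None,
    spacer_range: tuple[int, int],
    max_mm: int,
    both_strands: bool = True,
) -> set[tuple]:
    """Every (start, end, strand) with min mismatches <= max_mm.

    ``half_b=None`` means a lone halfsite (spacer_range ignored).
    Returns {(start, end, strand, mismatches)} with forward coordinates,
    keeping the minimum mismatch count per interval/strand.
    """
    L = len(residues)
    found: dict[tuple, int] = {}

    def scan_one(seq: str, strand: str) -> None:
        if half_b is None:
            combos = [half_a]
        else:
            combos = [
                half_a + [{"A", "C", "G", "T"}] * sp + half_b
                for sp in range(spacer_range[0], spacer_range[1] + 1)
            ]
        for sets in combos:
            m = len(sets)
            for start in range(L - m + 1):
                mm = brute_mismatches(seq[start : start + m], sets)
                if mm <= max_mm:
                    if strand == "+":
                        key = (start, start + m, "+")
                    else:
                        key = (L - start - m, L - start, "-")
                    if key not in found or mm < found[key]:
                        found[key] = mm

    scan_one(residues, "+")
    if both_strands:
        scan_one(revcomp(residues), "-")
    return {(s, e, st, mm) for (s, e, st), mm in found.items()}


HALF = [{"A", "G"}, {"G"}, {"G"}, {"A", "C", "G", "T"}, {"C"}, {"A"}]
HALF_AT = [{"A", "G"}, {"G"}, {"G"}, {"A", "T"}, {"C"}, {"A"}]


def brute_scan_pattern(residues: str, which: str, both_strands: bool = True) -> set[tuple]:
    if which == "halfsite":
        return brute_scan(residues, HALF, None, (0, 0), 0, both_strands)
    if which == "dr4":
        return brute_scan(residues, HALF, HALF, (4, 4), 0, both_strands)
    if which == "dr0_6":
        return brute_scan(residues, HALF_AT, HALF_AT, (0, 6), 2, both_strands)
    raise ValueError(which)


def brute_threshold(deg_counts: list[int], min_degs: int) -> int:
    """Largest K in [1, max] with >= min_degs DEG counts >= K, else 1."""
    best = None
    for k in range(1, max(deg_counts, default=0) + 1):
        if sum(c >= k for c in deg_counts) >= min_degs:
            best = k
    return best if best is not None else 1
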