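"""Associate motif hits with genes through their promoter windows.

A hit is credited to a gene when the hit's *start* coordinate lies inside
the gene's promoter window (half-open).  A hit may be credited to several
genes when windows overlap; genes with no nearby hits receive explicit
zeros so the gene universe is fixed for downstream enrichment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, PromoterWindow
from .motifs import MotifHit

__all__ = ["associate", "distance_to_tss", "counts_to_tsv", "read_counts"]


def associate(
    hits: Sequence[MotifHit],
    windows: Sequence[PromoterWindow],
    patterns: Iterable[str] | None = None,
    seq_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene hit tallies, one row per gene and one column per pattern.

    Parameters
    ----------
    hits, windows
        Scanner output and the promoter windows to credit hits to.
    patterns
        Pattern names to tally.  Defaults to the names present in ``hits``;
        pass explicitly to get zero columns when a pattern found nothing.
    seq_ids
        Known sequence-id universe.  When given, a window referencing an
        unknown sequence raises; otherwise the namespace is taken on trust.

    Returns
    -------
    DataFrame indexed by ``gene_id`` with integer count columns, every input
    gene present (zero counts included).
    """
    if seq_ids is not None:
        known = set(seq_ids)
        for w in windows:
            if w.seq_id not in known:
                raise ValueError(
                    f"window for {w.gene_id} references unknown sequence {w.seq_id!r}"
                )
    if patterns is None:
        names = sorted({h.pattern_name for h in hits})
    else:
        names = list(patterns)
    gene_ids = [w.gene_id for w in windows]
    counts = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=names)

    # sorted hit-start arrays per (seq_id, pattern) -> O(log H) per window
    starts: dict[tuple[str, str], np.ndarray] = {}
    for (sid, pat), group in _group_hits(hits):
        starts[(sid, pat)] = np.sort(group)
    for w in windows:
        for pat in names:
            arr = starts.get((w.seq_id, pat))
            if arr is None:
                continue
            n = np.searchsorted(arr, w.end, side="left") - np.searchsorted(
                arr, w.start, side="left"
            )
            if n:
                counts.loc[w.gene_id, pat] += int(n)
    return counts


def _group_hits(hits: Sequence[MotifHit]):
    groups: dict[tuple[str, str], list[int]] = {}
    for h in hits:
        groups.setdefault((h.seq_id, h.pattern_name), []).append(h.start)
    for key, val in groups.items():
        yield key, np.asarray(val, dtype=np.int64)


def distance_to_tss(hit: MotifHit, gene: GeneModel) -> int:
    """Strand-aware signed distance from hit start to TSS (negative = upstream)."""
    if hit.seq_id != gene.seq_id:
        raise ValueError(
            f"hit on {hit.seq_id!r} cannot be compared with gene on {gene.seq_id!r}"
        )
    if gene.strand == "+":
        return hit.start - gene.tss
    return gene.tss - hit.start


def min_abs_distances(
    hits: Sequence[MotifHit],
    genes: Sequence[GeneModel],
    windows: Sequence[PromoterWindow],
) -> pd.DataFrame:
    """Minimum |distance to TSS| among in-window hits, per gene and pattern."""
    by_gene = {g.gene_id: g for g in genes}
    win_by_gene = {w.gene_id: w for w in windows}
    rows = []
    for h in hits:
        for gid, w in win_by_gene.items():
            if h.seq_id == w.seq_id and w.start <= h.start < w.end:
                rows.append((gid, h.pattern_name, abs(distance_to_tss(h, by_gene[gid]))))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "pattern", "min_abs_distance"])
    df = pd.DataFrame(rows, columns=["gene_id", "pattern", "min_abs_distance"])
    return df.groupby(["gene_id", "pattern"], as_index=False)["min_abs_distance"].min()


def counts_to_tsv(
    counts: pd.DataFrame,
    path: str | Path,
    distances: pd.DataFrame | None = None,
) -> None:
    """Write counts in long form: gene_id, pattern, count[, min_abs_distance]."""
    long = counts.reset_index().melt(
        id_vars="gene_id", var_name="pattern", value_name="count"
    )
    if distances is not None and len(distances):
        long = long.merge(distances, on=["gene_id", "pattern"], how="left")
    long.sort_values(["pattern", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a long-form counts TSV back into the wide gene x pattern table."""
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(
        index="gene_id", columns="pattern", values="count", fill_value=0
    ).astype(int)
    wide.columns.name = None
    return wide
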