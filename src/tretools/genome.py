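"""Genome sequences, gene models, and promoter windows.

All coordinates are 0-based, half-open internally; GFF3 I/O converts to and
from the 1-based inclusive convention of that format.  The transcription
start site (TSS) of a gene is the first transcribed base: the GFF ``start``
column for plus-strand features and the GFF ``end`` column for minus-strand
features, each converted to 0-based.

The promoter window used throughout the package spans 500 bp upstream of the
TSS through 20 bp downstream (521 bases including the TSS itself when no
clamping occurs); windows are clamped at sequence boundaries rather than
discarded, so the gene universe stays fixed for enrichment denominators.
"""

from __future__ import annotations

import re
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "PromoterWindow",
    "read_genome",
    "write_genome",
    "read_gene_models",
    "write_gene_models",
    "promoter_window",
    "promoter_windows",
    "windows_to_bed",
]

_VALID = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome/contig with uppercase residues over {A,C,G,T,N}."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """A gene object (one per mRNA locus) with a strand-aware TSS.

    ``tss`` is the 0-based genomic coordinate of the predicted transcription
    initiation site.  ``start``/``end`` record the full feature extent
    (0-based half-open) when known, and are only used for GFF3 round trips.
    """

    gene_id: str
    seq_id: str
    strand: str
    tss: int
    start: int | None = field(default=None, compare=False)
    end: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


@dataclass(frozen=True)
class PromoterWindow:
    """0-based half-open genomic interval around a gene's TSS."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"window for {self.gene_id} is empty: [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into :class:`GenomeSequence` records.

    Residues are uppercased; characters outside {A,C,G,T,N} (IUPAC
    ambiguity codes, gaps, ...) are mapped to N with a warning.  An empty
    file or a duplicate sequence id is an error.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        n_bad = len(_VALID.findall(residues))
        if n_bad:
            warnings.warn(
                f"{rec.id}: {n_bad} non-ACGTN residues mapped to N", stacklevel=2
            )
            residues = _VALID.sub("N", residues)
        records.append(GenomeSequence(rec.id, residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_genome(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_gene_models(
    path: str | Path,
    feature_kind: str = "mRNA",
    seq_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per feature.

    Each record of ``feature_kind`` becomes its own gene object (mRNA loci
    are not collapsed onto parent genes).  The TSS is the GFF ``start`` for
    plus-strand and ``end`` for minus-strand features, 0-based.  Records
    with no strand or no ID attribute are skipped with a warning; a TSS
    falling outside its sequence (when ``seq_lengths`` is given) is an
    error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    for feat in db.features_of_type(feature_kind, order_by=("seqid", "start")):
        ids = feat.attributes.get("ID")
        if not ids:
            warnings.warn(
                f"{feature_kind} at {feat.seqid}:{feat.start} has no ID attribute; skipped",
                stacklevel=2,
            )
            continue
        gene_id = ids[0]
        if feat.strand not in ("+", "-"):
            warnings.warn(f"{gene_id} has no strand; skipped", stacklevel=2)
            continue
        if gene_id in seen_ids:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seen_ids.add(gene_id)
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        if seq_lengths is not None:
            seq_len = seq_lengths.get(feat.seqid)
            if seq_len is None:
                raise ValueError(f"{gene_id}: unknown sequence {feat.seqid!r}")
            if not 0 <= tss < seq_len:
                raise ValueError(
                    f"{gene_id}: tss {tss} outside sequence {feat.seqid} "
                    f"(length {seq_len})"
                )
        genes.append(
            GeneModel(gene_id, feat.seqid, feat.strand, tss, feat.start - 1, feat.end)
        )
    return genes


def write_gene_models(
    genes: Iterable[GeneModel], path: str | Path, feature_kind: str = "mRNA"
) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.start is not None and g.end is not None:
                start1, end1 = g.start + 1, g.end
            else:
                start1 = end1 = g.tss + 1
            fh.write(
                f"{g.seq_id}\ttretools\t{feature_kind}\t{start1}\t{end1}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def promoter_window(
    gene: GeneModel,
    seq_len: int,
    upstream: int = 500,
    downstream: int = 20,
) -> PromoterWindow:
    """The promoter window of a gene, clamped to the sequence bounds.

    Plus strand: ``[tss - upstream, tss + downstream + 1)``; minus strand is
    the mirror image.  The TSS base is always inside the window, so the
    unclamped width is ``upstream + downstream + 1``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream + 1
    else:
        start, end = gene.tss - downstream, gene.tss + upstream + 1
    start = max(start, 0)
    end = min(end, seq_len)
    return PromoterWindow(gene.gene_id, gene.seq_id, start, end, gene.strand)


def promoter_windows(
    genes: Iterable[GeneModel],
    seq_lengths: Mapping[str, int],
    upstream: int = 500,
    downstream: int = 20,
) -> list[PromoterWindow]:
    """Promoter windows for a collection of genes (one per mRNA locus)."""
    out = []
    for g in genes:
        if g.seq_id not in seq_lengths:
            raise ValueError(f"{g.gene_id}: unknown sequence {g.seq_id!r}")
        out.append(promoter_window(g, seq_lengths[g.seq_id], upstream, downstream))
    return out


def windows_to_bed(windows: Sequence[PromoterWindow], path: str | Path) -> None:
    """Export windows as BED6; the score column carries a stable gene-id hash."""
    with open(path, "w") as fh:
        for w in windows:
            score = zlib.crc32(w.gene_id.encode()) % 1000
            fh.write(
                f"{w.seq_id}\t{w.start}\t{w.end}\t{w.gene_id}\t{score}\t{w.strand}\n"
            )
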