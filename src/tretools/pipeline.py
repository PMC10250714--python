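"""Run configuration and the scan -> associate -> enrich pipeline.

Stages compose through files (hits CSV, counts TSV, enrichment TSVs) so
each is independently testable and rerunnable; every run writes its
resolved configuration and a log next to its outputs, and identical
configurations with identical seeds produce byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import associate, counts_to_tsv, min_abs_distances
from .enrichment import TreEnrichmentModel
from .genome import promoter_windows, read_gene_models, read_genome
from .motifs import builtin_patterns, compile_pattern, scan_genome, write_hits

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("tretools")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (serializable to YAML)."""

    genome: str
    gff: str
    expression: str
    out_dir: str
    patterns: list[str] = field(default_factory=lambda: ["halfsite", "dr4", "dr0_6"])
    feature_kind: str = "mRNA"
    upstream: int = 500
    downstream: int = 20
    alpha: float = 0.05
    fold_cut: float = 2.0
    min_degs: int = 50
    contrasts: list[str] | None = None
    both_strands: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("genome", "gff", "expression"):
            path = getattr(self, name)
            if not path:
                raise PipelineError(f"config field {name!r} is missing")
            if not Path(path).exists():
                raise PipelineError(f"config field {name!r}: no such file {path!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("scan")
def _scan(config: RunConfig, seqs):
    builtins = builtin_patterns()
    patterns = []
    for name in config.patterns:
        if name in builtins:
            patterns.append(builtins[name])
        elif Path(name).exists():
            spec = Path(name).read_text().strip()
            patterns.append(compile_pattern(spec, Path(name).stem))
        else:
            raise PipelineError(f"stage 'scan' failed: unknown pattern {name!r}")
    return scan_genome(seqs, patterns, config.both_strands), [p.name for p in patterns]


@_stage("associate")
def _associate(config: RunConfig, hits, genes, seq_lengths, pattern_names):
    windows = promoter_windows(genes, seq_lengths, config.upstream, config.downstream)
    counts = associate(hits, windows, patterns=pattern_names, seq_ids=seq_lengths)
    distances = min_abs_distances(hits, genes, windows)
    return counts, distances


@_stage("enrich")
def _enrich(config: RunConfig, counts, expression):
    model = TreEnrichmentModel(
        counts, expression, alpha=config.alpha,
        fold_cut=config.fold_cut, min_degs=config.min_degs,
    )
    return model.fit_all(contrasts=config.contrasts)


def run_pipeline(config: RunConfig) -> Path:
    """Execute scan -> associate -> enrich and write all result tables.

    Returns the output directory.  Outputs: ``hits.csv``, ``counts.tsv``,
    ``enrichment.tsv``, ``run_config.yaml`` and ``run.log``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_lines = [f"tretools {__version__}"]
    try:
        seqs = read_genome(config.genome)
    except Exception as exc:
        raise PipelineError(f"stage 'read_genome' failed: {exc}") from exc
    seq_lengths = {s.seq_id: s.length for s in seqs}
    try:
        genes = read_gene_models(config.gff, config.feature_kind, seq_lengths)
        expression = pd.read_csv(config.expression, sep=None, engine="python")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'read_inputs' failed: {exc}") from exc

    hits, pattern_names = _scan(config, seqs)
    write_hits(hits, out / "hits.csv", out / "hits.bed")
    log_lines.append(f"scan: {len(hits)} hits for patterns {pattern_names}")

    counts, distances = _associate(config, hits, genes, seq_lengths, pattern_names)
    counts_to_tsv(counts, out / "counts.tsv", distances)
    log_lines.append(f"associate: {len(counts)} genes")

    results = _enrich(config, counts, expression)
    results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    log_lines.append(f"enrich: {len(results)} pattern x contrast results")

    config.to_file(out / "run_config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return out
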