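"""Synthetic genomes, expression tables and binding curves with known truth.

Every pipeline stage can be exercised end to end without external data:

* a random i.i.d. genome with genes at regular spacing on alternating
  strands (i.i.d. background keeps motif occurrence probabilities in
  closed form);
* zero-mismatch motif instances planted at non-overlapping positions inside
  the promoter windows of a random gene subset, with a truth table;
* a differential-expression table in which planted-TRE genes carry an
  additive log2-fold-change effect of random sign plus Gaussian noise, with
  normal-theory p-values and Benjamini-Hochberg adjustment;
* noisy binding curves drawn from the one-site models on the assay's
  18-point 3-fold dilution design.

All generators require an explicit seed and are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binding import DilutionSeries, competition_model, saturation_model
from .genome import GeneModel, GenomeSequence, promoter_window
from .motifs import DirectRepeatPattern, HalfsitePattern, Pattern

__all__ = [
    "gen_genome_and_genes",
    "plant_tres",
    "gen_expression",
    "gen_binding",
    "expected_fold_ratio",
    "folded_normal_mean",
    "pattern_match_probability",
]


def gen_genome_and_genes(
    n_genes: int,
    gene_spacing: int = 2000,
    gc_content: float = 0.4,
    seed: int | None = None,
    flank: int = 1000,
    seq_id: str = "chr1",
    seq_len: int | None = None,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """One chromosome of i.i.d. bases with evenly spaced genes.

    Genes sit at ``flank + i * gene_spacing`` with alternating strands so
    promoter windows never overlap for the default spacing.  ``seq_len``
    defaults to exactly fitting the genes plus flanks; an explicit shorter
    value is an error.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    if seed is None:
        raise ValueError("an explicit seed is required")
    needed = flank + (n_genes - 1) * gene_spacing + 500 + flank
    if seq_len is None:
        seq_len = needed
    elif seq_len < needed:
        raise ValueError(
            f"seq_len {seq_len} too short for {n_genes} genes (need {needed})"
        )
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=seq_len, p=p)
    residues = bases.tobytes().decode()
    genes = []
    for i in range(n_genes):
        tss = flank + i * gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, min(tss + 500, seq_len)
        else:
            start, end = max(tss - 499, 0), tss + 1
        genes.append(GeneModel(f"gene_{i:05d}", seq_id, strand, tss, start, end))
    return GenomeSequence(seq_id, residues), genes


def _realize_instance(pattern: Pattern, rng: np.random.Generator) -> str:
    """A concrete zero-mismatch sequence drawn from the pattern."""

    def draw(positions) -> str:
        return "".join(rng.choice(sorted(s)) for s in positions)

    if isinstance(pattern, HalfsitePattern):
        return draw(pattern.positions)
    spacer = int(rng.integers(pattern.spacer_min, pattern.spacer_max + 1))
    mid = "".join(rng.choice(list("ACGT"), size=spacer))
    return draw(pattern.halfsite_a.positions) + mid + draw(pattern.halfsite_b.positions)


def plant_tres(
    genome: GenomeSequence,
    genes: list[GeneModel],
    fraction_affected: float,
    count_per_gene: int,
    pattern: Pattern,
    seed: int | None = None,
    upstream: int = 500,
    downstream: int = 20,
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Overwrite promoter positions of a random gene subset with motif instances.

    Instances are zero-mismatch, forward-oriented and non-overlapping within
    each window.  Returns the modified genome and a truth table with columns
    ``gene_id``, ``affected``, ``planted_count``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if not 0.0 <= fraction_affected <= 1.0:
        raise ValueError("fraction_affected must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_aff = int(round(fraction_affected * len(genes)))
    affected_idx = set(
        rng.choice(len(genes), size=n_aff, replace=False).tolist()
    )
    residues = list(genome.residues)
    rows = []
    for i, gene in enumerate(genes):
        planted = 0
        if i in affected_idx:
            win = promoter_window(gene, len(residues), upstream, downstream)
            occupied: list[tuple[int, int]] = []
            candidates = rng.permutation(np.arange(win.start, win.end)).tolist()
            for pos in candidates:
                if planted >= count_per_gene:
                    break
                inst = _realize_instance(pattern, rng)
                end = pos + len(inst)
                if end > win.end:
                    continue
                if any(pos < e and s < end for s, e in occupied):
                    continue
                residues[pos:end] = inst
                occupied.append((pos, end))
                planted += 1
            if planted < count_per_gene:
                raise ValueError(
                    f"window of {gene.gene_id} too small to plant "
                    f"{count_per_gene} non-overlapping instances"
                )
        rows.append((gene.gene_id, i in affected_idx, planted))
    truth = pd.DataFrame(rows, columns=["gene_id", "affected", "planted_count"])
    return GenomeSequence(genome.seq_id, "".join(residues)), truth


def gen_expression(
    truth: pd.DataFrame,
    delta: float,
    sigma_lfc: float = 0.5,
    se_lfc: float = 0.25,
    seed: int | None = None,
    contrast: str = "T4_27d",
) -> pd.DataFrame:
    """A per-gene DE table with an additive effect on affected genes.

    Affected genes draw log2FC from Normal(+/-delta, sigma_lfc) with random
    sign; null genes from Normal(0, sigma_lfc).  p-values come from a
    two-sided normal test of log2fc / se_lfc, adjusted by
    Benjamini-Hochberg.
    """
    if sigma_lfc <= 0 or se_lfc <= 0:
        raise ValueError("sigma_lfc and se_lfc must be positive")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    n = len(truth)
    affected = truth["affected"].to_numpy(dtype=bool)
    signs = rng.choice([-1.0, 1.0], size=n)
    mu = np.where(affected, signs * delta, 0.0)
    lfc = rng.normal(mu, sigma_lfc)
    z = lfc / se_lfc
    pval = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "contrast": contrast,
            "log2fc": lfc,
            "pvalue": pval,
            "padj": padj,
            "true_delta": mu,
        }
    )


def gen_binding(
    model: str,
    params: dict,
    design: DilutionSeries,
    n_replicates: int = 3,
    noise_frac: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy observations from a one-site model on a dilution design.

    ``model`` is ``"saturation"`` (params kd, bmax, ns_slope, background) or
    ``"competition"`` (params ki, top, bottom, hot_conc, hot_kd).  Noise is
    Gaussian with sd = ``noise_frac`` x the model's dynamic range over the
    design, so a flat curve stays exactly flat.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if seed is None:
        raise ValueError("an explicit seed is required")
    conc = design.concentrations
    if model == "saturation":
        clean = saturation_model(
            conc, params["kd"], params["bmax"],
            params.get("ns_slope", 0.0), params.get("background", 0.0),
        )
    elif model == "competition":
        clean = competition_model(
            np.log10(conc), params["ki"], params["top"], params["bottom"],
            params["hot_conc"], params["hot_kd"],
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    sd = noise_frac * float(clean.max() - clean.min())
    rows = []
    for rep in range(1, n_replicates + 1):
        noisy = clean + rng.normal(0.0, sd, size=conc.size) if sd > 0 else clean
        for c, s in zip(conc, noisy):
            rows.append((float(c), float(s), rep))
    return pd.DataFrame(rows, columns=["conc", "signal", "replicate"])


def folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ Normal(mu, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = mu / sigma
    return float(
        sigma * np.sqrt(2.0 / np.pi) * np.exp(-a * a / 2.0)
        + mu * (1.0 - 2.0 * stats.norm.cdf(-a))
    )


def expected_fold_ratio(delta: float, sigma_lfc: float) -> float:
    """Analytic |log2FC| fold ratio between affected and null genes.

    Ratio of folded-normal means: E|N(delta, sigma)| / E|N(0, sigma)|.
    This is what the enrichment analysis estimates when the high-TRE class
    contains only affected genes and the zero-TRE class only null genes.
    """
    return folded_normal_mean(abs(delta), sigma_lfc) / folded_normal_mean(0.0, sigma_lfc)


def pattern_match_probability(pattern: Pattern, gc_content: float = 0.5) -> float:
    """Per-position, per-strand match probability on i.i.d. background.

    Sums base probabilities over each position's allowed set (spacer
    positions contribute 1); for a direct repeat the probabilities for each
    spacer length are summed, upper-bounding the per-start hit probability
    by ignoring the (rare) multi-spacer overlap at one start.
    Zero-mismatch matching only.
    """
    base_p = {
        "A": (1 - gc_content) / 2, "T": (1 - gc_content) / 2,
        "G": gc_content / 2, "C": gc_content / 2,
    }

    def prob(positions) -> float:
        out = 1.0
        for s in positions:
            out *= sum(base_p[b] for b in s)
        return out

    if isinstance(pattern, HalfsitePattern):
        return prob(pattern.positions)
    p_ab = prob(pattern.halfsite_a.positions) * prob(pattern.halfsite_b.positions)
    return p_ab * (pattern.spacer_max - pattern.spacer_min + 1)
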