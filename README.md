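# tretools

Tools for asking whether thyroid hormone (TH) responsive genes in a genome
are explained by nearby thyroid hormone response elements (TREs), and for
quantifying TH binding to membrane protein extracts.

When THs act genomically, the T3-bound thyroid receptor/RXR complex binds
TREs — direct repeats of the hexameric halfsite 5'-AGGTCA-3', canonically
spaced by four bases (DR4) — and regulates transcription of nearby genes.
`tretools` implements the analysis chain that connects predicted TREs to
differential expression:

1. **Motif scanning** — three degenerate search patterns on both strands:
   the lone halfsite `[AG]-G-G-N-C-A` (no mismatches), the canonical DR4
   `[AG]-[G]-G-N-C-A-N-N-N-N-[AG]-[G]-G-N-C-A`, and a permissive direct
   repeat `[AG]-[G]-G-[AT]-C-A-N(0,6)-[AG]-[G]-G-[AT]-C-A` allowing 0–6
   spacer bases and up to two mismatches counted jointly over both
   halfsites.
2. **Gene association** — hits are tallied within each gene's promoter
   window (500 bp upstream through 20 bp downstream of the transcription
   initiation site, one gene object per mRNA locus in the GFF3).
3. **Enrichment statistics** — (a) genes with many nearby TREs
   (count ≥ K, with K the largest threshold retaining at least 50
   differentially expressed genes) versus genes with none, compared on
   mean |log2 fold change|; (b) DEGs (adjusted p < 0.05 and ≥ 2-fold)
   versus unregulated genes, compared on mean TRE count and TRE presence.
   All comparisons are two-tailed Welch t-tests.
4. **Binding fits** — one-site total (saturation) binding
   `B(L) = Bmax·L/(Kd+L) + ns·L + bg` and one-site competitive
   displacement, a unit-slope logistic in log10 concentration whose
   midpoint is tied to the inhibition constant by the Cheng–Prusoff
   relation `IC50 = Ki·(1 + [hot]/Kd_hot)`, fitted by nonlinear least
   squares on the assay's 18-point 3-fold dilution design.

A synthetic-data module generates genomes with planted TREs, matched
expression tables with a TRE-linked effect, and noisy binding curves, so
every stage is testable end to end with known ground truth.

## Worked example

```python
from tretools.simulate import gen_genome_and_genes, plant_tres, gen_expression
from tretools.motifs import builtin_patterns, scan_sequence
from tretools.genome import promoter_windows
from tretools.association import associate
from tretools.enrichment import TreEnrichmentModel

pattern = builtin_patterns()["halfsite"]
genome, genes = gen_genome_and_genes(2000, seed=42)
genome, truth = plant_tres(genome, genes, 0.10, 11, pattern, seed=43)

hits = scan_sequence(genome, pattern)
windows = promoter_windows(genes, {genome.seq_id: genome.length})
counts = associate(hits, windows, patterns=["halfsite"])
expr = gen_expression(truth, delta=1.0, seed=44)

print(TreEnrichmentModel(counts, expr).fit("halfsite", "T4_27d").summary())
```

```
TRE enrichment: pattern=halfsite  contrast=T4_27d
================================================================
Regulation by TRE class (K = 12)
  high-TRE genes (count >= 12): n = 128,  mean |log2FC| = 0.9548
  zero-TRE genes:            n = 519,  mean |log2FC| = 0.3934
  fold ratio = 2.427   t = 12.956   p = 2.03e-26
----------------------------------------------------------------
TRE load by DEG status (169 DEGs vs 1831 unregulated)
  mean count: DEG = 7.024,  non-DEG = 1.876  (fold = 3.744, p = 2.32e-24)
  with >=1 TRE: DEG = 0.852,  non-DEG = 0.730  (p = 4.56e-05)
```

Ten percent of the 2000 genes carry 11 planted halfsites and a ±1 log2-unit
expression effect; the fit recovers a data-driven threshold K = 12 (11
planted sites plus i.i.d. background occurrences), a 2.4-fold stronger
regulation of high-TRE genes, and a strongly elevated TRE load near DEGs —
both highly significant.

Binding fits work the same way:

```python
from tretools.binding import fit_competition, make_dilution_series
from tretools.simulate import gen_binding

design = make_dilution_series(2.7e-4, 3.0, 18)   # floor 2.1e-12 M
obs = gen_binding("competition", {"ki": 1e-9, "top": 100.0, "bottom": 0.0,
                                  "hot_conc": 1e-7, "hot_kd": 9.5e-8},
                  design, seed=45)
print(fit_competition(obs, hot_conc=1e-7, hot_kd=9.5e-8).summary())
```

```
One site - fit Ki (Cheng-Prusoff)
================================================
  ki          9.626e-10   95% CI [8.157e-10, 1.136e-09]
  ic50        1.976e-09   95% CI [1.674e-09, 2.332e-09]
  top             98.62   95% CI [96.15, 101.1]
  bottom       -0.06979   95% CI [-1.813, 1.674]
  hot ligand: 1e-07 M at Kd 9.5e-08 M
  n = 54, RSS = 1032
```

The true Ki of 1 nM is recovered within its confidence interval from three
replicates with 5% noise.

## Command line

```sh
tre simulate --preset enrichment --seed 5 --out sim/
tre run --genome sim/genome.fa --gff sim/genes.gff3 \
        --expression sim/expression.tsv --out results/
tre scan --genome genome.fa --pattern dr4 --out hits.csv
tre fit-binding data.csv --mode competition --hot-conc 1e-7 --hot-kd 9.5e-8
```

`tre run` writes `hits.csv`, `counts.tsv`, `enrichment.tsv`, the resolved
`run_config.yaml` and a `run.log`; identical configurations and seeds give
byte-identical tables.

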