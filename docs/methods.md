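# Methods

## Coordinates and gene objects

All internal coordinates are 0-based half-open; GFF3 I/O converts to and
from that format's 1-based inclusive convention. Each mRNA record in the
annotation is its own gene object — overlapping loci are not collapsed onto
parent genes, so a multi-transcript gene contributes one promoter window
per mRNA. The transcription initiation site (TSS) is the first transcribed
base: the feature start on the plus strand, the feature end on the minus
strand.

The promoter window spans `upstream` bases before the TSS through
`downstream` bases after it, *including* the TSS base (defaults 500 and 20,
hence width 521 unclamped). Windows are clamped at sequence boundaries
rather than discarded so that the gene universe — the denominator of every
enrichment comparison — is identical across patterns and contrasts.

## Motif model

Patterns are positional: each position carries an allowed-base set, written
in bracket notation (`[AG]`, single bases, `N`). A direct repeat is two such
halfsites separated by a spacer of `spacer_min..spacer_max` fully
degenerate bases; a fixed-spacer repeat may equivalently be written with a
central run of plain `N` tokens (the compiler recognises the longest
interior N-run leaving equal-length flanks). The two encodings are
semantically identical because spacer positions and N positions both
contribute zero mismatches.

Mismatch counting: only informative positions count; the budget applies
jointly across both halfsites of a repeat (a budget of 2 means two
mismatches total, not per halfsite). An `N` residue in the sequence never
satisfies an informative position — conservative on assembly gaps. The
built-in allowances are 0 for the halfsite and DR4 patterns and 2 for the
permissive DR0-6 pattern; both are configurable per compiled pattern.

Both strands are scanned by default (response elements are functional in
either orientation); minus-strand matching runs on the reverse complement
and reports intervals in forward coordinates. At one start position a
repeat may match at several spacer lengths; all distinct (start, end,
strand) intervals are retained, and exact duplicates keep the lowest
mismatch count. Whether to scan one strand, and how to aggregate
overlapping matches, are deliberate flags because different scanning tools
make different choices here.

The scanner is vectorised: sequences are integer-encoded and per-position
mismatch indicators are summed over shifted slices, giving a mismatch
profile per (pattern, spacer, strand) in O(length × pattern positions).
The test suite checks it against a naive position-by-position enumeration
on random sequences for all three built-in patterns.

## Gene association

A hit is credited to a gene when the hit's start coordinate lies in the
gene's window. This start-in-window rule (rather than full containment or
midpoint) is the simplest deterministic choice and is configurable in
effect via the window bounds; a hit in overlapping windows is credited to
every such gene. Zero-count genes appear explicitly. Signed distances to
the TSS (negative = upstream, strand-aware) are recorded alongside counts
but the enrichment statistics use only the window counts.

## Enrichment statistics

Within one contrast (treatment × stage), write `c_g` for a gene's TRE count
and `y_g` for its log2 fold change.

**Regulation by TRE class.** The high class is `c_g ≥ K`, the reference
class `c_g = 0`; the statistic is the ratio of mean |y| between classes,
with a two-tailed Welch t-test on the |y| samples. Magnitudes rather than
signed values are compared by default — the question is how *strongly*
genes respond, not in which direction — with a signed mode behind a flag.
K is data-driven: the largest integer such that at least `min_degs`
(default 50) differentially expressed genes remain in the high class. This
keeps the high class from shrinking into noise while staying as stringent
as the data allow; if no K ≥ 1 qualifies the threshold falls back to 1 with
a warning.

**TRE load by DEG status.** A DEG has adjusted p < α (default 0.05, the
conventional FDR level) and |y| ≥ log2(fold_cut) (default 2-fold). DEGs and
unregulated genes are compared on mean TRE count and on the indicator of
carrying ≥ 1 TRE, each with a two-tailed Welch t-test. A t-test on a 0/1
indicator is a blunt instrument; it is the default to keep the stated
method uniform, and a two-proportion z-test is available via
`presence_test="ztest"`.

Welch's unequal-variance form (with Welch–Satterthwaite degrees of freedom)
is used throughout because the groups are wildly unbalanced — tens of
high-TRE genes against thousands of others. No multiple-testing correction
is applied across patterns and contrasts by default. Degenerate inputs:
identical constant groups report t = 0, p = 1 with a warning rather than
NaN.

## Binding models

**Saturation (one-site total binding).**
`signal = Bmax·L/(Kd+L) + ns·L + bg`: specific hyperbola plus linear
nonspecific binding plus background. Initial values come from the data
(background ≈ minimum signal, Bmax ≈ dynamic range, Kd ≈ concentration at
half-range).

**Competition (one-site, fit Ki).**
`signal = bottom + (top−bottom)/(1 + 10^(x − log10 IC50))` with
`x = log10[I]`, slope fixed at 1, and `IC50 = Ki·(1 + [hot]/Kd_hot)` — the
Cheng–Prusoff correction for the labelled ligand present at known
concentration and affinity, so Ki is a fitted parameter and the identity
holds exactly for every returned fit.

Both fits run scipy least squares with the affinity parameter in log10
space, which enforces positivity and makes the error roughly symmetric on
the scale on which affinities are compared. 95% confidence intervals are
asymptotic (t-based on the least-squares covariance, back-transformed for
Kd/Ki); profile-likelihood intervals are not implemented. Replicates
(n = 3 in the emulated design) are pooled into one residual vector rather
than averaged first, weighting concentrations by their replicate counts; an
averaging option exists.

A competition fit first checks for an actual transition: if the range of
per-concentration means does not exceed three times the within-
concentration noise estimate (or an absolute floor for noiseless data), a
`NoDisplacementError` is raised — this is how non-displacing ligands
surface, rather than as an arbitrary huge Ki.

Millipolarization normalization rescales each replicate series to 0–100 by
its observed extremes. Normalizing to fitted plateaus instead is possible
by fitting first and rescaling with the returned top/bottom; observed
extremes are the default because they require no model commitment.

## Synthetic data

The generator emulates the assay and screening conditions, not real genome structure:

* **Genome** — one chromosome of i.i.d. bases at GC 0.4 (typical for an
  AT-rich invertebrate genome), genes every 2000 bp on alternating strands
  with 1000 bp flanks. i.i.d. background makes motif occurrence
  probabilities available in closed form (halfsite: 8/4096 per position and
  strand at GC 0.5), which the tests exploit.
* **Planted TREs** — zero-mismatch, forward-oriented, non-overlapping
  instances overwrite random positions inside the promoter windows of a
  random gene fraction; a truth table records planted counts, and
  re-scanning is guaranteed to recover at least them.
* **Expression** — affected genes draw log2FC from Normal(±δ, σ) with
  random sign, null genes from Normal(0, σ); σ = 0.5 and a standard error
  of 0.25 log2 units are typical dispersions for a bulk RNA-seq contrast.
  p-values come from a two-sided normal test of y/se with
  Benjamini–Hochberg adjustment. Under this generator the analytic
  expectation of the enrichment fold ratio is the ratio of folded-normal
  means E|N(δ,σ)| / E|N(0,σ)| (≈ 2.53 at δ = 1, σ = 0.5), which the
  recovery tests compare against.
* **Binding curves** — model signal plus Gaussian noise with sd equal to
  `noise_frac` (default 5%) of the curve's dynamic range, on the 18-point
  3-fold dilution from 2.7×10⁻⁴ M (floor ≈ 2.1×10⁻¹² M), three replicates.

What passing tests do **not** show about real data: real promoters have
repeat structure, composition bias and clustered binding sites that i.i.d.
background lacks; real DE tables have correlated genes and heavy-tailed
fold changes; real plates have position effects and non-Gaussian noise.
The tests establish that the statistics are correctly computed and well
calibrated under their own assumptions, not that those assumptions hold in
any particular genome.

## Problem sizes and numerical choices

The simulated enrichment study uses 2000 genes with 10% affected carrying
11 planted halfsites — large enough that the null calibration check (200
replicates) has a tight binomial band and the recovery check (100
replicates) estimates the fold ratio to within a few percent, while the
whole suite runs in seconds. Binding recovery uses 100 simulated assays of
54 observations each. All generators require explicit seeds; there is no
global random state.

Ties in `choose_threshold` cannot occur (the qualifying K set is a
prefix of the integers); ties in the scanner's duplicate merge resolve to
the lowest mismatch count. Fits that fail to converge raise with the
residual at the last iterate rather than returning garbage estimates.

## Known limitations

* No position-weight-matrix scoring or statistical calibration of motif
  hits; matching is combinatorial (allowed sets + mismatch budget).
* Association is promoter-window only — no distal enhancers, no 3D
  contacts.
* The DE table is consumed as given; the package does not run differential
  expression.
* Binding models are single-site with unit Hill slope; no cooperative or
  two-site variants, no anisotropy physics.
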