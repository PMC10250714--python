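"""Promoter TRE-count enrichment statistics.

Two complementary analyses relate per-gene TRE tallies to differential
expression within one treatment-vs-control contrast:

1. *Regulation by TRE class* — genes with many nearby TREs (count >= K)
   versus genes with none (count == 0), comparing mean |log2 fold change|.
   K is chosen as the largest threshold that still leaves at least
   ``min_degs`` differentially expressed genes in the high-TRE class.
2. *TRE load by DEG status* — differentially expressed genes (adjusted
   p < alpha and |log2FC| >= log2(fold_cut)) versus unregulated genes,
   comparing mean TRE count and the proportion of genes with at least one
   TRE.

All comparisons use two-tailed Welch (unequal-variance) t-tests; group
sizes and variances are typically wildly unequal (tens versus thousands of
genes), so the pooled-variance test would be anti-conservative.  No
multiple-testing correction is applied across patterns or contrasts by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "DegTreResult",
    "TreEnrichmentModel",
    "TreEnrichmentResults",
    "choose_threshold",
    "lfc_by_tre_class",
    "deg_tre_enrichment",
    "welch_t_two_tailed",
]


def welch_t_two_tailed(x, y) -> tuple[float, float]:
    """Welch unequal-variance t statistic and two-tailed p.

    Uses the Welch-Satterthwaite degrees of freedom.  Degenerate inputs:
    if both samples have zero variance and equal means the test is
    uninformative and (0, 1) is returned with a warning; zero variance with
    unequal means gives (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"each sample needs >= 2 values (got {x.size} and {y.size})"
        )
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            warnings.warn("zero variance in both groups; p reported as 1", stacklevel=2)
            return 0.0, 1.0
        t = np.inf if np.mean(x) > np.mean(y) else -np.inf
        warnings.warn("zero variance in both groups with unequal means", stacklevel=2)
        return float(t), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def choose_threshold(
    counts: pd.Series, degs: set[str], min_degs: int = 50
) -> int:
    """Largest K such that at least ``min_degs`` DEGs carry count >= K.

    ``counts`` is a per-gene count series for one pattern; ``degs`` the
    gene ids called differentially expressed.  Falls back to 1 with a
    warning when no K >= 1 retains enough DEGs.
    """
    if min_degs < 1:
        raise ValueError("min_degs must be >= 1")
    deg_ids = [g for g in degs if g in counts.index]
    if not degs or not deg_ids:
        raise ValueError("DEG set is empty (or shares no genes with the counts)")
    deg_counts = counts.loc[deg_ids].to_numpy()
    best = 0
    for k in range(1, int(deg_counts.max()) + 1):
        if (deg_counts >= k).sum() >= min_degs:
            best = k
    if best == 0:
        warnings.warn(
            f"no threshold K >= 1 keeps {min_degs} DEGs; falling back to K = 1",
            stacklevel=2,
        )
        return 1
    return best


@dataclass(frozen=True)
class EnrichmentResult:
    """|log2FC| comparison between high-TRE and zero-TRE genes."""

    pattern_name: str
    contrast: str
    threshold_k: int
    n_high: int
    n_zero: int
    mean_abs_lfc_high: float
    mean_abs_lfc_zero: float
    fold_ratio: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class DegTreResult:
    """TRE count / presence comparison between DEGs and unregulated genes."""

    pattern_name: str
    contrast: str
    n_deg: int
    n_nondeg: int
    mean_count_deg: float
    mean_count_nondeg: float
    count_fold: float
    prop_deg_with_tre: float
    prop_nondeg_with_tre: float
    p_count: float
    p_prop: float


def _contrast_table(expression: pd.DataFrame, contrast: str) -> pd.DataFrame:
    sub = expression[expression["contrast"] == contrast]
    if sub.empty:
        raise ValueError(f"no expression records for contrast {contrast!r}")
    if sub["gene_id"].duplicated().any():
        raise ValueError(f"duplicate gene ids in contrast {contrast!r}")
    return sub.set_index("gene_id")


def lfc_by_tre_class(
    counts: pd.Series,
    expression: pd.DataFrame,
    contrast: str,
    pattern_name: str,
    k: int,
    signed: bool = False,
) -> EnrichmentResult:
    """Compare fold-change magnitude of high-TRE (count >= k) vs zero-TRE genes.

    ``signed=True`` compares signed log2FC instead of magnitudes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    expr = _contrast_table(expression, contrast)
    common = counts.index.intersection(expr.index)
    cnt = counts.loc[common]
    lfc = expr.loc[common, "log2fc"].astype(float)
    values = lfc if signed else lfc.abs()
    high = values[cnt >= k]
    zero = values[cnt == 0]
    if high.empty:
        raise ValueError(f"high-TRE group (count >= {k}) is empty")
    if zero.empty:
        raise ValueError("zero-TRE group (count == 0) is empty")
    mean_high = float(high.mean())
    mean_zero = float(zero.mean())
    ratio = mean_high / mean_zero if mean_zero != 0 else np.nan
    t, p = welch_t_two_tailed(high, zero)
    return EnrichmentResult(
        pattern_name, contrast, k, len(high), len(zero),
        mean_high, mean_zero, float(ratio), t, p,
    )


def deg_tre_enrichment(
    counts: pd.Series,
    expression: pd.DataFrame,
    contrast: str,
    pattern_name: str,
    fold_cut: float = 2.0,
    alpha: float = 0.05,
    presence_test: str = "ttest",
) -> DegTreResult:
    """Compare TRE load of DEGs vs unregulated genes.

    A DEG has adjusted p < ``alpha`` and |log2FC| >= log2(``fold_cut``).
    Presence (>= 1 TRE) is compared with a Welch t-test on 0/1 indicators
    by default; ``presence_test="ztest"`` uses a two-proportion z-test.
    """
    if fold_cut <= 1:
        raise ValueError("fold_cut must be > 1")
    expr = _contrast_table(expression, contrast)
    common = counts.index.intersection(expr.index)
    cnt = counts.loc[common].astype(float)
    expr = expr.loc[common]
    is_deg = (expr["padj"] < alpha) & (expr["log2fc"].abs() >= np.log2(fold_cut))
    deg_counts = cnt[is_deg]
    non_counts = cnt[~is_deg]
    if deg_counts.empty:
        raise ValueError(
            f"no DEGs in {contrast!r} under padj < {alpha} and fold >= {fold_cut}"
        )
    if non_counts.empty:
        raise ValueError(f"no unregulated genes in {contrast!r}")
    mean_deg = float(deg_counts.mean())
    mean_non = float(non_counts.mean())
    fold = mean_deg / mean_non if mean_non != 0 else np.nan
    _, p_count = welch_t_two_tailed(deg_counts, non_counts)
    pres_deg = (deg_counts >= 1).astype(float)
    pres_non = (non_counts >= 1).astype(float)
    if presence_test == "ttest":
        _, p_prop = welch_t_two_tailed(pres_deg, pres_non)
    elif presence_test == "ztest":
        from statsmodels.stats.proportion import proportions_ztest

        successes = np.array([pres_deg.sum(), pres_non.sum()])
        nobs = np.array([len(pres_deg), len(pres_non)])
        _, p_prop = proportions_ztest(successes, nobs)
        p_prop = float(p_prop)
    else:
        raise ValueError(f"unknown presence_test {presence_test!r}")
    return DegTreResult(
        pattern_name, contrast, int(is_deg.sum()), int((~is_deg).sum()),
        mean_deg, mean_non, float(fold),
        float(pres_deg.mean()), float(pres_non.mean()), p_count, p_prop,
    )


@dataclass
class TreEnrichmentResults:
    """Results of both enrichment analyses for one pattern x contrast."""

    lfc: EnrichmentResult
    deg: DegTreResult | None = None

    def summary(self) -> str:
        r = self.lfc
        lines = [
            f"TRE enrichment: pattern={r.pattern_name}  contrast={r.contrast}",
            "=" * 64,
            f"Regulation by TRE class (K = {r.threshold_k})",
            f"  high-TRE genes (count >= {r.threshold_k}): n = {r.n_high},"
            f"  mean |log2FC| = {r.mean_abs_lfc_high:.4f}",
            f"  zero-TRE genes:            n = {r.n_zero},"
            f"  mean |log2FC| = {r.mean_abs_lfc_zero:.4f}",
            f"  fold ratio = {r.fold_ratio:.3f}   t = {r.t_stat:.3f}"
            f"   p = {r.p_value:.3g}",
        ]
        if self.deg is not None:
            d = self.deg
            lines += [
                "-" * 64,
                f"TRE load by DEG status ({d.n_deg} DEGs vs {d.n_nondeg} unregulated)",
                f"  mean count: DEG = {d.mean_count_deg:.3f},"
                f"  non-DEG = {d.mean_count_nondeg:.3f}"
                f"  (fold = {d.count_fold:.3f}, p = {d.p_count:.3g})",
                f"  with >=1 TRE: DEG = {d.prop_deg_with_tre:.3f},"
                f"  non-DEG = {d.prop_nondeg_with_tre:.3f}"
                f"  (p = {d.p_prop:.3g})",
            ]
        return "\n".join(lines)


@dataclass
class TreEnrichmentModel:
    """Joint container for per-gene TRE counts and a DE table.

    Parameters
    ----------
    counts
        Gene x pattern count table from :func:`tretools.association.associate`.
    expression
        Long-form DE table with columns ``gene_id``, ``contrast``,
        ``log2fc``, ``padj``.
    """

    counts: pd.DataFrame
    expression: pd.DataFrame
    alpha: float = 0.05
    fold_cut: float = 2.0
    min_degs: int = 50
    _deg_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = {"gene_id", "contrast", "log2fc", "padj"} - set(
            self.expression.columns
        )
        if missing:
            raise ValueError(f"expression table lacks columns {sorted(missing)}")
        bad = ~self.expression["padj"].between(0, 1)
        if bad.any():
            raise ValueError("padj values must lie in [0, 1]")

    @classmethod
    def from_files(cls, counts_path, expression_path, **kw) -> "TreEnrichmentModel":
        from .association import read_counts

        expr = pd.read_csv(expression_path, sep=None, engine="python")
        return cls(read_counts(counts_path), expr, **kw)

    def degs(self, contrast: str) -> set[str]:
        """Gene ids with padj < alpha in the given contrast."""
        if contrast not in self._deg_cache:
            sub = _contrast_table(self.expression, contrast)
            self._deg_cache[contrast] = set(sub.index[sub["padj"] < self.alpha])
        return self._deg_cache[contrast]

    def fit(
        self,
        pattern: str,
        contrast: str,
        k: int | None = None,
        signed: bool = False,
        with_deg_analysis: bool = True,
    ) -> TreEnrichmentResults:
        """Run both analyses for one pattern and contrast.

        ``k`` defaults to the data-driven threshold: the largest count such
        that at least ``min_degs`` DEGs remain in the high-TRE class.
        """
        if pattern not in self.counts.columns:
            raise ValueError(f"unknown pattern {pattern!r}")
        cnt = self.counts[pattern]
        if k is None:
            k = choose_threshold(cnt, self.degs(contrast), self.min_degs)
        lfc = lfc_by_tre_class(cnt, self.expression, contrast, pattern, k, signed)
        deg = None
        if with_deg_analysis:
            deg = deg_tre_enrichment(
                cnt, self.expression, contrast, pattern, self.fold_cut, self.alpha
            )
        return TreEnrichmentResults(lfc, deg)

    def fit_all(self, patterns=None, contrasts=None) -> pd.DataFrame:
        """Fit every pattern x contrast combination; long-form results table."""
        patterns = list(patterns) if patterns is not None else list(self.counts.columns)
        if contrasts is None:
            contrasts = sorted(self.expression["contrast"].unique())
        rows = []
        for c in contrasts:
            for p in patterns:
                res = self.fit(p, c)
                r, d = res.lfc, res.deg
                rows.append(
                    {
                        "pattern": p, "contrast": c, "threshold_k": r.threshold_k,
                        "n_high": r.n_high, "n_zero": r.n_zero,
                        "mean_abs_lfc_high": r.mean_abs_lfc_high,
                        "mean_abs_lfc_zero": r.mean_abs_lfc_zero,
                        "fold_ratio": r.fold_ratio, "t_stat": r.t_stat,
                        "p_value": r.p_value,
                        "count_fold": d.count_fold if d else np.nan,
                        "prop_deg_with_tre": d.prop_deg_with_tre if d else np.nan,
                        "prop_nondeg_with_tre": d.prop_nondeg_with_tre if d else np.nan,
                        "p_count": d.p_count if d else np.nan,
                        "p_prop": d.p_prop if d else np.nan,
                    }
                )
        return pd.DataFrame(rows)
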