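"""Two-condition differential expression for a small bacterial transcriptome.

The pipeline is deliberately self-contained and fully specified:
median-of-ratios size factors, a negative-binomial Wald test with
method-of-moments dispersion, Benjamini–Hochberg adjustment, and the
classification rule |log2FC| >= 2 and adjusted p < 0.05 used to call a
gene differentially expressed. Summaries report the DEG count, the DEG
percentage of the annotated gene universe, and per-category counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DegResult",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_and_summarize",
    "run_deg",
]

TREATMENT = "treatment"
REFERENCE = "reference"

#: Pseudocount added to normalized group means for fold-change display.
PSEUDOCOUNT = 0.5
#: Lower floor for the method-of-moments NB dispersion estimate.
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples integer counts with a two-level condition label per sample."""

    gene_ids: Sequence[str]
    counts: np.ndarray
    condition: Sequence[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != counts.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {counts.shape[0]} count rows"
            )
        condition = tuple(self.condition)
        if len(condition) != counts.shape[1]:
            raise ValueError("one condition label per sample is required")
        labels = set(condition)
        if labels != {TREATMENT, REFERENCE}:
            raise ValueError(
                f"condition labels must be {{{TREATMENT!r}, {REFERENCE!r}}}, got {sorted(labels)}"
            )
        for label in (TREATMENT, REFERENCE):
            if condition.count(label) < 2:
                raise ValueError(f"need >= 2 replicates for {label!r}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "condition", condition)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.condition])


def size_factors(m: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample scale factors, rescaled to geometric mean 1.

    For each gene with strictly positive counts in every sample, the ratio
    of each sample's count to the gene's geometric mean is formed; a
    sample's factor is the median of those ratios.
    """
    counts = m.counts
    if np.any(counts.sum(axis=0) == 0):
        bad = [i for i in range(counts.shape[1]) if counts[:, i].sum() == 0]
        raise ValueError(f"sample(s) {bad} have all-zero counts; cannot normalize")
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logc = np.log(counts[positive].astype(float))
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _group_moments(norm: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    group = norm[:, mask]
    return group.mean(axis=1), group.var(axis=1, ddof=1), int(mask.sum())


def nb_wald_test(
    m: CountMatrix,
    factors: np.ndarray | None = None,
    pseudocount: float = PSEUDOCOUNT,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Per-gene log2 fold change (treatment vs reference), Wald SE and p-value.

    Counts are divided by the size factors; the NB dispersion alpha in
    Var = mu + alpha mu^2 is estimated per gene by method of moments
    pooled over the two conditions and floored; the delta-method standard
    error of the log2 ratio of group means gives a two-sided Wald p-value
    referred to a t distribution with n1 + n2 - 2 degrees of freedom (a
    small-sample correction: with 3 + 3 replicates the normal reference is
    badly anticonservative, the t reference calibrates to the nominal
    level). Genes with degenerate variance get p = 1 and a flag;
    all-zero genes additionally carry log2fc = 0 and are excluded from the
    multiple-testing denominator downstream.
    """
    if factors is None:
        factors = size_factors(m)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.counts.shape[1],) or np.any(factors <= 0):
        raise ValueError("factors must be positive, one per sample")

    norm = m.counts / factors
    mean_trt, var_trt, n_trt = _group_moments(norm, m.mask(TREATMENT))
    mean_ref, var_ref, n_ref = _group_moments(norm, m.mask(REFERENCE))

    log2fc = np.log2(mean_trt + pseudocount) - np.log2(mean_ref + pseudocount)

    # method-of-moments dispersion pooled over conditions, floored
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_trt = np.where(mean_trt > 0, (var_trt - mean_trt) / mean_trt**2, np.nan)
        alpha_ref = np.where(mean_ref > 0, (var_ref - mean_ref) / mean_ref**2, np.nan)
    stacked = np.stack([alpha_trt, alpha_ref])
    valid = np.isfinite(stacked)
    alpha = np.where(valid, stacked, 0.0).sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
    alpha = np.where(valid.any(axis=0), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    # delta method on log2 of (group mean + pseudocount); Var(mean) = (mu + alpha mu^2)/n
    ln2_sq = np.log(2.0) ** 2
    var_log2_trt = (mean_trt + alpha * mean_trt**2) / n_trt / ((mean_trt + pseudocount) ** 2 * ln2_sq)
    var_log2_ref = (mean_ref + alpha * mean_ref**2) / n_ref / ((mean_ref + pseudocount) ** 2 * ln2_sq)
    se = np.sqrt(var_log2_trt + var_log2_ref)

    degenerate = ~(se > 0) | ~np.isfinite(se)
    all_zero = (mean_trt == 0) & (mean_ref == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, log2fc / np.where(degenerate, 1.0, se))
    df = n_trt + n_ref - 2
    pvalue = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(z), df))
    log2fc = np.where(all_zero, 0.0, log2fc)

    return pd.DataFrame(
        {
            "gene_id": list(m.gene_ids),
            "baseMean_ref": mean_ref,
            "baseMean_trt": mean_trt,
            "log2FC": log2fc,
            "se": se,
            "pvalue": np.clip(pvalue, 0.0, 1.0),
            "degenerate": degenerate,
            "all_zero": all_zero,
        }
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ties shared)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DegResult:
    """Per-gene table plus the summary the classification rule produces."""

    table: pd.DataFrame
    n_deg: int
    n_total_genes: int
    fraction_deg_percent: float
    fc_threshold: float
    alpha: float
    category_counts: dict[str, int] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "n_deg": self.n_deg,
            "n_total_genes": self.n_total_genes,
            "fraction_deg_percent": self.fraction_deg_percent,
            "fc_threshold": self.fc_threshold,
            "alpha": self.alpha,
            "category_counts": dict(sorted(self.category_counts.items())),
        }


def classify_and_summarize(
    result: pd.DataFrame,
    annotation: Mapping[str, Sequence[str]] | None = None,
    n_total_genes: int | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> DegResult:
    """Apply the DEG rule |log2FC| >= fc_threshold AND padj < alpha; summarize.

    ``n_total_genes`` fixes the annotated gene universe for the percentage
    (e.g. 489 of 2594 genes -> 18.85%); it defaults to the table length.
    All-zero genes are excluded from the BH denominator but kept in the
    universe, reported with padj = 1.
    """
    table = result.copy()
    testable = ~table["all_zero"].to_numpy() if "all_zero" in table else np.ones(len(table), bool)
    padj = np.ones(len(table))
    if testable.any():
        padj[testable] = bh_adjust(table.loc[testable, "pvalue"].to_numpy())
    table["padj"] = padj
    table["is_deg"] = (np.abs(table["log2FC"]) >= fc_threshold) & (table["padj"] < alpha)

    n_total = n_total_genes if n_total_genes is not None else len(table)
    n_deg = int(table["is_deg"].sum())
    fraction = round(100.0 * n_deg / n_total, 2)

    category_counts: dict[str, int] = {}
    if annotation is not None:
        deg_genes = set(table.loc[table["is_deg"], "gene_id"])
        for gene, categories in annotation.items():
            if gene in deg_genes:
                for cat in categories:
                    category_counts[cat] = category_counts.get(cat, 0) + 1

    return DegResult(
        table=table,
        n_deg=n_deg,
        n_total_genes=n_total,
        fraction_deg_percent=fraction,
        fc_threshold=fc_threshold,
        alpha=alpha,
        category_counts=category_counts,
    )


def run_deg(
    m: CountMatrix,
    annotation: Mapping[str, Sequence[str]] | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> DegResult:
    """Full pipeline: size factors -> NB Wald -> BH -> classification summary."""
    factors = size_factors(m)
    table = nb_wald_test(m, factors)
    return classify_and_summarize(
        table, annotation=annotation, n_total_genes=m.n_genes,
        fc_threshold=fc_threshold, alpha=alpha,
    )
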