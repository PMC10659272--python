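"""Normalization, differential expression, and aging analyses of snRNA-seq.

Differential expression between elderly and adult cells follows the
common single-cell workflow: per-cell log normalization to a fixed scale
(ln(1 + count x 10,000 / cell total)), a percent-expressed filter, a
two-sided Wilcoxon rank-sum test per gene, and a fold-change threshold;
p-values are reported raw (an optional BH-FDR column is provided for
convenience but plays no role in the significance calls, which mirror the
|log2FC| > 0.5 and p < 0.05 convention).

"Logged CPM" throughout means the same ln(1 + CPM-scaled) quantity,
applied to cell-type mean profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .io_formats import CountMatrix
from .signature_inference import RegressionFit

log = logging.getLogger(__name__)

#: Percent-expressed presets: (min fraction in adult, min fraction in elderly,
#: combine) where combine "either" passes if either group clears 0.25 and
#: "both" requires adult >= 0.25 and elderly >= 0.20.
PCT_FILTERS = {"either": (0.25, 0.25, "either"), "both": (0.25, 0.20, "both")}


def log_normalize(counts: np.ndarray, scale: float = 10_000.0) -> np.ndarray:
    """Per-cell log normalization: ln(1 + count * scale / cell_total).

    ``counts`` is genes x cells; raises on an all-zero cell (naming it by
    column index).
    """
    X = np.asarray(counts, dtype=float)
    totals = X.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise DataError(f"all-zero cell(s) at column(s) {zero[:5].tolist()}")
    return np.log1p(X * scale / totals[None, :])


@dataclass
class DEResult:
    gene_id: str
    cell_type: str
    log2_fc: float
    p_value: float
    pct_adult: float
    pct_elderly: float
    significant: bool
    direction: str  # "up" | "down" | "none"


def differential_expression(
    normalized: np.ndarray,
    gene_ids: list[str],
    cells_elderly: np.ndarray,
    cells_adult: np.ndarray,
    cell_type: str = "all",
    min_pct: float = 0.25,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DEResult]:
    """Elderly-vs-adult differential expression on log-normalized values.

    Genes detected in at least ``min_pct`` of elderly *or* adult cells are
    tested by two-sided Wilcoxon rank-sum; log2FC compares the expm1-mean
    of the two groups with a pseudocount. Significance requires
    |log2FC| > ``lfc_threshold`` and p < ``alpha``. P-values are raw.
    """
    X = np.asarray(normalized, dtype=float)
    e_idx = np.asarray(cells_elderly)
    a_idx = np.asarray(cells_adult)
    if e_idx.dtype == bool:
        e_idx = np.nonzero(e_idx)[0]
    if a_idx.dtype == bool:
        a_idx = np.nonzero(a_idx)[0]
    if e_idx.size < 3 or a_idx.size < 3:
        raise DataError(
            f"need >= 3 cells per group, got elderly={e_idx.size}, adult={a_idx.size}"
        )
    Xe, Xa = X[:, e_idx], X[:, a_idx]
    pct_e = (Xe > 0).mean(axis=1)
    pct_a = (Xa > 0).mean(axis=1)
    tested = np.maximum(pct_e, pct_a) >= min_pct

    mean_e = np.expm1(Xe).mean(axis=1)
    mean_a = np.expm1(Xa).mean(axis=1)
    lfc = np.log2((mean_e + pseudocount) / (mean_a + pseudocount))

    pvals = np.ones(X.shape[0])
    idx = np.nonzero(tested)[0]
    if idx.size:
        res = stats.mannwhitneyu(
            Xe[idx, :], Xa[idx, :], axis=1, alternative="two-sided", method="asymptotic"
        )
        pvals[idx] = res.pvalue
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    out = []
    for g in range(X.shape[0]):
        if not tested[g]:
            continue
        sig = abs(lfc[g]) > lfc_threshold and pvals[g] < alpha
        direction = "none"
        if sig:
            direction = "up" if lfc[g] > 0 else "down"
        out.append(
            DEResult(
                gene_id=gene_ids[g],
                cell_type=cell_type,
                log2_fc=float(lfc[g]),
                p_value=float(pvals[g]),
                pct_adult=float(pct_a[g]),
                pct_elderly=float(pct_e[g]),
                significant=bool(sig),
                direction=direction,
            )
        )
    return out


def de_by_cell_type(cm: CountMatrix, **kwargs) -> dict[str, list[DEResult]]:
    """Run elderly-vs-adult DE separately within every cell type."""
    norm = log_normalize(cm.counts)
    out: dict[str, list[DEResult]] = {}
    for ct in sorted(cm.cell_meta["cell_type"].unique()):
        e = cm.cells_where(cell_type=ct, age_group="elderly")
        a = cm.cells_where(cell_type=ct, age_group="adult")
        out[ct] = differential_expression(
            norm, cm.gene_ids, e, a, cell_type=ct, **kwargs
        )
    return out


def de_frame(results) -> pd.DataFrame:
    """Flatten DE results (list or dict of lists) into a DataFrame with BH-FDR."""
    if isinstance(results, dict):
        flat = [r for lst in results.values() for r in lst]
    else:
        flat = list(results)
    df = pd.DataFrame([vars(r) for r in flat])
    if len(df):
        df["fdr_bh"] = np.nan
        for ct, sub in df.groupby("cell_type"):
            df.loc[sub.index, "fdr_bh"] = stats.false_discovery_control(
                sub["p_value"].to_numpy(), method="bh"
            )
    return df


# ---------------------------------------------------------------------------
# gene program classification


def classify_gene_programs(means: pd.DataFrame) -> pd.DataFrame:
    """Housekeeping / neuron-specific / other calls from four cell-type means.

    ``means`` must have columns ``excitatory``, ``inhibitory``,
    ``microglia``, ``endothelia`` of mean logged CPM per gene.
    Housekeeping: spread of the four means < 0.1 and every mean > 0.1.
    Neuron-specific: both neuron means > 0.2 and both microglia/endothelia
    means < 0.1. Strict inequalities throughout.
    """
    required = ["excitatory", "inhibitory", "microglia", "endothelia"]
    missing = [c for c in required if c not in means.columns]
    if missing:
        raise DataError(f"classify_gene_programs: missing cell type(s) {missing}")
    m = means[required]
    spread = m.max(axis=1) - m.min(axis=1)
    # strict inequality at the boundary: a spread of exactly 0.1 fails even
    # when floating-point subtraction lands a hair below it
    spread_ok = (spread < 0.1) & ~np.isclose(spread, 0.1, rtol=0.0, atol=1e-9)
    hk = spread_ok & (m > 0.1).all(axis=1)
    ns = (
        (m["excitatory"] > 0.2)
        & (m["inhibitory"] > 0.2)
        & (m["microglia"] < 0.1)
        & (m["endothelia"] < 0.1)
    )
    cls = pd.Series("other", index=means.index, name="gene_class")
    cls[ns] = "neuron_specific"
    cls[hk] = "housekeeping"  # mutually exclusive: hk requires all means > 0.1
    out = m.copy()
    out["gene_class"] = cls
    return out


def celltype_mean_logged_cpm(cm: CountMatrix, scale: float = 10_000.0) -> pd.DataFrame:
    """Mean log-normalized expression per gene per cell type."""
    norm = log_normalize(cm.counts, scale=scale)
    cols = {}
    for ct in sorted(cm.cell_meta["cell_type"].unique()):
        mask = cm.cells_where(cell_type=ct)
        cols[ct] = norm[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=cm.gene_ids)


# ---------------------------------------------------------------------------
# shared-downregulation permutation test


def count_shared(
    down_sets: dict[str, set],
    categories: dict[str, str],
    min_excitatory: int = 1,
    min_inhibitory: int = 1,
    min_glial: int = 2,
) -> int:
    """Genes down in >= the required number of cell types per category."""
    all_genes = set().union(*down_sets.values()) if down_sets else set()
    n = 0
    for g in all_genes:
        hits = {"excitatory": 0, "inhibitory": 0, "glial": 0, "endothelial": 0}
        for ct, s in down_sets.items():
            if g in s:
                hits[categories[ct]] += 1
        if (
            hits["excitatory"] >= min_excitatory
            and hits["inhibitory"] >= min_inhibitory
            and hits["glial"] >= min_glial
        ):
            n += 1
    return n


def shared_down_permutation(
    down_sets: dict[str, set],
    expressed_sets: dict[str, set],
    categories: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    min_excitatory: int = 1,
    min_inhibitory: int = 1,
    min_glial: int = 2,
) -> tuple[int, np.ndarray, float]:
    """Permutation null for the cross-cell-type shared downregulation count.

    Each permutation draws, per cell type, a uniform random subset of that
    type's expressed genes matching its observed down-set size, and counts
    genes meeting the category criterion. Empirical
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    for ct, s in down_sets.items():
        if not s <= expressed_sets[ct]:
            raise DataError(f"{ct}: down genes not a subset of expressed genes")
    cats_present = {categories[ct] for ct in down_sets}
    for needed, minimum in (
        ("excitatory", min_excitatory),
        ("inhibitory", min_inhibitory),
        ("glial", min_glial),
    ):
        if minimum > 0 and needed not in cats_present:
            raise DataError(f"criterion needs {needed} cell types but none present")
    kw = dict(
        min_excitatory=min_excitatory, min_inhibitory=min_inhibitory, min_glial=min_glial
    )
    observed = count_shared(down_sets, categories, **kw)
    rng = np.random.default_rng(seed)
    expressed_lists = {ct: sorted(s) for ct, s in expressed_sets.items()}
    sizes = {ct: len(down_sets[ct]) for ct in down_sets}
    perm_counts = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        perm_sets = {
            ct: set(rng.choice(expressed_lists[ct], size=sizes[ct], replace=False))
            if sizes[ct]
            else set()
            for ct in down_sets
        }
        perm_counts[b] = count_shared(perm_sets, categories, **kw)
    p = (1 + int((perm_counts >= observed).sum())) / (n_perm + 1)
    return observed, perm_counts, float(p)


# ---------------------------------------------------------------------------
# gene-set enrichment, composition trend, length deciles


def gene_set_enrichment(
    de_results: list[DEResult], gene_set: set, background: set, direction: str = "down"
) -> dict:
    """Fisher's exact test for a gene set among down- (or up-) regulated genes.

    The 2x2 table crosses set membership with direction calls over the
    background (active) genes; two-sided p.
    """
    if not background:
        raise DataError("empty background")
    if not gene_set <= background:
        raise DataError("gene_set must be a subset of background")
    called = {r.gene_id for r in de_results if r.significant and r.direction == direction}
    called &= background
    a = len(gene_set & called)
    b = len(gene_set - called)
    c = len(called - gene_set)
    d = len(background - gene_set - called)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "table": [[a, b], [c, d]],
        "odds_ratio": float(odds) if np.isfinite(odds) else float("inf"),
        "p_value": float(p),
        "set_down_fraction": a / len(gene_set) if gene_set else np.nan,
        "background_down_fraction": len(called) / len(background),
    }


def composition_trend(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p for per-donor cell-type fractions.

    Exact enumeration when the combined sample is small (n <= 20), normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be nonempty")
    method = "exact" if (a.size + b.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def length_decile_foldchange(
    log2_fc: pd.Series, lengths: pd.Series, n_deciles: int = 10
) -> tuple[pd.DataFrame, RegressionFit]:
    """Per-length-decile median fold change and its OLS trend on decile index.

    Genes are ranked by length (ties by identifier); returns the decile
    summary and a fit of median log2FC on the 1-based decile index.
    """
    common = log2_fc.index.intersection(lengths.index)
    if len(common) < n_deciles:
        raise DataError(f"{len(common)} genes < {n_deciles} deciles")
    df = pd.DataFrame({"lfc": log2_fc[common], "length": lengths[common]})
    df = df.loc[sorted(df.index)]  # identifier order breaks length ties
    df = df.sort_values("length", kind="stable")
    df["decile"] = [min(i * n_deciles // len(df), n_deciles - 1) + 1 for i in range(len(df))]
    summary = (
        df.groupby("decile")
        .agg(
            n_genes=("lfc", "size"),
            median_log2_fc=("lfc", "median"),
            median_length=("length", "median"),
        )
        .reset_index()
    )
    res = stats.linregress(summary["decile"], summary["median_log2_fc"])
    fit = RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n_deciles,
    )
    return summary, fit


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z contrast of two correlation coefficients.

    Returns (z, two-sided p). Use the signed correlations of the two fits
    being contrasted (e.g. length-fold-change trends of two gene classes).
    """
    if n1 <= 3 or n2 <= 3:
        raise DataError("need n > 3 in both samples for the r-to-z contrast")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
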