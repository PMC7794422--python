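"""Differential-expression filtering, correlations, ddCt and preranked GSEA.

DE tables are plain DataFrames with columns ``gene_id``, ``log2fc``,
``pvalue`` and ``fdr`` (contrast/cell-line labels in ``df.attrs``). The
consistent-upregulation filter uses strict inequalities at both thresholds
so boundary genes are reproducibly excluded. The enrichment statistic is the
weighted Kolmogorov-Smirnov-like running sum over a preranked list, with a
gene-relabeling permutation null (the pipeline consumes preranked lists, so
phenotype permutation is not applicable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "fdr"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    group: str
    n: int
    pearson_r: float
    p: float


# ---------------------------------------------------------------------------
# BH correction and the upregulation filter
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValueError("empty differential-expression table")
    missing = [c for c in DE_COLUMNS if c not in df.columns and c != "fdr"]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    if "fdr" not in df.columns:
        df = df.copy()
        df["fdr"] = benjamini_hochberg(df["pvalue"].to_numpy())
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in DE table")
    return df


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_de_table(df)


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def consistent_upregulated(
    tables: Sequence[pd.DataFrame],
    l2fc_min: float = 0.0,
    fdr_max: float = 0.05,
    universe: GeneSet | None = None,
) -> list[str]:
    """Genes with log2FC > l2fc_min AND fdr < fdr_max in *every* table.

    Both inequalities are strict. When ``universe`` is given the result is
    intersected with it. Gene order follows the first table.
    """
    if len(tables) < 2:
        raise ValueError("need at least two DE tables")
    tables = [validate_de_table(t) for t in tables]
    keep: set[str] | None = None
    for df in tables:
        passing = set(
            df.loc[(df["log2fc"] > l2fc_min) & (df["fdr"] < fdr_max), "gene_id"]
        )
        keep = passing if keep is None else keep & passing
    if universe is not None:
        keep &= universe.members
    first = tables[0]["gene_id"]
    return [g for g in first if g in keep]


# ---------------------------------------------------------------------------
# Correlations and qPCR fold change
# ---------------------------------------------------------------------------

def pearson_by_group(
    expr: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    groups: Mapping[str, str],
) -> list[CorrelationResult]:
    """Per-group Pearson correlation of two genes across samples.

    ``expr`` is gene x sample; ``groups`` maps sample -> group label. Groups
    with fewer than 3 samples raise; a zero-variance gene in a group yields
    NaN r (reported, not raised).
    """
    by_label: dict[str, list[str]] = {}
    for sample, label in groups.items():
        if sample not in expr.columns:
            raise ValueError(f"sample {sample!r} not in expression matrix")
        by_label.setdefault(label, []).append(sample)
    results = []
    for label in sorted(by_label):
        samples = by_label[label]
        n = len(samples)
        if n < 3:
            raise ValueError(f"group {label!r} has n={n} < 3 samples")
        a = expr.loc[gene_a, samples].to_numpy(dtype=float)
        b = expr.loc[gene_b, samples].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            results.append(CorrelationResult(label, n, math.nan, math.nan))
            continue
        r, p = stats.pearsonr(a, b)
        results.append(CorrelationResult(label, n, float(r), float(p)))
    return results


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """qPCR relative quantification: fold = 2^-ddCt."""
    for ct in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# Preranked gene-set enrichment
# ---------------------------------------------------------------------------

def _running_sum_es(
    hit_mask: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """ES (max signed deviation) for each row of a (m, N) hit-mask matrix.

    Hits step up by |score|^p normalized to the in-set total; misses step
    down by 1/(N - N_hits). When the positive and negative extremes tie
    (within 1e-9, which can happen exactly in real arithmetic) the positive
    deviation is reported. Returns (es, extremum_index).
    """
    m, n = hit_mask.shape
    n_hits = hit_mask.sum(axis=1)
    if np.any(n_hits == 0) or np.any(n_hits == n):
        raise ValueError("gene set fully inside or fully outside the ranked list")
    hit_w = hit_mask * weights
    hit_tot = hit_w.sum(axis=1, keepdims=True)
    # all-zero weights in the set degenerate to equal hit steps
    steps = np.where(
        hit_tot > 0, hit_w / np.where(hit_tot > 0, hit_tot, 1.0), hit_mask / n_hits[:, None]
    )
    steps = steps - (~hit_mask) / (n - n_hits)[:, None]
    cs = np.cumsum(steps, axis=1)
    mx, mn = cs.max(axis=1), cs.min(axis=1)
    positive = mx >= -mn - 1e-9
    arg = np.where(positive, cs.argmax(axis=1), cs.argmin(axis=1))
    return np.where(positive, mx, mn), arg


def preranked_enrichment(
    ranked: Sequence[tuple[str, float]] | pd.Series,
    gene_set: GeneSet,
    weight_p: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted running-sum enrichment of a gene set in a preranked list.

    ``ranked`` is (gene, score) sorted descending (a Series index->score is
    accepted and used in its given order; ties keep input order). The null is
    random gene-set relabeling: ``n_perm`` same-size sets drawn uniformly.
    NES = ES / mean(|permuted ES| of matching sign); nominal p is the
    fraction of same-sign permuted ES at least as extreme, floored at
    1/n_perm. For a single set, fdr_q is reported as the nominal p.
    """
    if isinstance(ranked, pd.Series):
        genes = list(ranked.index)
        scores = ranked.to_numpy(dtype=float)
    else:
        genes = [g for g, _ in ranked]
        scores = np.array([s for _, s in ranked], dtype=float)
    n = len(genes)
    members = gene_set.members
    mask = np.array([g in members for g in genes], dtype=bool)
    n_hits = int(mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError(
            f"gene set {gene_set.name!r} is fully inside or outside the ranked list"
        )
    weights = np.abs(scores) ** weight_p if weight_p else np.ones(n)

    es_arr, arg_arr = _running_sum_es(mask[None, :], weights)
    es, arg = float(es_arr[0]), int(arg_arr[0])

    rng = np.random.default_rng(seed)
    perm_mask = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perm_mask[i, rng.choice(n, size=n_hits, replace=False)] = True
    perm_es, _ = _running_sum_es(perm_mask, weights)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    pool = perm_es[same_sign]
    if pool.size:
        denom = float(np.abs(pool).mean())
        nes = es / denom if denom > 0 else math.nan
        p = float(np.sum(np.abs(pool) >= abs(es))) / pool.size
    else:
        nes, p = math.nan, 1.0 / n_perm
    p = max(p, 1.0 / n_perm)

    hit_pos = np.nonzero(mask)[0]
    if es >= 0:
        leading = [genes[i] for i in hit_pos if i <= arg]
    else:
        leading = [genes[i] for i in hit_pos if i >= arg]
    return EnrichmentResult(gene_set.name, es, float(nes), p, p, leading)


def preranked_enrichment_multi(
    ranked: Sequence[tuple[str, float]] | pd.Series,
    gene_sets: Sequence[GeneSet],
    weight_p: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Enrichment of several sets with an NES-pooled FDR q.

    Permuted ES are normalized per set by the same same-sign mean as the
    observed NES; q(set) = [fraction of pooled null |NES| >= |NES_set| of
    matching sign] / [fraction of observed same-sign |NES| >= |NES_set|],
    clipped to [0, 1]. With a single set this reduces to the nominal p.
    """
    results = [
        preranked_enrichment(ranked, gs, weight_p, n_perm, seed + i)
        for i, gs in enumerate(gene_sets)
    ]
    if len(results) < 2:
        return results
    # rebuild null NES pools per set
    if isinstance(ranked, pd.Series):
        genes = list(ranked.index)
        scores = ranked.to_numpy(dtype=float)
    else:
        genes = [g for g, _ in ranked]
        scores = np.array([s for _, s in ranked], dtype=float)
    n = len(genes)
    weights = np.abs(scores) ** weight_p if weight_p else np.ones(n)
    null_nes: list[np.ndarray] = []
    for i, gs in enumerate(gene_sets):
        rng = np.random.default_rng(seed + i)
        n_hits = sum(g in gs.members for g in genes)
        perm_mask = np.zeros((n_perm, n), dtype=bool)
        for j in range(n_perm):
            perm_mask[j, rng.choice(n, size=n_hits, replace=False)] = True
        perm_es, _ = _running_sum_es(perm_mask, weights)
        pos, neg = perm_es[perm_es >= 0], perm_es[perm_es < 0]
        pos_mean = np.abs(pos).mean() if pos.size else math.nan
        neg_mean = np.abs(neg).mean() if neg.size else math.nan
        scaled = np.where(perm_es >= 0,
                          perm_es / pos_mean if pos_mean else math.nan,
                          perm_es / neg_mean if neg_mean else math.nan)
        null_nes.append(scaled)
    pooled = np.concatenate(null_nes)
    obs = np.array([r.nes for r in results])
    for r in results:
        if not math.isfinite(r.nes):
            r.fdr_q = math.nan
            continue
        if r.nes >= 0:
            null_frac = np.mean(pooled[pooled >= 0] >= r.nes) if np.any(pooled >= 0) else 0.0
            obs_frac = np.mean(obs[obs >= 0] >= r.nes)
        else:
            null_frac = np.mean(pooled[pooled < 0] <= r.nes) if np.any(pooled < 0) else 0.0
            obs_frac = np.mean(obs[obs < 0] <= r.nes)
        r.fdr_q = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else math.nan
    return results


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")
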