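"""Pairwise co-expression statistics over a microarray-style compendium.

Implements the correlation analyses used to validate inferred regulatory
relationships: overall Pearson correlation of a gene pair, an empirical
p-value against a null of random gene pairs, per-condition Z-scores of the
pair's correlation against the within-condition random-pair distribution,
and baseline correlation distributions for co-operonic pairs, neighboring
non-operonic pairs, and random pairs.

The null for both the empirical p-value and the Z-scores is a sample of
random gene PAIRS (not permutations of one gene's arrays): the reference
distribution is the spread of conditional correlations across pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """genes x arrays expression values with one condition label per array."""

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.conditions.index):
            self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            raise ExpressionError("every array needs a condition label")

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def arrays_in(self, condition: str | None) -> np.ndarray:
        if condition is None:
            return np.arange(self.n_arrays)
        return np.nonzero((self.conditions == condition).values)[0]

    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class PairCorrelationResult:
    gene_a: str
    gene_b: str
    r_overall: float
    empirical_p: float | None = None
    per_condition: pd.DataFrame | None = None


@dataclass
class BaselineDistribution:
    kind: str
    correlations: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.mean = float(np.mean(self.correlations)) if len(self.correlations) else np.nan
        self.sd = float(np.std(self.correlations, ddof=1)) if len(self.correlations) > 1 else np.nan


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ExpressionError("constant expression vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def pair_correlation(
    expr: ExpressionMatrix, gene_a: str, gene_b: str, condition: str | None = None
) -> float:
    """Pearson correlation of two genes over all arrays, or within one
    condition."""
    cols = expr.arrays_in(condition)
    if len(cols) < 3:
        raise ExpressionError(
            f"need >= 3 arrays in scope, got {len(cols)} for condition {condition!r}"
        )
    x = expr.values.loc[gene_a].values[cols]
    y = expr.values.loc[gene_b].values[cols]
    return _pearson(x, y)


def _sample_distinct_pairs(genes: np.ndarray, n: int, rng) -> np.ndarray:
    if len(genes) < 2:
        raise ExpressionError("need >= 2 genes to sample pairs")
    a = rng.integers(0, len(genes), n)
    b = rng.integers(0, len(genes) - 1, n)
    b = np.where(b >= a, b + 1, b)
    return np.stack([a, b], axis=1)


def _null_correlations(expr: ExpressionMatrix, cols: np.ndarray, n_pairs: int, rng) -> np.ndarray:
    X = expr.values.values[:, cols]
    pairs = _sample_distinct_pairs(np.arange(X.shape[0]), n_pairs, rng)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    num = (Xc[pairs[:, 0]] * Xc[pairs[:, 1]]).sum(axis=1)
    denom = norms[pairs[:, 0]] * norms[pairs[:, 1]]
    valid = ok[pairs[:, 0]] & ok[pairs[:, 1]]
    return num[valid] / denom[valid]


def empirical_pvalue(
    expr: ExpressionMatrix,
    r_observed: float,
    n_null_pairs: int = 10000,
    seed: int = 0,
) -> float:
    """p = (1 + #{null pairs with r >= r_observed}) / (n_null_pairs + 1),
    null pairs drawn uniformly from distinct random gene pairs over all
    arrays."""
    if n_null_pairs < 1000:
        raise ExpressionError("n_null_pairs must be >= 1000")
    rng = np.random.default_rng(seed)
    r_null = _null_correlations(expr, np.arange(expr.n_arrays), n_null_pairs, rng)
    return float((1 + np.sum(r_null >= r_observed)) / (n_null_pairs + 1))


def condition_zscores(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    n_null_pairs: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition Z-score of the pair's correlation against the
    within-condition distribution of random gene-pair correlations:
    z_c = (r_pair,c - mean_c) / sd_c.  Conditions with fewer than 3 arrays
    are skipped with a log entry."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond in expr.condition_names():
        cols = expr.arrays_in(cond)
        if len(cols) < 3:
            logger.info("condition %r has %d arrays (<3); skipped", cond, len(cols))
            continue
        r = pair_correlation(expr, gene_a, gene_b, cond)
        r_null = _null_correlations(expr, cols, n_null_pairs, rng)
        sd = float(np.std(r_null, ddof=1))
        if sd == 0:
            raise ExpressionError(f"null correlation sd is 0 in condition {cond!r}")
        z = (r - float(np.mean(r_null))) / sd
        rows.append({"condition": cond, "n_arrays": len(cols), "r": r, "z_score": z})
    return pd.DataFrame(rows)


def analyze_pair(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    n_null_pairs: int = 10000,
    seed: int = 0,
) -> PairCorrelationResult:
    r = pair_correlation(expr, gene_a, gene_b)
    p = empirical_pvalue(expr, r, n_null_pairs=n_null_pairs, seed=seed)
    z = condition_zscores(expr, gene_a, gene_b, n_null_pairs=max(1000, n_null_pairs // 10), seed=seed + 1)
    return PairCorrelationResult(gene_a, gene_b, r_overall=r, empirical_p=p, per_condition=z)


def baseline_distributions(
    expr: ExpressionMatrix,
    operon_pairs: list[tuple[str, str]],
    gene_order: list[str] | None = None,
    n_random_pairs: int = 2000,
    seed: int = 0,
) -> dict[str, BaselineDistribution]:
    """Correlation baselines: co-operonic pairs, neighboring non-operonic
    pairs (adjacent in gene_order but not co-operonic), and random pairs.
    Empty categories are flagged with a log entry and omitted."""
    rng = np.random.default_rng(seed)
    out: dict[str, BaselineDistribution] = {}

    def corr(a: str, b: str) -> float | None:
        try:
            return pair_correlation(expr, a, b)
        except (KeyError, ExpressionError):
            return None

    op = [c for a, b in operon_pairs if (c := corr(a, b)) is not None]
    if op:
        out["co_operonic"] = BaselineDistribution("co_operonic", np.array(op))
    else:
        logger.info("no co-operonic pairs available for baseline")

    if gene_order is not None:
        operonic = {frozenset(p) for p in operon_pairs}
        nb = [
            c
            for a, b in zip(gene_order[:-1], gene_order[1:])
            if frozenset((a, b)) not in operonic and (c := corr(a, b)) is not None
        ]
        if nb:
            out["neighboring_non_operonic"] = BaselineDistribution(
                "neighboring_non_operonic", np.array(nb)
            )

    r_rand = _null_correlations(expr, np.arange(expr.n_arrays), n_random_pairs, rng)
    out["random_pairs"] = BaselineDistribution("random_pairs", r_rand)
    return out
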