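"""Expression–rate association battery.

Rank statistics connecting per-gene evolutionary rates and selection scores
to expression: Spearman correlation, rank-residual partial Spearman with
arbitrary covariates (binary confounders coded 0/1), pairwise rank-sum
comparisons across codon-optimality classes with Benjamini–Hochberg
adjustment, and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "EnrichmentResult",
    "spearman",
    "partial_spearman",
    "group_compare",
    "significance_stars",
    "enrichment",
]


@dataclass(frozen=True)
class AssociationResult:
    name: str
    rho: float
    p: float
    n: int
    covariates: tuple = ()


def _align(x, y, covariates=None):
    """Listwise deletion over aligned per-gene vectors; returns numpy arrays."""
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    frame = pd.DataFrame({"x": x, "y": y})
    cov_names: list[str] = []
    if covariates is not None:
        if isinstance(covariates, pd.Series):
            covariates = covariates.to_frame()
        if isinstance(covariates, pd.DataFrame):
            for c in covariates.columns:
                frame[str(c)] = pd.Series(covariates[c], dtype=float)
                cov_names.append(str(c))
        else:
            for i, c in enumerate(covariates):
                frame[f"z{i}"] = pd.Series(c, dtype=float)
                cov_names.append(f"z{i}")
    n_before = len(frame)
    frame = frame.dropna()
    if len(frame) < n_before:
        logger.info("%d genes dropped for missing values", n_before - len(frame))
    return frame, cov_names


def spearman(x, y, name: str = "spearman") -> AssociationResult:
    """Spearman rank correlation with two-sided p-value.

    Constant input yields rho = NaN (undefined, flagged by a warning)
    rather than an exception.
    """
    frame, _ = _align(x, y)
    if len(frame) < 3:
        raise ValueError(f"need ≥3 paired values, have {len(frame)}")
    if frame["x"].nunique() == 1 or frame["y"].nunique() == 1:
        logger.warning("%s: constant vector, rho undefined", name)
        return AssociationResult(name, float("nan"), float("nan"), len(frame))
    rho, p = stats.spearmanr(frame["x"], frame["y"])
    return AssociationResult(name, float(rho), float(p), len(frame))


def partial_spearman(x, y, covariates, name: str = "partial_spearman") -> AssociationResult:
    """Rank-residual partial Spearman correlation.

    All vectors are rank-transformed (average ranks); the ranks of x and y
    are each residualized on the covariate ranks (plus intercept) by least
    squares, and the Pearson correlation of the residuals is reported with a
    t-test p-value on n − 2 − k degrees of freedom.  An empty covariate set
    reduces exactly to ``spearman``.
    """
    frame, cov_names = _align(x, y, covariates)
    if not cov_names:
        return spearman(x, y, name=name)
    if len(frame) < 4 + len(cov_names):
        raise ValueError("too few complete cases for partial correlation")
    ranks = frame.apply(lambda col: stats.rankdata(col), axis=0)
    Z = np.column_stack([np.ones(len(ranks))] + [ranks[c] for c in cov_names])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        pair = _find_collinear(ranks[cov_names])
        raise ValueError(f"collinear covariates: {pair}")
    rx = ranks["x"] - Z @ np.linalg.lstsq(Z, ranks["x"], rcond=None)[0]
    ry = ranks["y"] - Z @ np.linalg.lstsq(Z, ranks["y"], rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        logger.warning("%s: residual variance is zero, rho undefined", name)
        return AssociationResult(name, float("nan"), float("nan"), len(frame), tuple(cov_names))
    rho = float(rx @ ry / denom)
    df = len(frame) - 2 - len(cov_names)
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return AssociationResult(name, rho, p, len(frame), tuple(cov_names))


def _find_collinear(cov_ranks: pd.DataFrame) -> str:
    cols = list(cov_ranks.columns)
    for a, b in combinations(cols, 2):
        r = np.corrcoef(cov_ranks[a], cov_ranks[b])[0, 1]
        if abs(r) > 1 - 1e-10:
            return f"{a} ~ {b}"
    return " + ".join(cols)


def significance_stars(p: float) -> str:
    """Star labels: ns >0.05, * <0.05, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests across groups, BH-adjusted.

    Returns one row per group pair with the raw Mann–Whitney p, the BH
    adjusted p across the pairs, and its star label.  Groups smaller than 2
    are skipped with a log message.
    """
    frame = pd.DataFrame({"v": pd.Series(values, dtype=float), "g": labels}).dropna()
    groups = {g: sub["v"].to_numpy() for g, sub in frame.groupby("g")}
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    for g in set(groups) - set(usable):
        logger.info("group %s has <2 values; its pairs are skipped", g)
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with ≥2 values")
    rows = []
    for a, b in combinations(sorted(usable), 2):
        stat, p = stats.mannwhitneyu(usable[a], usable[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "n_a": len(usable[a]), "n_b": len(usable[b]),
                     "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["stars"] = out["p_adj"].map(significance_stars)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    p: float
    q: float
    significant: bool


def enrichment(
    gene_set: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    p_cutoff: float = 0.01,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment with BH q-values.

    For each term, the upper-tail hypergeometric probability of drawing at
    least the observed overlap when ``len(gene_set)`` genes are sampled from
    the universe.  Terms are flagged significant at p < ``p_cutoff`` and
    q < ``q_cutoff`` (the conventional 0.01/0.05 screen).  Terms with no
    gene in the universe, and an empty gene set, are skipped.
    """
    universe_set = set(universe)
    genes = set(gene_set) & universe_set
    if set(gene_set) - universe_set:
        raise ValueError("gene_set contains genes outside the universe")
    rows = []
    M, n = len(universe_set), len(genes)
    for term, members in term_map.items():
        K = len(set(members) & universe_set)
        if K == 0 or n == 0:
            continue
        k = len(set(members) & genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "overlap": k, "set_size": n, "term_size": K,
                     "universe_size": M, "p": p})
    if not rows:
        return pd.DataFrame(
            columns=["term", "overlap", "set_size", "term_size", "universe_size", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["p"] < p_cutoff) & (out["q"] < q_cutoff)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
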