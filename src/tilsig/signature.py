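"""Derivation of the lymphocyte gene signature.

A curated candidate list (standing in for a gene-portal-derived panel of
lymphocyte-expressed genes) is filtered in two steps: (1) keep candidates
whose expression Spearman-correlates at ≥ 0.7 with either anchor gene —
CD247 for T cells, MS4A1 (CD20) for B cells; (2) keep genes differentially
expressed between pathologic complete responders and residual-disease
cases by a two-sided Mann-Whitney rank-sum test at p < 0.05.  No
multiplicity adjustment is applied at either step — a deliberate (and
documented) property of the procedure being modelled, not an oversight.
The canonical outcome of this procedure is the eight-gene panel
CD19, CD3D, CD48, GZMB, LCK, MS4A1, PRF1, SELL.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "SignatureConfig",
    "GeneSignature",
    "CANONICAL_SIGNATURE",
    "spearman_rho",
    "anchor_filter",
    "mann_whitney_test",
    "refine_signature",
    "signature_score",
]

#: The eight-gene lymphocyte signature this procedure canonically yields.
CANONICAL_SIGNATURE = ("CD19", "CD3D", "CD48", "GZMB", "LCK", "MS4A1", "PRF1", "SELL")


@dataclass
class SignatureConfig:
    candidate_genes: tuple[str, ...]
    anchor_genes: tuple[str, ...] = ("CD247", "MS4A1")
    correlation_threshold: float = 0.7
    refinement_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not 0 < self.refinement_alpha < 1:
            raise ValueError("refinement_alpha must be in (0, 1)")


@dataclass
class GeneSignature:
    """Ordered gene list plus the per-gene statistics that produced it."""

    genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature contains duplicate genes")

    @classmethod
    def canonical(cls) -> "GeneSignature":
        return cls(genes=CANONICAL_SIGNATURE, provenance={"source": "fixed"})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tprovenance\n")
            for gene in self.genes:
                blob = json.dumps(self.provenance.get(gene, {}))
                fh.write(f"{gene}\t{blob}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneSignature":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        provenance = {
            g: json.loads(blob) for g, blob in zip(frame["gene"], frame["provenance"])
        }
        return cls(genes=tuple(frame["gene"]), provenance=provenance)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN with a warning when either vector is constant, where the
    statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", RuntimeWarning)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def anchor_filter(matrix: ExpressionMatrix, config: SignatureConfig) -> list[str]:
    """Keep candidates whose max Spearman rho against any anchor meets the
    threshold; an anchor's self-correlation is excluded, so anchors are
    retained only through the other anchor(s)."""
    if not matrix.normalized:
        raise ValueError("anchor filter expects a z-normalized, gene-keyed matrix")
    for anchor in config.anchor_genes:
        if anchor not in matrix.data.index:
            raise KeyError(f"anchor gene {anchor!r} missing from matrix")
    anchor_rows = {a: matrix.row(a) for a in config.anchor_genes}
    kept = []
    for gene in config.candidate_genes:
        if gene not in matrix.data.index:
            continue
        row = matrix.row(gene)
        rhos = [
            spearman_rho(row, arow)
            for aname, arow in anchor_rows.items()
            if aname != gene
        ]
        rhos = [r for r in rhos if not math.isnan(r)]
        if rhos and max(rhos) >= config.correlation_threshold:
            kept.append(gene)
    return kept


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group labelings (no ties),
    doubling the smaller one-sided tail and capping at 1."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    n_b = len(b)
    u_values = []
    for idx in combinations(range(len(pooled)), n_a):
        rank_sum = ranks[list(idx)].sum()
        u_values.append(rank_sum - n_a * (n_a + 1) / 2)
    u_values = np.asarray(u_values)
    lower = float(np.mean(u_values <= u_obs + 1e-12))
    upper = float(np.mean(u_values >= u_obs - 1e-12))
    return min(1.0, 2 * min(lower, upper))


def _dp_mw_p(ranks: np.ndarray, n_a: int, u: float) -> float:
    """Exact two-sided p from the permutation distribution of the rank
    sum, computed by subset-sum dynamic programming.

    Doubling average ranks makes every rank an integer, so the count of
    size-``n_a`` subsets at each rank-sum is tracked exactly (as floats,
    which stay well within precision at the totals this path handles).
    Handles arbitrary tie patterns; cost is O(n · n_a · Σranks).
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    # table[k, s] = number of size-k subsets with doubled-rank sum s
    table = np.zeros((n_a + 1, total + 1))
    table[0, 0] = 1.0
    for r in doubled:
        table[1:, r:] += table[:-1, : total + 1 - r]
    dist = table[n_a]
    dist /= dist.sum()
    n = len(ranks)
    # doubled rank-sum observed for group a: 2·(u + n_a(n_a+1)/2)
    s_obs = int(round(2 * u + n_a * (n_a + 1)))
    lower = float(dist[: s_obs + 1].sum())
    upper = float(dist[s_obs:].sum())
    return min(1.0, 2 * min(lower, upper))


#: Largest pooled size for which the exact permutation distribution of
#: the rank sum is computed by dynamic programming; beyond this the
#: normal approximation is accurate to well below any tabulated digit.
_DP_MAX_POOLED = 60


def mann_whitney_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (a vs b) with a two-sided p.

    Exact enumeration of all group labelings (average ranks, so ties are
    handled) when both groups have ≤ 8 observations; an exact
    dynamic-programming evaluation of the same permutation distribution
    for pooled sizes up to 60 (the normal approximation with heavy ties
    can be off by several hundredths there); otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)
    if len(a) <= 8 and len(b) <= 8:
        return u, _exact_mw_p(a, b, u)
    if len(pooled) <= _DP_MAX_POOLED:
        return u, _dp_mw_p(ranks, len(a), u)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def refine_signature(
    matrix: ExpressionMatrix,
    genes: list[str] | tuple[str, ...],
    outcomes: dict[str, str] | pd.Series,
    alpha: float = 0.05,
) -> GeneSignature:
    """Keep genes differentially expressed between pCR and RD cases at the
    two-sided Mann-Whitney level ``alpha`` (no multiplicity adjustment)."""
    outcomes = pd.Series(dict(outcomes) if not isinstance(outcomes, pd.Series) else outcomes)
    outcomes = outcomes.dropna()
    labels = set(outcomes.unique())
    if not labels <= {"pCR", "RD"} or len(labels) != 2:
        raise ValueError("outcomes must contain both pCR and RD labels")
    samples = [s for s in matrix.sample_ids if s in outcomes.index]
    is_pcr = np.array([outcomes[s] == "pCR" for s in samples])
    sub = matrix.subset_samples(samples)
    kept = []
    provenance = {}
    for gene in genes:
        row = sub.row(gene)
        u, p = mann_whitney_test(row[is_pcr], row[~is_pcr])
        provenance[gene] = {"mann_whitney_u": u, "refinement_p": p}
        if p < alpha:
            kept.append(gene)
    if not kept:
        raise ValueError(f"no gene passed refinement at alpha={alpha}")
    return GeneSignature(genes=tuple(kept), provenance=provenance)


def signature_score(
    matrix: ExpressionMatrix, signature: GeneSignature | list[str] | tuple[str, ...]
) -> pd.Series:
    """Per-sample mean z-score across signature genes (the 'TIL mean')."""
    genes = signature.genes if isinstance(signature, GeneSignature) else tuple(signature)
    if not matrix.normalized:
        raise ValueError("signature score expects a z-normalized matrix")
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    sub = matrix.data.loc[list(genes)]
    return sub.mean(axis=0)
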