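"""Anti-correlated miRNA-mRNA pair mining with target-prediction support.

miRNAs mostly repress their targets (by destabilizing the mRNA), so a
strongly negative Spearman correlation between a miRNA and a transcript
across tumor samples is evidence of a functional regulatory edge.  The
procedure tests every (miRNA, gene) combination for a chosen miRNA subset,
keeps pairs with rho < rho_max (default -0.7) AND p < p_max (default 0.05)
— both strict inequalities — and then filters the survivors for support by
at least ``min_support`` external target-prediction resources (TargetScan /
microT / Microcosm / PITA / miRTarBase-style edge sets, consumed as given).

No multiple-testing correction is applied at the pair level; the resource
filter is the error control.  Correlations are computed across all tumor
samples (primary and relapse pooled) unless the caller subsets columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .synthetic import SimulationTruth, TargetResource

EXACT_N_MAX = 8


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by full enumeration of rank permutations of y against x."""
    n = len(rx)
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    rhos = (pc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _t_approx_p(rho: float, n: int) -> float:
    r2 = min(rho * rho, 1.0 - 1e-15)
    t = abs(rho) * np.sqrt((n - 2) / (1.0 - r2))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    rho is Pearson correlation of average ranks.  For n <= 8 the p-value
    is exact, from full enumeration of all n! rank permutations; for
    larger n the usual t approximation with n - 2 degrees of freedom is
    used.  Zero variance in either vector makes rho undefined: (nan, nan)
    is returned and such pairs are excluded upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan
    if n <= EXACT_N_MAX:
        return rho, _exact_perm_p(rx, ry, rho)
    return rho, _t_approx_p(rho, n)


@dataclass
class AnticorrPair:
    """One miRNA-gene candidate with its anti-correlation evidence."""

    mirna: str
    gene: str
    rho: float
    p_value: float
    supporting_resources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho must lie in [-1, 1]")


def find_anticorrelated_pairs(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    mirna_subset=None,
    rho_max: float = -0.7,
    p_max: float = 0.05,
) -> list[AnticorrPair]:
    """All (miRNA, gene) pairs with rho < rho_max and p < p_max.

    The two matrices must share an identical *ordered* sample set; a
    mismatch is a hard error (no silent intersection).  Features with zero
    rank variance are excluded (rho undefined).  ``supporting_resources``
    is left empty here; see :func:`filter_by_target_support`.
    """
    if list(mirna_expr.sample_ids) != list(mrna_expr.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share an identical ordered sample set")
    mirnas = list(mirna_subset) if mirna_subset is not None else mirna_expr.feature_ids
    missing = set(mirnas) - set(mirna_expr.feature_ids)
    if missing:
        raise ValueError(f"miRNAs not in matrix: {sorted(missing)}")
    n = len(mirna_expr.sample_ids)
    if n < 4:
        raise ValueError("need >= 4 shared samples")

    mr = stats.rankdata(mirna_expr.values.loc[mirnas].to_numpy(dtype=float), axis=1)
    gr = stats.rankdata(mrna_expr.values.to_numpy(dtype=float), axis=1)
    genes = mrna_expr.feature_ids

    def _standardize(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((c**2).sum(axis=1))
        ok = norm > 0
        c[ok] /= norm[ok, None]
        return c, ok

    mc, m_ok = _standardize(mr)
    gc, g_ok = _standardize(gr)
    rho = mc @ gc.T  # (n_mirnas, n_genes)

    pairs: list[AnticorrPair] = []
    cand_m, cand_g = np.nonzero(rho < rho_max)
    for i, j in zip(cand_m, cand_g):
        if not (m_ok[i] and g_ok[j]):
            continue
        r = float(rho[i, j])
        if n <= EXACT_N_MAX:
            p = _exact_perm_p(mr[i], gr[j], r)
        else:
            p = _t_approx_p(r, n)
        if p < p_max:
            pairs.append(AnticorrPair(mirnas[i], genes[j], r, p))
    pairs.sort(key=lambda pr: (pr.rho, pr.mirna, pr.gene))
    return pairs


def filter_by_target_support(
    pairs: list[AnticorrPair],
    resources: list[TargetResource],
    min_support: int = 1,
) -> list[AnticorrPair]:
    """Keep pairs predicted by at least ``min_support`` resources.

    Each retained pair is annotated with the exact set of supporting
    resource names.
    """
    if not resources and min_support >= 1:
        raise ValueError("empty resource list with min_support >= 1")
    out = []
    for p in pairs:
        support = {r.name for r in resources if (p.mirna, p.gene) in r.edges}
        if len(support) >= min_support:
            out.append(
                AnticorrPair(p.mirna, p.gene, p.rho, p.p_value, support)
            )
    return out


def summarize_pairs(pairs: list[AnticorrPair]) -> tuple[int, int, dict[str, list[str]]]:
    """(number of pairs, number of unique genes, per-miRNA sorted gene lists)."""
    per_mirna: dict[str, list[str]] = {}
    genes = set()
    for p in pairs:
        per_mirna.setdefault(p.mirna, []).append(p.gene)
        genes.add(p.gene)
    for m in per_mirna:
        per_mirna[m] = sorted(set(per_mirna[m]))
    return len(pairs), len(genes), per_mirna


def edge_recall_precision(
    pairs: list[AnticorrPair], truth: SimulationTruth
) -> tuple[float, float]:
    """Recall and precision of recovered edges against the planted map."""
    found = {(p.mirna, p.gene) for p in pairs}
    true = truth.true_edges()
    if not true:
        return np.nan, np.nan
    recall = len(found & true) / len(true)
    precision = len(found & true) / len(found) if found else np.nan
    return recall, precision


def pairs_frame(pairs: list[AnticorrPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [p.mirna for p in pairs],
            "gene": [p.gene for p in pairs],
            "rho": [p.rho for p in pairs],
            "p": [p.p_value for p in pairs],
            "n_support": [len(p.supporting_resources) for p in pairs],
            "resources": [";".join(sorted(p.supporting_resources)) for p in pairs],
        }
    )
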