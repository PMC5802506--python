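"""Normalization, paired differential expression, and high/low classification.

The paired test compares relapse against primary within patients on
log2-CPM values, reporting a per-miRNA log2 fold change (mean over patients
of relapse minus primary) and a two-sided p-value from either a paired t
test or a Wilcoxon signed-rank test.  Calls are made at a raw significance
level (no multiplicity adjustment) — this mirrors how small paired tumor
cohorts are usually screened, and the downstream anti-correlation and
resource-support filters act as the effective error control.

Classification against a non-malignant reference labels each miRNA ``high``
or ``low`` when its mean tumor log2 expression differs from the reference
mean by at least a threshold (inclusive) with a rank-sum p below alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import COUNTS, LOG2, ExpressionMatrix, PairingTable

logger = logging.getLogger(__name__)

CLASSES = ("DE_up", "DE_down", "high", "low", "unclassified")


@dataclass
class MiRNAStatus:
    mirna: str
    log2fc: float
    p_value: float
    mirna_class: str
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.mirna_class not in CLASSES:
            raise ValueError(f"unknown class {self.mirna_class!r}")


def normalize_counts(counts: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million: log2((c + pseudocount) / library_size * 1e6).

    Library size is the raw column sum (pseudocount excluded).  A column
    with zero library size is an error.
    """
    if counts.scale != COUNTS:
        raise ValueError("normalize_counts expects a counts-scale matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lib = counts.values.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    cpm = (counts.values + pseudocount).div(lib, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm), counts.sample_meta.copy(), LOG2)


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by sign-flip enumeration.

    Zero differences are dropped (Wilcoxon convention); tied absolute
    differences take average ranks.  The null distribution of the positive
    rank sum W+ is built by dynamic programming over doubled ranks (so
    half-integer average ranks stay integral), which is exact for any tie
    pattern.  p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    w2 = int(ranks2[d > 0].sum())
    # counts[s] = number of sign assignments with doubled rank sum s
    total = ranks2.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0**n
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _paired_diffs(
    expr: ExpressionMatrix, pairs: PairingTable
) -> tuple[pd.DataFrame, PairingTable]:
    complete = pairs.complete_pairs(expr.sample_ids)
    dropped = len(pairs) - len(complete)
    if dropped:
        logger.warning(
            "%d pair(s) dropped because a partner sample is missing from the matrix",
            dropped,
        )
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete pairs")
    prim = expr.values[list(complete.records["primary_sample"])]
    rel = expr.values[list(complete.records["relapse_sample"])]
    diffs = pd.DataFrame(
        rel.to_numpy() - prim.to_numpy(),
        index=expr.values.index,
        columns=list(complete.records["patient"]),
    )
    return diffs, complete


def paired_de_test(
    expr: ExpressionMatrix,
    pairs: PairingTable,
    method: str = "paired_t",
    alpha: float = 0.05,
) -> list[MiRNAStatus]:
    """Per-miRNA paired relapse-vs-primary test on log2 expression.

    log2FC is the mean over patients of (relapse - primary); p-values are
    two-sided; class is DE_up/DE_down when p < alpha (raw, unadjusted),
    else unclassified.  Under ``paired_t`` a miRNA whose differences have
    zero variance is unassessable and reported with p = 1 and a flag.
    """
    if expr.scale != LOG2:
        raise ValueError("paired_de_test expects a log2-normalized matrix")
    if method not in ("paired_t", "wilcoxon_signed_rank"):
        raise ValueError(f"unknown method {method!r}")
    diffs, _ = _paired_diffs(expr, pairs)
    out = []
    for mirna, row in diffs.iterrows():
        d = row.to_numpy(dtype=float)
        fc = float(d.mean())
        flagged = False
        if method == "paired_t":
            if d.std(ddof=1) == 0:
                p = 1.0
                flagged = True
            else:
                p = float(stats.ttest_rel(d, np.zeros_like(d)).pvalue)
        else:
            p = signed_rank_exact_p(d) if len(d) <= 25 else float(
                stats.wilcoxon(d, method="approx").pvalue
            )
        if p < alpha and fc != 0:
            cls = "DE_up" if fc > 0 else "DE_down"
        else:
            cls = "unclassified"
        out.append(MiRNAStatus(str(mirna), fc, p, cls, flagged))
    return out


def classify_vs_reference(
    expr: ExpressionMatrix,
    reference: ExpressionMatrix,
    up_log2fc: float = 1.0,
    down_log2fc: float = 1.0,
    alpha: float = 0.05,
) -> list[MiRNAStatus]:
    """Label miRNAs high/low in tumor relative to a reference matrix.

    A miRNA is ``high`` when mean tumor log2 expression exceeds the
    reference mean by at least ``up_log2fc`` (inclusive) with a two-sided
    rank-sum p < alpha; ``low`` symmetrically with ``down_log2fc``;
    otherwise ``unclassified``.
    """
    if expr.scale != LOG2 or reference.scale != LOG2:
        raise ValueError("classification expects log2-scale matrices")
    if reference.values.shape[1] < 2:
        raise ValueError("reference needs >= 2 samples")
    shared = expr.values.index.intersection(reference.values.index)
    if len(shared) == 0:
        raise ValueError("empty feature intersection with reference")
    out = []
    for mirna in shared:
        t = expr.values.loc[mirna].to_numpy(dtype=float)
        r = reference.values.loc[mirna].to_numpy(dtype=float)
        delta = float(t.mean() - r.mean())
        if np.all(t == t[0]) and np.all(r == r[0]) and t[0] == r[0]:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.mannwhitneyu(t, r, alternative="two-sided").pvalue)
        if delta >= up_log2fc and p < alpha:
            cls = "high"
        elif delta <= -down_log2fc and p < alpha:
            cls = "low"
        else:
            cls = "unclassified"
        out.append(MiRNAStatus(str(mirna), delta, p, cls))
    return out


def merge_status(
    de: list[MiRNAStatus], ref: list[MiRNAStatus]
) -> list[MiRNAStatus]:
    """Combine DE calls with reference classification, DE taking precedence.

    The result is an exclusive, exhaustive partition over
    {DE_up, DE_down, high, low, unclassified}.
    """
    by_id = {s.mirna: s for s in ref}
    out = []
    seen = set()
    for s in de:
        seen.add(s.mirna)
        if s.mirna_class in ("DE_up", "DE_down"):
            out.append(s)
        elif s.mirna in by_id and by_id[s.mirna].mirna_class != "unclassified":
            out.append(by_id[s.mirna])
        else:
            out.append(s)
    out.extend(s for s in ref if s.mirna not in seen)
    return out


def status_frame(statuses: list[MiRNAStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [s.mirna for s in statuses],
            "log2fc": [s.log2fc for s in statuses],
            "p": [s.p_value for s in statuses],
            "class": [s.mirna_class for s in statuses],
        }
    )
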