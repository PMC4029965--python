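"""Pattern discovery and CoMi index computation.

Pattern discovery asks, for every (miRNA, gene-set) pair, whether the miRNA's
targets are over-represented inside the set (upper-tail hypergeometric test on
the overlap, against a declared gene universe).  Each significant pair becomes
a CoMi pattern whose target / non-target partition of the set is frozen.

The CoMi index then contrasts the expression behaviour of the two halves of
the partition with a Welch (unequal-variance) two-sample t statistic:

    t = (mean(x_T) - mean(x_NT)) / sqrt(s2_T/n_T + s2_NT/n_NT)

with Welch–Satterthwaite degrees of freedom and a two-sided p-value.  For a
condition-level index, x_T and x_NT are per-gene log2 fold changes (case vs
control); for a per-sample index they are the sample's raw expression values.
A positive statistic means the targets sit above the non-targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    CoMiIndex,
    CoMiPattern,
    CoMiProfile,
    ExpressionMatrix,
    GeneSetCollection,
    TargetMap,
)

logger = logging.getLogger(__name__)

#: cap applied to the statistic when both subsets are constant but unequal
DEGENERATE_STAT_CAP = 1e6
#: p-value reported in that capped case (smallest positive float)
DEGENERATE_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class FoldChangeVector:
    """Per-gene log2 fold change of a case condition against its control."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids and values length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.values).all():
            raise ValueError("fold changes must be finite")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.values))


def hypergeom_overlap_p(k_overlap: int, K_targets: int, n_set: int, N_universe: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k_overlap).

    X counts the targets falling in a set of ``n_set`` genes drawn without
    replacement from a universe of ``N_universe`` genes of which ``K_targets``
    are targets.
    """
    if not (0 <= K_targets <= N_universe and 0 <= n_set <= N_universe):
        raise ValueError("subset sizes exceed the universe")
    if not (0 <= k_overlap <= min(K_targets, n_set)):
        raise ValueError(
            f"impossible overlap {k_overlap} for K={K_targets}, n={n_set}, N={N_universe}"
        )
    return float(stats.hypergeom.sf(k_overlap - 1, N_universe, K_targets, n_set))


def discover_patterns(
    targets: TargetMap,
    sets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[CoMiPattern]:
    """All (miRNA, term) pairs with significant target overlap inside the term.

    The hypergeometric test is evaluated against ``universe`` (all genes the
    caller declares measurable); both partition halves must be non-empty so a
    two-sample statistic is defined.  Output order is deterministic (miRNA,
    then term, lexicographic).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if len(targets) == 0:
        raise ValueError("empty target map")
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    uni = frozenset(universe)
    missing = sets.universe() - uni
    if missing:
        raise ValueError(
            f"{len(missing)} gene-set genes missing from the declared universe"
        )
    N = len(uni)
    logger.info("pattern discovery against a universe of %d genes", N)
    patterns: list[CoMiPattern] = []
    for mirna in targets.mirna_ids():
        m_genes = targets.targets[mirna] & uni
        if not m_genes:
            continue
        for term in sets.term_ids():
            g_genes = sets.genes(term) & uni
            t_in = m_genes & g_genes
            nt_in = g_genes - m_genes
            if not t_in or not nt_in:
                continue
            p = hypergeom_overlap_p(len(t_in), len(m_genes), len(g_genes), N)
            if p <= alpha:
                patterns.append(
                    CoMiPattern(
                        mirna=mirna,
                        term=term,
                        target_in_set=frozenset(t_in),
                        nontarget_in_set=frozenset(nt_in),
                        overlap_p=p,
                    )
                )
    return patterns


def fold_change(
    case: ExpressionMatrix, control: ExpressionMatrix, paired: bool = False
) -> FoldChangeVector:
    """Per-gene log2 fold change, case vs control.

    Paired designs average the per-pair differences (columns matched by
    order); unpaired designs take the difference of group means.  On a log2
    scale the two coincide for equal sample counts.
    """
    if case.gene_ids != control.gene_ids:
        raise ValueError("case and control gene universes differ")
    if paired:
        if len(case.sample_ids) != len(control.sample_ids):
            raise ValueError("paired design requires equal sample counts")
        diffs = case.values - control.values
        values = diffs.mean(axis=1)
    else:
        values = case.values.mean(axis=1) - control.values.mean(axis=1)
    return FoldChangeVector(gene_ids=list(case.gene_ids), values=values)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Welch two-sample t statistic and two-sided p-value for x vs y.

    Returns ``(statistic, p_value, degenerate)``.  Degenerate variance
    structure is handled explicitly: both samples constant and equal gives
    (0, 1); both constant and unequal gives the capped statistic with a
    floor p-value; a singleton sample yields a statistic but p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, 1.0, False
        stat = math.copysign(DEGENERATE_STAT_CAP, mx - my)
        return stat, DEGENERATE_P_FLOOR, True
    stat = (mx - my) / math.sqrt(se2)
    if nx < 2 or ny < 2:
        # no Welch-Satterthwaite df with a singleton sample
        return stat, 1.0, True
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(stat), df))
    return stat, min(p, 1.0), False


def _index_from_values(
    pattern: CoMiPattern, values: Mapping[str, float]
) -> CoMiIndex:
    try:
        x_t = np.array([values[g] for g in sorted(pattern.target_in_set)])
        x_nt = np.array([values[g] for g in sorted(pattern.nontarget_in_set)])
    except KeyError as exc:
        raise KeyError(
            f"pattern ({pattern.mirna}, {pattern.term}) gene {exc.args[0]!r} "
            "missing from the expression input"
        ) from None
    stat, p, degenerate = welch_t(x_t, x_nt)
    return CoMiIndex(pattern=pattern, statistic=stat, p_value=p, degenerate=degenerate)


def comi_index_differential(
    pattern: CoMiPattern, fc: FoldChangeVector | Mapping[str, float]
) -> CoMiIndex:
    """CoMi index of a pattern for a condition-level fold-change vector."""
    values = fc.as_mapping() if isinstance(fc, FoldChangeVector) else fc
    return _index_from_values(pattern, values)


def comi_index_per_sample(
    pattern: CoMiPattern, sample_expr: Mapping[str, float]
) -> CoMiIndex:
    """CoMi index of a pattern for one sample's raw expression values."""
    return _index_from_values(pattern, sample_expr)


def compute_profile(
    patterns: Sequence[CoMiPattern],
    values: FoldChangeVector | Mapping[str, float],
    mode: str = "differential",
    condition_id: str = "condition",
) -> CoMiProfile:
    """One CoMi index per pattern; patterns with uncovered genes are dropped.

    ``mode`` is ``differential`` (values are fold changes) or ``per_sample``
    (values are one sample's expression); the contrast is identical, the mode
    only documents the provenance of the values.
    """
    if mode not in ("differential", "per_sample"):
        raise ValueError(f"unknown mode {mode!r}")
    if not patterns:
        raise ValueError("no patterns supplied")
    mapping = values.as_mapping() if isinstance(values, FoldChangeVector) else dict(values)
    indices = {}
    dropped = 0
    for pattern in sorted(patterns, key=lambda p: p.key):
        if not (pattern.genes <= mapping.keys()):
            dropped += 1
            continue
        indices[pattern.key] = _index_from_values(pattern, mapping)
    if dropped:
        logger.warning("dropped %d/%d patterns with uncovered genes", dropped, len(patterns))
    if not indices:
        raise ValueError("every pattern was dropped: no gene coverage")
    return CoMiProfile(condition_id=condition_id, indices=indices)
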