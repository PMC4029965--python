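"""Signature-reversal drug screening with the DSP (Drug Screening Performance)
statistic.

The screen follows the connectivity-map idea in CoMi space: the disease
profile is condensed to a query signature (the k most up- and k most
down-regulated patterns), every library instance is scored by the Spearman
correlation between its statistics and the disease statistics over the
signature patterns, and instances are ranked ascending — the most
anti-correlated (treatment-like) instance first.  Screen success is the
KS-type enrichment of the known-positive instances near the top of that
ranking; its permutation p-value (positives placed uniformly at random) is
the DSP p-value.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CoMiProfile,
    CoMiSignature,
    DrugInstance,
    DSPResult,
    PatternKey,
    RankedDrugList,
)

logger = logging.getLogger(__name__)

#: minimum number of shared signature patterns for a connectivity score
MIN_SHARED_PATTERNS = 3


def make_signature(profile: CoMiProfile, k: int) -> CoMiSignature:
    """Top-k up-regulated and bottom-k down-regulated patterns of a profile.

    The admissible window is 5 <= k <= floor(n/3) where n is the profile
    size; ties at the window boundary are broken lexicographically by
    pattern key so the signature is deterministic.
    """
    n = len(profile)
    k_max = n // 3
    if not (5 <= k <= k_max):
        raise ValueError(f"k={k} outside the valid window [5, {k_max}] for {n} patterns")
    # descending statistic with lexicographic tie-break; the down-tag is
    # drawn from the remaining patterns so tied extremes never collide
    stats_map = profile.statistics()
    desc = sorted(stats_map, key=lambda key: (-stats_map[key], key))
    up = tuple(desc[:k])
    asc = sorted(
        (key for key in stats_map if key not in set(up)),
        key=lambda key: (stats_map[key], key),
    )
    return CoMiSignature(k=k, up_tags=up, down_tags=tuple(asc[:k]))


def connectivity_score(
    sig: CoMiSignature, disease: CoMiProfile, drug: CoMiProfile
) -> float | None:
    """Spearman rho between disease and drug statistics over the signature.

    Negative rho means the drug counteracts the disease pattern.  Returns
    ``None`` when fewer than three signature patterns are shared (the
    instance is then excluded from ranking).
    """
    shared = [key for key in sig.patterns if key in drug.indices and key in disease.indices]
    if len(shared) < MIN_SHARED_PATTERNS:
        return None
    x = [disease.indices[key].statistic for key in shared]
    y = [drug.indices[key].statistic for key in shared]
    rho = stats.spearmanr(x, y).statistic
    if not math.isfinite(rho):  # constant input degenerates rho
        return None
    return float(rho)


def rank_library(
    sig: CoMiSignature, disease: CoMiProfile, library: Sequence[DrugInstance]
) -> RankedDrugList:
    """Rank library instances ascending by connectivity score.

    Rank 1 is the most anti-correlated (strongest predicted treatment).
    Ties are broken by instance id; unscorable instances are dropped with a
    logged warning.
    """
    scored: list[tuple[float, DrugInstance]] = []
    skipped = 0
    for inst in library:
        rho = connectivity_score(sig, disease, inst.profile)
        if rho is None:
            skipped += 1
            continue
        scored.append((rho, inst))
    if skipped:
        logger.warning("excluded %d/%d unscorable instances", skipped, len(library))
    if not scored:
        raise ValueError("no scorable instances in the library")
    scored.sort(key=lambda pair: (pair[0], pair[1].instance_id))
    instances = [inst for _, inst in scored]
    scores = [rho for rho, _ in scored]
    positions = [rank for rank, inst in enumerate(instances, start=1) if inst.is_positive]
    return RankedDrugList(
        instances=instances,
        scores=scores,
        positive_positions=positions,
        N=len(instances),
        n_pos=len(positions),
    )


def ks_score(positions: Sequence[int], n_pos: int, N: int) -> float:
    """Signed KS enrichment of positive ranks toward the top of a list.

    With V(j) the (ascending) rank of the j-th positive instance among N,

        a = max_j [ j/n_pos - V(j)/N ]
        b = max_j [ V(j)/N - (j-1)/n_pos ]

    and the score is ``a`` if a >= b else ``-b``; it lies in [-1, 1].  A
    positive score means the positives concentrate at the top of the ranking.
    """
    v = np.asarray(positions, dtype=float)
    if v.size != n_pos or n_pos < 1 or n_pos > N:
        raise ValueError("positions length must equal n_pos, with 1 <= n_pos <= N")
    if np.any(np.diff(v) <= 0):
        raise ValueError("positions must be strictly increasing")
    if v[0] < 1 or v[-1] > N:
        raise ValueError("positions outside 1..N")
    j = np.arange(1, n_pos + 1, dtype=float)
    a = float(np.max(j / n_pos - v / N))
    b = float(np.max(v / N - (j - 1) / n_pos))
    return a if a >= b else -b


def _ks_scores_batch(positions: np.ndarray, N: int) -> np.ndarray:
    """Vectorized :func:`ks_score` over rows of sorted 1-based positions."""
    n_pos = positions.shape[1]
    j = np.arange(1, n_pos + 1, dtype=float)
    a = (j / n_pos - positions / N).max(axis=1)
    b = (positions / N - (j - 1) / n_pos).max(axis=1)
    return np.where(a >= b, a, -b)


def dsp_pvalue(
    observed: RankedDrugList, n_perm: int = 1000, seed: int = 0
) -> DSPResult:
    """Permutation p-value of the observed KS score.

    Positives are placed uniformly at random (without replacement) among the
    N ranks; p uses the add-one estimator
    ``(#{|KS_perm| >= |KS_obs|} + 1) / (n_perm + 1)`` so it never reaches 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = ks_score(observed.positive_positions, observed.n_pos, observed.N)
    if observed.n_pos == observed.N:
        logger.warning("all instances positive: permutation null has no variability")
        return DSPResult(ks_score=obs, p_value=1.0, n_permutations=n_perm, seed=seed)
    rng = np.random.default_rng(seed)
    # one uniform draw per rank, take the n_pos smallest -> uniform subset
    u = rng.random((n_perm, observed.N))
    idx = np.argpartition(u, observed.n_pos - 1, axis=1)[:, : observed.n_pos]
    perm_positions = np.sort(idx + 1, axis=1).astype(float)
    perm_scores = _ks_scores_batch(perm_positions, observed.N)
    exceed = int(np.sum(np.abs(perm_scores) >= abs(obs)))
    p = (exceed + 1) / (n_perm + 1)
    return DSPResult(ks_score=obs, p_value=p, n_permutations=n_perm, seed=seed)


def dsp_sweep(
    disease: CoMiProfile,
    library: Sequence[DrugInstance],
    k_values: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One DSP evaluation per signature window size k.

    Returns the per-k table (columns k, ks_score, p_value plus the signature
    object) and a summary of the pooled KS distribution (median, quartiles).
    """
    if len(k_values) == 0:
        raise ValueError("empty k list")
    rows = []
    for k in k_values:
        sig = make_signature(disease, k)
        ranked = rank_library(sig, disease, library)
        result = dsp_pvalue(ranked, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "k": k,
                "ks_score": result.ks_score,
                "p_value": result.p_value,
                "signature": sig,
            }
        )
    table = pd.DataFrame(rows)
    ks = table["ks_score"].to_numpy()
    summary = {
        "median_ks": float(np.median(ks)),
        "q1_ks": float(np.percentile(ks, 25)),
        "q3_ks": float(np.percentile(ks, 75)),
    }
    return table, summary


def default_k_values(n_patterns: int, step: int = 1) -> list[int]:
    """The full admissible signature window sweep: k = 5 .. floor(n/3)."""
    k_max = n_patterns // 3
    if k_max < 5:
        raise ValueError(f"profile too small for a signature sweep ({n_patterns} patterns)")
    return list(range(5, k_max + 1, step))


def discriminative_features(
    sweep: pd.DataFrame, top_fraction: float = 0.5
) -> set[PatternKey]:
    """Union of signature patterns of the best-performing sweep signatures.

    The sweep rows with DSP KS score in the top ``top_fraction`` contribute
    their up- and down-tags; these patterns are the most discriminative for
    the screened indication.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    if len(sweep) == 0:
        raise ValueError("empty sweep")
    n_top = max(1, math.ceil(top_fraction * len(sweep)))
    ordered = sweep.sort_values(["ks_score", "k"], ascending=[False, True])
    features: set[PatternKey] = set()
    for _, row in ordered.head(n_top).iterrows():
        features.update(row["signature"].patterns)
    return features
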