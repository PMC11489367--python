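"""Pairwise differentiation, geographic distance, the permutation GLM on
pair type plus distance, and the delta-K summary of clustering runs.

Jost's D per locus uses the unbiased within/total heterozygosities with
harmonic-mean sample size, scaled by n/(n-1) for n = 2 populations, and
combines loci by an arithmetic mean by default (harmonic available).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ripopgen.genotype_io import GenotypeMatrix, PopulationSet

logger = logging.getLogger("ripopgen")


def _locus_freqs(pop: GenotypeMatrix, j: int) -> tuple[dict[int, float], int]:
    genes = pop.calls[:, j, :].ravel()
    genes = genes[genes != 0]
    n = int((~pop.missing_mask()[:, j]).sum())
    if genes.size == 0:
        return {}, 0
    alleles, counts = np.unique(genes, return_counts=True)
    return {int(a): float(c) / genes.size for a, c in zip(alleles, counts)}, n


def jost_d_locus(pA: dict[int, float], pB: dict[int, float],
                 nA: int, nB: int) -> float | None:
    """Per-locus Jost's D for two populations; None when undefined.

    With harmonic-mean sample size n~,
      Hs = (2 n~ / (2 n~ - 1)) * mean_pop(1 - sum p^2)
      Ht = 1 - sum pbar^2 + Hs / (4 n~),   pbar = (pA + pB) / 2
      D  = (Ht - Hs) / (1 - Hs) * 2        (n/(n-1) with n = 2 pops)
    clamped below at 0.
    """
    if nA < 2 or nB < 2:
        return None
    n_h = 2.0 / (1.0 / nA + 1.0 / nB)
    hs_raw = np.mean([
        1.0 - sum(p ** 2 for p in pA.values()),
        1.0 - sum(p ** 2 for p in pB.values()),
    ])
    hs = (2 * n_h / (2 * n_h - 1)) * hs_raw
    if hs >= 1.0:
        return None
    alleles = set(pA) | set(pB)
    ht = 1.0 - sum(((pA.get(a, 0.0) + pB.get(a, 0.0)) / 2.0) ** 2 for a in alleles)
    ht += hs / (4.0 * n_h)
    d = (ht - hs) / (1.0 - hs) * 2.0
    return max(d, 0.0)


def jost_d_pair(popA: GenotypeMatrix, popB: GenotypeMatrix,
                combine: str = "arithmetic") -> float:
    """Multi-locus Jost's D between two populations.

    ``combine``: "arithmetic" (default) or "harmonic" mean of per-locus
    D values; the harmonic variant follows the global-D convention and
    treats non-positive loci as zero contribution.
    """
    if popA.locus_ids != popB.locus_ids:
        raise ValueError("populations must share loci")
    per_locus = []
    for j, locus in enumerate(popA.locus_ids):
        pA, nA = _locus_freqs(popA, j)
        pB, nB = _locus_freqs(popB, j)
        if not pA or not pB:
            logger.warning("locus %s skipped in Jost's D (no data)", locus)
            continue
        d = jost_d_locus(pA, pB, nA, nB)
        if d is None:
            logger.warning("locus %s skipped in Jost's D (undefined)", locus)
            continue
        per_locus.append(d)
    if not per_locus:
        raise ValueError("no locus usable for Jost's D")
    arr = np.asarray(per_locus)
    if combine == "arithmetic":
        return float(arr.mean())
    if combine == "harmonic":
        if (arr <= 0).any():
            # 1/mean(1/D) with D=0 terms -> harmonic mean 0
            return 0.0
        return float(1.0 / np.mean(1.0 / arr))
    raise ValueError("combine must be 'arithmetic' or 'harmonic'")


@dataclass
class PairwiseMatrix:
    pop_ids: list[str]
    values: np.ndarray           # symmetric, zero diagonal
    pair_type: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.pop_ids),) * 2:
            raise ValueError("matrix shape must match population count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pop_ids, columns=self.pop_ids)


def _pair_type(t1: str, t2: str) -> str:
    key = sorted([t1, t2])
    if key == ["sympatric", "sympatric"]:
        return "sym-sym"
    if key == ["allopatric", "sympatric"]:
        return "allo-sym"
    return "allo-allo"


def jost_d_matrix(pop_set: PopulationSet, combine: str = "arithmetic") -> PairwiseMatrix:
    ids = pop_set.pop_ids
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = jost_d_pair(pop_set[ids[i]], pop_set[ids[j]], combine)
        mat[i, j] = mat[j, i] = d
    return PairwiseMatrix(ids, mat)


def pairwise_distance_km(pop_set: PopulationSet) -> PairwiseMatrix:
    """Euclidean distance on planar km coordinates."""
    ids = pop_set.pop_ids
    coords = []
    for pid in ids:
        meta = pop_set.metadata[pid]
        if meta.x_km is None or meta.y_km is None:
            raise ValueError(f"population {pid!r} lacks coordinates")
        coords.append((meta.x_km, meta.y_km))
    xy = np.asarray(coords)
    diff = xy[:, None, :] - xy[None, :, :]
    return PairwiseMatrix(ids, np.sqrt((diff ** 2).sum(axis=2)))


def pair_table(pop_set: PopulationSet, d: PairwiseMatrix,
               dist: PairwiseMatrix) -> pd.DataFrame:
    """One row per unordered population pair: D, type, distance."""
    if d.pop_ids != dist.pop_ids:
        raise ValueError("matrices must index the same populations")
    pop_set.require_types()
    rows = []
    ids = d.pop_ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        rows.append({
            "pop_a": ids[i],
            "pop_b": ids[j],
            "pair_type": _pair_type(pop_set.metadata[ids[i]].type,
                                    pop_set.metadata[ids[j]].type),
            "distance_km": dist.values[i, j],
            "D": d.values[i, j],
        })
    return pd.DataFrame(rows)


@dataclass
class PermutationGlmResult:
    names: list[str]
    coefficients: np.ndarray
    pvalues: np.ndarray
    n_perm: int
    flags: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coefficient": self.coefficients,
                             "perm_p": self.pvalues}, index=self.names)


def permutation_glm_d(pairs: pd.DataFrame, n_perm: int = 9999,
                      seed: int = 0) -> PermutationGlmResult:
    """OLS of pairwise D on pair-type factors plus distance, with
    permutation p-values obtained by shuffling the response over rows.

    p = (1 + #{|coef*| >= |coef_obs|}) / (1 + n_perm).  Pairwise rows
    are not independent; the scheme is the conventional row permutation
    and inherits that caveat.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    y = pairs["D"].to_numpy(dtype=float)
    types = pairs["pair_type"].to_numpy()
    levels = sorted(set(types))
    cols = [np.ones(len(pairs))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((types == lev).astype(float))
        names.append(f"pair_type[{lev}]")
    cols.append(pairs["distance_km"].to_numpy(dtype=float))
    names.append("distance_km")
    X = np.column_stack(cols)
    flags: list[str] = []
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        flags.append(f"design rank {rank} < {X.shape[1]} columns")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    rng = np.random.default_rng(seed)
    # all permutations at once: (n_perm, n) response matrix
    perm_idx = np.argsort(rng.random((n_perm, len(y))), axis=1)
    beta_perm = (pinv @ y[perm_idx].T).T                 # (n_perm, p)
    exceed = (np.abs(beta_perm) >= np.abs(beta)[None, :] - 1e-12).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationGlmResult(names, beta, pvals, n_perm, flags)


# ---------------------------------------------------------------------------
# Evanno delta-K post-processing of clustering log-probabilities


def evanno_delta_k(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Delta-K per interior K and the argmax K.

    ``table`` columns: K, replicate, lnP (>= 2 replicates for >= 3
    consecutive K).  deltaK(K) = |mean lnP(K+1) - 2 mean lnP(K)
    + mean lnP(K-1)| / sd(lnP(K)), sd with n-1 denominator; K values
    with zero sd are excluded from the argmax with a warning.
    """
    required = {"K", "replicate", "lnP"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    grouped = table.groupby("K")["lnP"]
    stats = pd.DataFrame({"mean_lnP": grouped.mean(), "sd_lnP": grouped.std(ddof=1),
                          "n_rep": grouped.count()}).sort_index()
    ks = stats.index.to_numpy()
    if len(ks) < 3 or not np.array_equal(ks, np.arange(ks[0], ks[0] + len(ks))):
        raise ValueError("need >= 3 consecutive K values")
    if (stats["n_rep"] < 2).any():
        raise ValueError("need >= 2 replicates per K")
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        sd = stats["sd_lnP"].iloc[i]
        second = (stats["mean_lnP"].iloc[i + 1] - 2 * stats["mean_lnP"].iloc[i]
                  + stats["mean_lnP"].iloc[i - 1])
        if sd == 0:
            logger.warning("K=%d has zero sd; deltaK undefined there", ks[i])
            continue
        delta[i] = abs(second) / sd
    stats["deltaK"] = delta
    if np.all(np.isnan(delta)):
        raise ValueError("deltaK undefined at every interior K")
    best_k = int(ks[int(np.nanargmax(delta))])
    return stats, best_k
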