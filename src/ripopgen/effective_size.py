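"""Single-sample effective population size estimators.

``ne_ld`` follows the linkage-disequilibrium method: Burrows composite
disequilibrium r^2 averaged over allele pairs across locus pairs, minus
the sample-size expectation, mapped to Ne with the random-mating
constants of the published bias-corrected method (large-sample and
small-sample variants switch at S = 30).  ``ne_coancestry`` estimates
Ne from mean positive pairwise molecular co-ancestry.

Both assume random mating; under strong selfing they are biased
downward, so a warning is emitted when the sample's inbreeding
coefficient exceeds 0.5 (usage kept faithful to common practice).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ripopgen.genotype_io import GenotypeMatrix, PopulationSet

logger = logging.getLogger("ripopgen")


@dataclass
class NeLdResult:
    ne: float                    # may be math.inf
    r2_mean: float
    r2_drift: float
    S: float                     # harmonic-mean sample size over comparisons
    n_comparisons: int
    ci: tuple[float, float]
    flags: list[str] = field(default_factory=list)


def _retained_alleles(pop: GenotypeMatrix, allele_freq_min: float) -> list[list[int]]:
    out = []
    for j in range(pop.n_loci):
        genes = pop.calls[:, j, :].ravel()
        genes = genes[genes != 0]
        if genes.size == 0:
            out.append([])
            continue
        alleles, counts = np.unique(genes, return_counts=True)
        freqs = counts / genes.size
        out.append([int(a) for a, f in zip(alleles, freqs) if f >= allele_freq_min])
    return out


def _expected_r2(S: float) -> float:
    """Sampling expectation of r^2 under random mating (unlinked loci)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def _r2_to_ne(r2_drift: float, S: float) -> float:
    if r2_drift <= 0:
        return float("inf")
    if S >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
        ne = (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_drift)
    else:
        disc = max(0.308 ** 2 - 2.08 * r2_drift, 0.0)
        ne = (0.308 + np.sqrt(disc)) / (2.0 * r2_drift)
    return float(ne) if ne > 0 else float("inf")


def ne_ld(pop: GenotypeMatrix, allele_freq_min: float = 0.02,
          ci_level: float = 0.95) -> NeLdResult:
    """Linkage-disequilibrium Ne with a parametric chi-square CI.

    Alleles below ``allele_freq_min`` are excluded; a non-positive drift
    signal reports an infinite estimate.
    """
    if pop.n_loci < 2:
        raise ValueError("ne_ld requires >= 2 loci")
    retained = _retained_alleles(pop, allele_freq_min)
    ok = ~pop.missing_mask()
    r2s, sizes = [], []
    flags: list[str] = []
    for k, l in itertools.combinations(range(pop.n_loci), 2):
        sub = ok[:, k] & ok[:, l]
        n = int(sub.sum())
        if n < 3:
            continue
        ck = pop.calls[sub, k, :]
        cl = pop.calls[sub, l, :]
        for a in retained[k]:
            X = (ck == a).sum(axis=1).astype(float)
            pA = X.mean() / 2.0
            if not 0 < pA < 1:
                continue
            dA = float((X == 2).mean()) - pA ** 2        # homozygote excess
            for b in retained[l]:
                Y = (cl == b).sum(axis=1).astype(float)
                pB = Y.mean() / 2.0
                if not 0 < pB < 1:
                    continue
                dB = float((Y == 2).mean()) - pB ** 2
                delta = (n / (n - 1.0)) * (float((X * Y).mean()) / 2.0 - 2 * pA * pB)
                denom = (pA * (1 - pA) + dA) * (pB * (1 - pB) + dB)
                if denom <= 0:
                    continue
                r2s.append(delta ** 2 / denom)
                sizes.append(n)
    if not r2s:
        raise ValueError("no usable allele-pair comparison (monomorphic data?)")
    r2_mean = float(np.mean(r2s))
    S = len(sizes) / float(np.sum(1.0 / np.asarray(sizes, dtype=float)))
    r2_drift = r2_mean - _expected_r2(S)
    ne = _r2_to_ne(r2_drift, S)
    if np.isinf(ne):
        flags.append("drift signal <= sampling expectation: Ne infinite")
    n_comp = len(r2s)
    alpha = 1 - ci_level
    lo_r2 = n_comp * r2_mean / chi2.ppf(1 - alpha / 2, n_comp)
    hi_r2 = n_comp * r2_mean / chi2.ppf(alpha / 2, n_comp)
    ci = (_r2_to_ne(hi_r2 - _expected_r2(S), S),
          _r2_to_ne(lo_r2 - _expected_r2(S), S))
    return NeLdResult(ne=ne, r2_mean=r2_mean, r2_drift=r2_drift, S=S,
                      n_comparisons=n_comp, ci=ci, flags=flags)


@dataclass
class NeCnResult:
    ne: float
    f_positive_mean: float
    n_pairs: int
    n_positive: int
    flags: list[str] = field(default_factory=list)


def ne_coancestry(pop: GenotypeMatrix) -> NeCnResult:
    """Molecular co-ancestry Ne: 1 / (2 * mean positive adjusted co-ancestry).

    Pairwise allele-sharing similarity per locus, adjusted by the
    chance-sharing baseline sum(p^2) and combined across loci as a ratio
    of sums; the summary averages the positive pair values only.
    """
    n = pop.n_individuals
    if n < 2:
        raise ValueError("ne_coancestry requires >= 2 individuals")
    calls = pop.calls                                     # (n, L, 2)
    ok = ~pop.missing_mask()                              # (n, L)
    # similarity s[i,j,l] = 1/4 * # matching allele comparisons
    eq = calls[:, None, :, :, None] == calls[None, :, :, None, :]
    sim = eq.mean(axis=(3, 4))                            # (n, n, L)
    s0 = np.zeros(pop.n_loci)
    for j in range(pop.n_loci):
        genes = calls[:, j, :].ravel()
        genes = genes[genes != 0]
        if genes.size:
            p = np.unique(genes, return_counts=True)[1] / genes.size
            s0[j] = float(np.sum(p ** 2))
        else:
            s0[j] = 1.0                                   # no information
    pair_ok = ok[:, None, :] & ok[None, :, :]             # (n, n, L)
    num = np.where(pair_ok, sim - s0[None, None, :], 0.0).sum(axis=2)
    den = np.where(pair_ok, 1.0 - s0[None, None, :], 0.0).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fstar = np.where(den[iu] > 0, num[iu] / den[iu], np.nan)
    fstar = fstar[np.isfinite(fstar)]
    if fstar.size == 0:
        raise ValueError("no informative pair for co-ancestry")
    positive = fstar[fstar > 0]
    flags: list[str] = []
    if positive.size == 0:
        flags.append("no positive co-ancestry: Ne infinite")
        return NeCnResult(float("inf"), 0.0, fstar.size, 0, flags)
    f_plus = float(positive.mean())
    return NeCnResult(ne=1.0 / (2.0 * f_plus), f_positive_mean=f_plus,
                      n_pairs=int(fstar.size), n_positive=int(positive.size),
                      flags=flags)


def ne_estimates(pop_set: PopulationSet, allele_freq_min: float = 0.02) -> pd.DataFrame:
    """NeEstimates table: Ne_LD with CI, Ne_Cn and settings per population."""
    from ripopgen.diversity import f_is

    rows = []
    for pid in pop_set.pop_ids:
        pop = pop_set[pid]
        fis = f_is(pop).f
        if np.isfinite(fis) and fis > 0.5:
            logger.warning(
                "population %s: F_IS=%.2f violates the random-mating assumption "
                "of Ne estimators (expect downward bias)", pid, fis)
        try:
            ld = ne_ld(pop, allele_freq_min)
            ne_ld_val, ci, S = ld.ne, ld.ci, ld.S
        except ValueError as exc:
            logger.warning("population %s: Ne_LD undefined (%s)", pid, exc)
            ne_ld_val, ci, S = np.nan, (np.nan, np.nan), np.nan
        try:
            cn = ne_coancestry(pop).ne
        except ValueError as exc:
            logger.warning("population %s: Ne_Cn undefined (%s)", pid, exc)
            cn = np.nan
        rows.append({
            "population": pid,
            "type": pop_set.metadata[pid].type,
            "Ne_LD": ne_ld_val,
            "Ne_LD_ci_low": ci[0],
            "Ne_LD_ci_high": ci[1],
            "Ne_Cn": cn,
            "S": S,
            "p_crit": allele_freq_min,
        })
    return pd.DataFrame(rows).set_index("population")
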