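"""Per-population diversity and inbreeding indices.

A (mean alleles/locus), AR (rarefied allelic richness), RA (rare-allele
count against pooled frequencies), H_O, Nei's unbiased H_E, and the
Weir & Cockerham (1984) within-population inbreeding coefficient f,
combined across alleles and loci as a ratio of summed variance
components.  Missing data are handled by locus-wise deletion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ripopgen.genotype_io import GenotypeMatrix, PopulationSet

logger = logging.getLogger("ripopgen")


def allele_frequencies(pop: GenotypeMatrix, locus: str) -> dict[int, float]:
    """Allele relative frequencies at one locus over observed gene copies.

    Raises ``ValueError`` when the locus has no non-missing call.
    """
    j = pop.locus_ids.index(locus)
    genes = pop.calls[:, j, :].ravel()
    genes = genes[genes != 0]
    if genes.size == 0:
        raise ValueError(f"locus {locus!r}: all calls missing")
    alleles, counts = np.unique(genes, return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def _allele_counts_per_locus(pop: GenotypeMatrix) -> list[dict[int, int]]:
    out = []
    for j in range(pop.n_loci):
        genes = pop.calls[:, j, :].ravel()
        genes = genes[genes != 0]
        alleles, counts = np.unique(genes, return_counts=True)
        out.append({int(a): int(c) for a, c in zip(alleles, counts)})
    return out


def observed_heterozygosity(pop: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Per-locus and mean H_O: fraction of non-missing calls that are heterozygous."""
    het = pop.het_mask()
    ok = ~pop.missing_mask()
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_locus = np.where(n_ok > 0, het.sum(axis=0) / np.maximum(n_ok, 1), np.nan)
    series = pd.Series(per_locus, index=pop.locus_ids, name="H_O")
    return series, float(np.nanmean(per_locus))


def expected_heterozygosity_nei(pop: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Nei's unbiased H_E per locus, (2n/(2n-1)) * (1 - sum p_i^2), and the mean.

    Loci with fewer than two non-missing calls are excluded with a warning.
    """
    ok = ~pop.missing_mask()
    n_ok = ok.sum(axis=0)
    values = np.full(pop.n_loci, np.nan)
    for j in range(pop.n_loci):
        n = int(n_ok[j])
        if n < 2:
            logger.warning("locus %s: <2 genotypes, excluded from H_E",
                           pop.locus_ids[j])
            continue
        genes = pop.calls[:, j, :].ravel()
        genes = genes[genes != 0]
        p = np.unique(genes, return_counts=True)[1] / genes.size
        values[j] = (2 * n / (2 * n - 1)) * (1.0 - np.sum(p ** 2))
    series = pd.Series(values, index=pop.locus_ids, name="H_E")
    return series, float(np.nanmean(values))


def mean_alleles_per_locus(pop: GenotypeMatrix) -> float:
    """A: observed allele count averaged over loci with data."""
    counts = [len(c) for c in _allele_counts_per_locus(pop) if c]
    return float(np.mean(counts)) if counts else float("nan")


def allelic_richness(pop_set: PopulationSet, g: int | str = "auto") -> pd.Series:
    """Rarefied allelic richness per population at standard gene count ``g``.

    Per locus, the expected number of alleles among ``g`` genes drawn
    without replacement:  sum_a [1 - C(N - N_a, g) / C(N, g)]  with N the
    observed gene copies and N_a the copies of allele a; averaged over
    loci.  ``g="auto"`` uses 2 * (smallest per-locus genotype count over
    all populations), the convention of standard rarefaction tools.
    """
    per_pop_counts = {pid: _allele_counts_per_locus(pop_set[pid])
                      for pid in pop_set.pop_ids}
    if g == "auto":
        min_n = min(
            int((~pop_set[pid].missing_mask()).sum(axis=0).min())
            for pid in pop_set.pop_ids
        )
        g_val = 2 * min_n
        if g_val < 1:
            raise ValueError("auto rarefaction size is 0: an all-missing locus exists")
    else:
        g_val = int(g)
        if g_val < 1:
            raise ValueError("g must be >= 1")
    out = {}
    for pid in pop_set.pop_ids:
        per_locus = []
        for j, counts in enumerate(per_pop_counts[pid]):
            n_genes = sum(counts.values())
            if n_genes == 0:
                continue
            if g_val > n_genes:
                raise ValueError(
                    f"g={g_val} exceeds {n_genes} genes at locus "
                    f"{pop_set.locus_ids[j]!r} in population {pid!r}"
                )
            denom = math.comb(n_genes, g_val)
            expected = sum(
                1.0 - math.comb(n_genes - na, g_val) / denom
                for na in counts.values()
            )
            per_locus.append(expected)
        out[pid] = float(np.mean(per_locus)) if per_locus else float("nan")
    return pd.Series(out, name=f"AR_g{g_val}")


def rare_alleles(pop_set: PopulationSet, threshold: float = 0.01) -> pd.Series:
    """RA per population: count of present alleles whose *pooled* relative
    frequency across all populations is strictly below ``threshold``."""
    pooled: list[dict[int, int]] = [dict() for _ in pop_set.locus_ids]
    per_pop = {pid: _allele_counts_per_locus(pop_set[pid]) for pid in pop_set.pop_ids}
    for counts_list in per_pop.values():
        for j, counts in enumerate(counts_list):
            for a, c in counts.items():
                pooled[j][a] = pooled[j].get(a, 0) + c
    rare: list[set[int]] = []
    for j, counts in enumerate(pooled):
        total = sum(counts.values())
        rare.append({a for a, c in counts.items() if total and c / total < threshold})
    out = {}
    for pid in pop_set.pop_ids:
        ra = 0
        for j, counts in enumerate(per_pop[pid]):
            ra += sum(1 for a in counts if a in rare[j])
        out[pid] = ra
    return pd.Series(out, name="RA", dtype=int)


@dataclass
class FisResult:
    """Weir & Cockerham within-population f with a naive diagnostic."""

    f: float
    per_locus: pd.Series
    f_naive: float  # 1 - H_O / H_E, diagnostics only


def _wc_components(pop: GenotypeMatrix, j: int) -> tuple[float, float]:
    """Summed (b, c) variance components over alleles at locus index j.

    Single-population Weir & Cockerham (1984): per allele A with sample
    frequency p and heterozygote-carrying frequency hbar over n genotypes,
      c = hbar / 2
      b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * hbar].
    """
    ok = ~pop.missing_mask()[:, j]
    n = int(ok.sum())
    if n < 2:
        return 0.0, 0.0
    calls = pop.calls[ok, j, :]
    genes = calls.ravel()
    alleles = np.unique(genes)
    if alleles.size < 2:
        return 0.0, 0.0
    b_sum = c_sum = 0.0
    for a in alleles:
        p = float((genes == a).sum()) / (2 * n)
        hbar = float(((calls[:, 0] == a) ^ (calls[:, 1] == a)).sum()) / n
        c = hbar / 2.0
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * hbar)
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def f_is(pop: GenotypeMatrix) -> FisResult:
    """Multilocus Weir & Cockerham f = 1 - sum(c) / sum(b + c).

    Components are summed over alleles and loci (ratio of sums, not mean
    of ratios).  Undefined (NaN, with a warning) when no polymorphic
    locus exists.
    """
    if pop.n_individuals < 2:
        raise ValueError("f_is requires >= 2 individuals")
    per_locus = {}
    b_tot = c_tot = 0.0
    for j, locus in enumerate(pop.locus_ids):
        b, c = _wc_components(pop, j)
        if b + c > 0:
            per_locus[locus] = 1.0 - c / (b + c)
            b_tot += b
            c_tot += c
        else:
            per_locus[locus] = np.nan
    if b_tot + c_tot == 0:
        logger.warning("f_is undefined: no polymorphic locus")
        f = float("nan")
    else:
        f = 1.0 - c_tot / (b_tot + c_tot)
    _, ho = observed_heterozygosity(pop)
    _, he = expected_heterozygosity_nei(pop)
    naive = 1.0 - ho / he if he and np.isfinite(he) and he > 0 else float("nan")
    return FisResult(f=f, per_locus=pd.Series(per_locus, name="F_IS"), f_naive=naive)


def diversity_indices(pop_set: PopulationSet, g: int | str = "auto",
                      rare_threshold: float = 0.01) -> pd.DataFrame:
    """IndexTable: one row per population with A, AR, RA, H_O, H_E, F_IS."""
    ar = allelic_richness(pop_set, g)
    ra = rare_alleles(pop_set, rare_threshold)
    rows = []
    for pid in pop_set.pop_ids:
        pop = pop_set[pid]
        _, ho = observed_heterozygosity(pop)
        _, he = expected_heterozygosity_nei(pop)
        rows.append({
            "population": pid,
            "type": pop_set.metadata[pid].type,
            "n": pop.n_individuals,
            "A": mean_alleles_per_locus(pop),
            "AR": float(ar[pid]),
            "RA": int(ra[pid]),
            "H_O": ho,
            "H_E": he,
            "F_IS": f_is(pop).f,
        })
    return pd.DataFrame(rows).set_index("population")
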