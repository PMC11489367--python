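"""Independent brute-force oracles, deliberately coded with plain Python
loops (no numpy vectorisation, no code shared with the package) so that
each estimator can be checked against a second, transparent route."""

from __future__ import annotations

import itertools
import math


def gene_copy_frequencies(calls: list[tuple[int, int]]) -> dict[int, float]:
    """Tally oracle: allele frequencies by explicit gene-copy count."""
    tally: dict[int, int] = {}
    for a, b in calls:
        if a == 0:
            continue
        tally[a] = tally.get(a, 0) + 1
        tally[b] = tally.get(b, 0) + 1
    total = sum(tally.values())
    return {k: v / total for k, v in tally.items()}


def observed_het(calls: list[tuple[int, int]]) -> float:
    """Per-individual tally oracle for one locus."""
    usable = [(a, b) for a, b in calls if a != 0]
    return sum(1 for a, b in usable if a != b) / len(usable)


def nei_unbiased_he(calls: list[tuple[int, int]]) -> float:
    """Gene-copy enumeration oracle for Nei's unbiased H_E at one locus."""
    usable = [(a, b) for a, b in calls if a != 0]
    n = len(usable)
    freqs = gene_copy_frequencies(usable)
    return (2 * n / (2 * n - 1)) * (1.0 - sum(p * p for p in freqs.values()))


def rarefied_richness(calls: list[tuple[int, int]], g: int) -> float:
    """Subset-enumeration oracle: average distinct alleles over every
    combination of g gene copies drawn from the observed copies."""
    genes = [x for a, b in calls if a != 0 for x in (a, b)]
    combos = list(itertools.combinations(range(len(genes)), g))
    total = 0
    for combo in combos:
        total += len({genes[i] for i in combo})
    return total / len(combos)


def wc_fis(calls_by_locus: list[list[tuple[int, int]]]) -> float:
    """Literal transcription of the Weir & Cockerham (1984) single-population
    variance components, combined by summing b and c over alleles and loci."""
    b_total = 0.0
    c_total = 0.0
    for calls in calls_by_locus:
        usable = [(a, b) for a, b in calls if a != 0]
        n = len(usable)
        if n < 2:
            continue
        alleles = sorted({x for pair in usable for x in pair})
        if len(alleles) < 2:
            continue
        for allele in alleles:
            copies = sum(int(a == allele) + int(b == allele) for a, b in usable)
            p = copies / (2 * n)
            hets = sum(1 for a, b in usable if (a == allele) != (b == allele))
            h_bar = hets / n
            c = h_bar / 2
            b_comp = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h_bar)
            b_total += b_comp
            c_total += c
    return 1.0 - c_total / (b_total + c_total)


def jost_d_two_pops(
    calls_a: list[list[tuple[int, int]]],
    calls_b: list[list[tuple[int, int]]],
) -> float:
    """Direct per-locus transcription of the two-population Jost's D with
    harmonic-mean sample size, arithmetic mean across usable loci."""
    per_locus = []
    for la, lb in zip(calls_a, calls_b):
        ua = [(a, b) for a, b in la if a != 0]
        ub = [(a, b) for a, b in lb if a != 0]
        na, nb = len(ua), len(ub)
        if na < 2 or nb < 2:
            continue
        fa = gene_copy_frequencies(ua)
        fb = gene_copy_frequencies(ub)
        n_h = 2.0 / (1.0 / na + 1.0 / nb)
        hs_raw = ((1 - sum(p * p for p in fa.values()))
                  + (1 - sum(p * p for p in fb.values()))) / 2.0
        hs = (2 * n_h / (2 * n_h - 1)) * hs_raw
        if hs >= 1.0:
            continue
        alleles = set(fa) | set(fb)
        ht = 1.0 - sum(((fa.get(x, 0.0) + fb.get(x, 0.0)) / 2) ** 2 for x in alleles)
        ht += hs / (4 * n_h)
        d = (ht - hs) / (1 - hs) * 2.0
        per_locus.append(max(d, 0.0))
    return sum(per_locus) / len(per_locus)


def ml_loglik_loops(
    s: float,
    h: list[float],
    het: list[list[int | None]],
    T: int = 30,
) -> float:
    """Plain-loop multilocus-heterozygosity log-likelihood.

    ``het[i][l]`` is 1 (het), 0 (hom) or None (missing).
    """
    total = 0.0
    for row in het:
        lik = 0.0
        for t in range(T + 1):
            w = (1 - s) * s ** t if s > 0 else (1.0 if t == 0 else 0.0)
            prod = w
            for l, y in enumerate(row):
                if y is None:
                    continue
                p = h[l] * 2.0 ** (-t)
                prod *= p if y else (1 - p)
            lik += prod
        total += math.log(lik)
    return total


def evanno_delta_k_table(mean_lnp: dict[int, float], sd_lnp: dict[int, float]) -> dict[int, float]:
    """Spreadsheet-style second-difference oracle."""
    ks = sorted(mean_lnp)
    out = {}
    for k in ks[1:-1]:
        if sd_lnp[k] == 0:
            continue
        second = mean_lnp[k + 1] - 2 * mean_lnp[k] + mean_lnp[k - 1]
        out[k] = abs(second) / sd_lnp[k]
    return out
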