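"""Selfing-rate estimators and the conservative outcrossing classifier.

Three routes to a population selfing rate:

* ``selfing_from_fis``: Wright's transform S = 2F/(1+F) of an inbreeding
  coefficient;
* ``g2_estimate``: identity disequilibrium across locus pairs, inverted
  through g2 = s / ((1-s)(4-s));
* ``ml_selfing_fit``: maximum likelihood on the distribution of
  multilocus heterozygosity with a latent geometric selfing age.

Plus the maternal allele-exclusion seed classifier (a seed is outcrossed
only when it carries an allele its mother lacks — deliberately
conservative) and the binomial-logit GLMM relating plot outcrossing
rates to congener abundance and pollinator visitation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from ripopgen._glmm import GlmmResult, fit_binomial_glmm
from ripopgen.genotype_io import GenotypeMatrix, PlotSurvey, PopulationSet, SeedFamily

logger = logging.getLogger("ripopgen")


# ---------------------------------------------------------------------------
# F_IS route


def selfing_from_fis(F: float) -> tuple[float, list[str]]:
    """S_F = 2F/(1+F), clamped to [0, 1]; flags report clamping."""
    if not -1 < F <= 1:
        raise ValueError(f"F must lie in (-1, 1], got {F}")
    s = 2 * F / (1 + F)
    flags = []
    if F < 0:
        flags.append("negative F clamped to S_F = 0")
        s = 0.0
    return float(min(s, 1.0)), flags


# ---------------------------------------------------------------------------
# identity-disequilibrium (g2) route


def g2_forward(s: float) -> float:
    """Identity disequilibrium implied by equilibrium selfing rate s."""
    if not 0 <= s < 1:
        raise ValueError("s must lie in [0, 1)")
    return s / ((1 - s) * (4 - s))


def g2_invert(g2: float) -> float:
    """Selfing rate in [0, 1) solving g2 = s/((1-s)(4-s)).

    Minus branch of  g2 s^2 - (5 g2 + 1) s + 4 g2 = 0; requires g2 >= 0.
    """
    if g2 < 0:
        raise ValueError("g2 must be >= 0 for inversion")
    if g2 == 0:
        return 0.0
    disc = (5 * g2 + 1) ** 2 - 16 * g2 ** 2
    # minus branch written in cancellation-free form (stable for g2 -> 0)
    return float(8 * g2 / ((5 * g2 + 1) + np.sqrt(disc)))


@dataclass
class G2Result:
    g2: float
    s_hat: float | None          # None when g2 < 0 (undetermined, RMES-style)
    n_pairs_used: int
    flags: list[str] = field(default_factory=list)


def g2_estimate(pop: GenotypeMatrix) -> G2Result:
    """Two-locus identity disequilibrium and the implied selfing rate.

    g2-hat = mean over locus pairs of (joint het rate) / (het_k * het_l) - 1,
    each pair computed on individuals non-missing at both loci; pairs
    where either locus shows no heterozygote are uninformative and
    skipped.
    """
    y = pop.het_mask()
    ok = ~pop.missing_mask()
    informative = [j for j in range(pop.n_loci) if y[:, j].any()]
    if len(informative) < 2:
        raise ValueError("g2 requires >= 2 loci with heterozygotes")
    ratios = []
    for k, l in itertools.combinations(range(pop.n_loci), 2):
        sub = ok[:, k] & ok[:, l]
        if not sub.any():
            continue
        pk = y[sub, k].mean()
        pl = y[sub, l].mean()
        if pk == 0 or pl == 0:
            continue
        pkl = (y[sub, k] & y[sub, l]).mean()
        ratios.append(pkl / (pk * pl))
    if not ratios:
        raise ValueError("no informative locus pair for g2")
    g2 = float(np.mean(ratios) - 1.0)
    flags = []
    if g2 < 0:
        flags.append("g2 < 0: s_g2 undetermined")
        s_hat = None
    else:
        s_hat = min(g2_invert(g2), 1.0)
    return G2Result(g2=g2, s_hat=s_hat, n_pairs_used=len(ratios), flags=flags)


# ---------------------------------------------------------------------------
# maximum-likelihood route (multilocus heterozygosity distribution)


@dataclass
class MlSelfingResult:
    s_hat: float
    h: pd.Series                 # per-locus outbred heterozygosity
    loglik: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def ml_selfing_loglik(s: float, h: np.ndarray, het: np.ndarray,
                      observed: np.ndarray, T: int = 30) -> float:
    """Log-likelihood of heterozygosity indicators under latent selfing age.

    L = prod_i sum_{t=0}^{T} (1-s) s^t prod_l [h_l 2^-t]^{y_il}
        [1 - h_l 2^-t]^{1-y_il},  missing loci dropped per individual.
    """
    h = np.asarray(h, dtype=float)
    t = np.arange(T + 1)
    if s == 0:
        log_w = np.full(T + 1, -np.inf)
        log_w[0] = 0.0
    else:
        log_w = np.log1p(-s) + t * np.log(s)
    with np.errstate(divide="ignore"):
        pw = h[None, :] * (2.0 ** -t)[:, None]            # (T+1, L)
        logA = np.log(pw)
        logB = np.log1p(-pw)
    yobs = (het & observed).astype(float)
    nobs = ((~het) & observed).astype(float)
    inner = yobs @ logA.T + nobs @ logB.T                 # (n, T+1)
    return float(np.sum(logsumexp(log_w[None, :] + inner, axis=1)))


def ml_selfing_fit(pop: GenotypeMatrix, T: int = 30) -> MlSelfingResult:
    """Maximise the multilocus-heterozygosity likelihood over (s, h_l)."""
    if pop.n_individuals < 2:
        raise ValueError("ml_selfing_fit requires >= 2 individuals")
    het = pop.het_mask()
    observed = ~pop.missing_mask()
    if not het.any():
        # all homozygous: s at the upper boundary, h unidentifiable
        L = pop.n_loci
        return MlSelfingResult(
            s_hat=1.0, h=pd.Series(np.zeros(L), index=pop.locus_ids, name="h"),
            loglik=0.0, converged=True, flags=["no heterozygote: s at upper boundary"],
        )
    L = pop.n_loci
    eps = 1e-6
    bounds = [(0.0, 1.0 - eps)] + [(eps, 1.0 - eps)] * L

    def neg(theta):
        val = -ml_selfing_loglik(theta[0], theta[1:], het, observed, T)
        return val if np.isfinite(val) else 1e12

    with np.errstate(invalid="ignore"):
        h0_base = np.clip(het.sum(axis=0) / np.maximum(observed.sum(axis=0), 1),
                          0.02, 0.98)
    best = None
    for s0 in (0.1, 0.5, 0.9):
        h0 = np.clip(h0_base / max(1.0 - s0 / 2.0, 0.5), 0.02, 1.0 - eps)
        res = minimize(neg, np.concatenate([[s0], h0]), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    s_hat = float(best.x[0])
    flags = []
    if s_hat >= 1.0 - 1e-5:
        flags.append("s at upper boundary")
    if s_hat <= 1e-8:
        flags.append("s at lower boundary")
    if not best.success:
        flags.append("optimiser reported non-convergence; best-found values")
    return MlSelfingResult(
        s_hat=s_hat,
        h=pd.Series(best.x[1:], index=pop.locus_ids, name="h"),
        loglik=-float(best.fun),
        converged=bool(best.success),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# conservative outcrossing classifier


@dataclass
class OutcrossingCall:
    embryo_id: str
    label: str                   # selfed | outcrossed | undetermined
    evidence_loci: list[str]

    def __post_init__(self) -> None:
        if self.label == "outcrossed" and not self.evidence_loci:
            raise ValueError("outcrossed call requires evidence loci")


def classify_seed(family: SeedFamily) -> list[OutcrossingCall]:
    """Maternal allele-exclusion classification of each embryo.

    Outcrossed iff, at some locus where both mother and embryo are
    genotyped, the embryo carries an allele absent from the maternal
    call.  With zero comparable loci the embryo is undetermined.  Never
    overestimates outcrossing on error-free genotypes.
    """
    mom = family.maternal.calls[0]                        # (L, 2)
    mom_missing = family.maternal.missing_mask()[0]
    calls = []
    for e in range(family.embryos.n_individuals):
        emb = family.embryos.calls[e]
        emb_missing = family.embryos.missing_mask()[e]
        comparable = ~(mom_missing | emb_missing)
        evidence = [
            family.embryos.locus_ids[j]
            for j in np.nonzero(comparable)[0]
            if not set(emb[j]).issubset(set(mom[j]))
        ]
        if not comparable.any():
            label = "undetermined"
        elif evidence:
            label = "outcrossed"
        else:
            label = "selfed"
        calls.append(OutcrossingCall(family.embryos.individual_ids[e], label,
                                     evidence))
    return calls


def plot_outcrossing_rate(plots: list[PlotSurvey]) -> pd.Series:
    """n_outcrossed / n_seeds per plot; zero-seed plots excluded and logged."""
    rates = {}
    for p in plots:
        if p.n_seeds == 0:
            logger.warning("plot %s has no seeds; excluded from outcrossing rate",
                           p.plot_id)
            continue
        rates[p.plot_id] = p.n_outcrossed / p.n_seeds
    return pd.Series(rates, name="outcrossing_rate")


def fit_outcrossing_glmm(plots: list[PlotSurvey]) -> GlmmResult:
    """Binomial-logit GLMM of plot outcrossing counts.

    Fixed effects: relative congener abundance, pollinator rate and
    their interaction; independent random intercepts for observation
    date and population.
    """
    usable = [p for p in plots if p.n_seeds > 0]
    if len(usable) < 2:
        raise ValueError("need >= 2 plots with seeds")
    rel = np.array([p.relative_abundance for p in usable])
    poll = np.array([p.pollinator_rate for p in usable])
    X = np.column_stack([np.ones(len(usable)), rel, poll, rel * poll])
    y = np.array([p.n_outcrossed for p in usable], dtype=float)
    m = np.array([p.n_seeds for p in usable], dtype=float)
    groups = {
        "date": np.array([p.date for p in usable]),
        "population": np.array([p.population_id for p in usable]),
    }
    return fit_binomial_glmm(
        X, y, m, groups,
        names=["intercept", "rel_abundance", "pollinator_rate", "interaction"],
    )


# ---------------------------------------------------------------------------
# per-population selfing estimate table


def selfing_estimates(pop_set: PopulationSet) -> pd.DataFrame:
    """SelfingEstimates table: S_F, g2 with S_g2, and S_ML per population."""
    from ripopgen.diversity import f_is

    rows = []
    for pid in pop_set.pop_ids:
        pop = pop_set[pid]
        flags: list[str] = []
        F = f_is(pop).f
        if np.isfinite(F) and -1 < F <= 1:
            s_f, fl = selfing_from_fis(F)
            flags += fl
        else:
            s_f = np.nan
            flags.append("F_IS undefined")
        try:
            g2res = g2_estimate(pop)
            g2, s_g2 = g2res.g2, g2res.s_hat
            flags += g2res.flags
        except ValueError as exc:
            g2, s_g2 = np.nan, None
            flags.append(str(exc))
        ml = ml_selfing_fit(pop)
        flags += ml.flags
        rows.append({
            "population": pid,
            "type": pop_set.metadata[pid].type,
            "F_IS": F,
            "S_F": s_f,
            "g2": g2,
            "S_g2": np.nan if s_g2 is None else s_g2,
            "S_ML": ml.s_hat,
            "ml_converged": ml.converged,
            "flags": "; ".join(flags),
        })
    return pd.DataFrame(rows).set_index("population")
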