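"""Forward simulators producing inputs with known truth.

A non-overlapping-generation, monoecious, partial-selfing Wright-Fisher
model with k-allele mutation and (optionally) island-model pollen
migration.  At mutation-drift equilibrium the inbreeding coefficient of
a population selfing at rate ``s`` converges to ``s / (2 - s)``, which
anchors the quantitative checks on every selfing estimator downstream.

All operations take an explicit seed and are deterministic given
(config, seed): integer allele arithmetic, one ``numpy`` Generator per
call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from ripopgen.genotype_io import (
    MISSING,
    GenotypeMatrix,
    PlotSurvey,
    PopulationMeta,
    PopulationSet,
    SeedFamily,
)


@dataclass
class SimulationConfig:
    """Parameters of the partial-selfing island-model simulator.

    ``s`` may be a single selfing rate or one per population.
    """

    n_pops: int = 1
    N: int = 100
    s: float | Sequence[float] = 0.0
    L: int = 10
    k: int = 8
    mu: float = 1e-3
    m: float = 0.0
    G: int = 50
    seed: int = 0
    sample_size: int = 30

    def selfing_rates(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.s, dtype=float), (self.n_pops,)).copy()
        if ((s < 0) | (s > 1)).any():
            raise ValueError("selfing rate(s) must lie in [0, 1]")
        return s

    def validate(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        s = self.selfing_rates()
        if self.N < 2 and np.any(s < 1):
            raise ValueError("N < 2 with s < 1: outcrossing impossible")
        if not (0 <= self.mu <= 1 and 0 <= self.m <= 1):
            raise ValueError("mu and m must lie in [0, 1]")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.L < 1 or self.k < 1:
            raise ValueError("L and k must be >= 1")
        if not (1 <= self.sample_size <= self.N):
            raise ValueError("sample_size must lie in [1, N]")


def _evolve(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Run the forward model; returns final allele array (n_pops, N, L, 2)."""
    cfg.validate()
    P, N, L = cfg.n_pops, cfg.N, cfg.L
    s = cfg.selfing_rates()
    pops = rng.integers(1, cfg.k + 1, size=(P, N, L, 2))
    for _ in range(cfg.G):
        nxt = np.empty_like(pops)
        for p in range(P):
            mothers = rng.integers(N, size=N)
            selfed = rng.random(N) < s[p]
            # outcross sire: distinct local parent, or a migrant's pollen
            fathers = rng.integers(N - 1, size=N)
            fathers += fathers >= mothers
            father_pop = np.full(N, p)
            if P > 1 and cfg.m > 0:
                mig = (~selfed) & (rng.random(N) < cfg.m)
                other = rng.integers(P - 1, size=N)
                other += other >= p
                father_pop[mig] = other[mig]
                fathers[mig] = rng.integers(N, size=N)[mig]
            fathers[selfed] = mothers[selfed]
            father_pop[selfed] = p
            cols = np.arange(L)[None, :]
            egg = pops[p][mothers[:, None], cols, rng.integers(2, size=(N, L))]
            sperm = pops[father_pop[:, None], fathers[:, None], cols,
                         rng.integers(2, size=(N, L))]
            child = np.stack([egg, sperm], axis=-1)
            if cfg.mu > 0:
                hit = rng.random(child.shape) < cfg.mu
                child[hit] = rng.integers(1, cfg.k + 1, size=int(hit.sum()))
            nxt[p] = child
        pops = nxt
    return pops


def _sample_matrix(alleles: np.ndarray, cfg: SimulationConfig, pop_label: str,
                   rng: np.random.Generator) -> GenotypeMatrix:
    idx = rng.choice(cfg.N, size=cfg.sample_size, replace=False)
    ids = [f"{pop_label}_i{j}" for j in range(cfg.sample_size)]
    loci = [f"L{j + 1}" for j in range(cfg.L)]
    return GenotypeMatrix(ids, loci, alleles[idx])


def simulate_mixed_mating_population(cfg: SimulationConfig) -> GenotypeMatrix:
    """Single partial-selfing population; returns a final-generation sample."""
    if cfg.n_pops != 1:
        raise ValueError("simulate_mixed_mating_population requires n_pops=1")
    rng = np.random.default_rng(cfg.seed)
    pops = _evolve(cfg, rng)
    return _sample_matrix(pops[0], cfg, "pop1", rng)


def simulate_island_metapopulation(cfg: SimulationConfig) -> PopulationSet:
    """Island-model metapopulation with synthetic coordinates and labels.

    Populations alternate sympatric/allopatric labels (inert to the
    simulation itself) and receive uniform coordinates in a 50x50 km
    square.
    """
    if cfg.n_pops < 2:
        raise ValueError("simulate_island_metapopulation requires n_pops >= 2")
    rng = np.random.default_rng(cfg.seed)
    pops = _evolve(cfg, rng)
    coords = rng.uniform(0.0, 50.0, size=(cfg.n_pops, 2))
    out: dict[str, GenotypeMatrix] = {}
    meta: dict[str, PopulationMeta] = {}
    for p in range(cfg.n_pops):
        label = "sympatric" if p % 2 == 0 else "allopatric"
        pid = f"{'S' if label == 'sympatric' else 'A'}{p + 1:02d}"
        out[pid] = _sample_matrix(pops[p], cfg, pid, rng)
        meta[pid] = PopulationMeta(type=label, x_km=float(coords[p, 0]),
                                   y_km=float(coords[p, 1]))
    return PopulationSet(out, meta)


def simulate_seed_families(
    mothers: GenotypeMatrix,
    s: float,
    pollen_pool: GenotypeMatrix,
    seeds_per_mother: int,
    seed: int,
    plot_id: str = "plot1",
    population_id: str = "pop1",
) -> list[SeedFamily]:
    """Mother-offspring families with known selfed/outcrossed labels.

    Each embryo is selfed with probability ``s`` (both gametes drawn from
    the mother) or sired by a random pollen-pool member.  A missing call
    in the contributing parent yields a missing embryo call.
    """
    if mothers.locus_ids != pollen_pool.locus_ids:
        raise ValueError("mothers and pollen pool must share loci")
    if not 0 <= s <= 1:
        raise ValueError("s must lie in [0, 1]")
    if pollen_pool.n_individuals == 0 and s < 1:
        raise ValueError("empty pollen pool with s < 1")
    rng = np.random.default_rng(seed)
    L = mothers.n_loci
    loci = mothers.locus_ids
    families = []
    for i, mid in enumerate(mothers.individual_ids):
        mrow = mothers.calls[i]
        n = seeds_per_mother
        selfed = rng.random(n) < s
        sires = rng.integers(max(pollen_pool.n_individuals, 1), size=n)
        cols = np.arange(L)[None, :]
        egg = mrow[cols, rng.integers(2, size=(n, L))]
        self_sperm = mrow[cols, rng.integers(2, size=(n, L))]
        pool_sperm = pollen_pool.calls[sires[:, None], cols,
                                       rng.integers(2, size=(n, L))] \
            if pollen_pool.n_individuals else np.zeros((n, L), dtype=np.int64)
        sperm = np.where(selfed[:, None], self_sperm, pool_sperm)
        calls = np.stack([egg, sperm], axis=-1)
        # a missing parental call gives an undetermined (missing) embryo call
        bad = (calls == MISSING).any(axis=-1)
        calls[bad] = MISSING
        labels = ["selfed" if x else "outcrossed" for x in selfed]
        embryos = GenotypeMatrix(
            [f"{mid}_e{j}" for j in range(n)], loci, calls
        )
        families.append(SeedFamily(plot_id, population_id, mothers.row(i),
                                   embryos, labels))
    return families


def simulate_plot_survey(
    beta0: float,
    beta_rel: float,
    beta_poll: float,
    beta_int: float,
    sd_date: float,
    sd_pop: float,
    n_plots: int,
    seeds_per_plot: int,
    seed: int,
    n_dates: int = 6,
    n_pops: int = 5,
) -> list[PlotSurvey]:
    """Plot survey tables from a binomial-logit mixed model with known betas.

    logit p = beta0 + beta_rel * rel + beta_poll * poll + beta_int * rel * poll
              + u[date] + v[population],
    u ~ N(0, sd_date^2), v ~ N(0, sd_pop^2) independent.
    """
    for name, v in [("beta0", beta0), ("beta_rel", beta_rel),
                    ("beta_poll", beta_poll), ("beta_int", beta_int)]:
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if n_plots < 2:
        raise ValueError("n_plots must be >= 2")
    if sd_date < 0 or sd_pop < 0:
        raise ValueError("random-effect sds must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sd_date, size=n_dates)
    v = rng.normal(0.0, sd_pop, size=n_pops)
    plots = []
    for i in range(n_plots):
        d, p = i % n_dates, (i // n_dates) % n_pops
        poll = rng.uniform(0.0, 2.0)
        total = int(rng.integers(20, 101))
        congener = int(round(rng.uniform() * total))
        rel = congener / total
        eta = (beta0 + beta_rel * rel + beta_poll * poll
               + beta_int * rel * poll + u[d] + v[p])
        n_out = int(rng.binomial(seeds_per_plot, expit(eta)))
        plots.append(PlotSurvey(
            plot_id=f"plot{i + 1}",
            population_id=f"pop{p + 1}",
            date=f"2017-09-{d + 4:02d}",
            focal_flowers=total - congener,
            congener_flowers=congener,
            pollinator_rate=float(poll),
            n_seeds=seeds_per_plot,
            n_outcrossed=n_out,
        ))
    return plots
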