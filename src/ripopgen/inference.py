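"""Bootstrap comparison of per-population indices between groups.

The resampling unit is the population-level index value: each group is
resampled with replacement at its own size, the statistic is
mean(sympatric) - mean(allopatric), and the one-sided p-value counts
resampled statistics that oppose the stated alternative, with a +1
correction so p never reaches 0.  A companion routine estimates power
at alternative sample sizes by resampling the observed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ripopgen")

ALTERNATIVES = ("sym_greater", "sym_less", "two_sided")

#: Directional alternatives for the standard index set: selfing/inbreeding
#: expected higher in sympatry, diversity and effective size lower.
DEFAULT_ALTERNATIVES = {
    "AR": "sym_less",
    "H_E": "sym_less",
    "F_IS": "sym_greater",
    "S_F": "sym_greater",
    "S_g2": "sym_greater",
    "S_RMES": "sym_greater",
    "S_ML": "sym_greater",
    "S_SIB": "sym_greater",
    "Ne_LD": "sym_less",
    "Ne_Cn": "sym_less",
    "Ne_SIB": "sym_less",
}


@dataclass
class GroupComparison:
    index_name: str
    values_sympatric: np.ndarray
    values_allopatric: np.ndarray
    alternative: str = "sym_greater"
    B: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.values_sympatric = np.asarray(self.values_sympatric, dtype=float)
        self.values_allopatric = np.asarray(self.values_allopatric, dtype=float)
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"alternative must be one of {ALTERNATIVES}")
        if self.B < 1000:
            raise ValueError("B must be >= 1000")
        if min(self.values_sympatric.size, self.values_allopatric.size) < 2:
            raise ValueError("each group needs >= 2 values")
        if np.isnan(self.values_sympatric).any() or np.isnan(self.values_allopatric).any():
            raise ValueError("drop NaN values before constructing a GroupComparison")


@dataclass
class BootstrapTestResult:
    index_name: str
    observed_diff: float
    p: float
    alternative: str
    B: int
    boot_mean: float
    boot_sd: float
    flags: list[str] = field(default_factory=list)


def bootstrap_group_test(gc: GroupComparison) -> BootstrapTestResult:
    """Bootstrap p-value for a sympatric-vs-allopatric mean difference."""
    rng = np.random.default_rng(gc.seed)
    sym, allo = gc.values_sympatric, gc.values_allopatric
    observed = float(sym.mean() - allo.mean())
    boot_sym = rng.choice(sym, size=(gc.B, sym.size), replace=True).mean(axis=1)
    boot_allo = rng.choice(allo, size=(gc.B, allo.size), replace=True).mean(axis=1)
    stat = boot_sym - boot_allo
    flags: list[str] = []
    if gc.alternative == "sym_greater":
        count = int((stat <= 0).sum())
    elif gc.alternative == "sym_less":
        count = int((stat >= 0).sum())
    else:  # two-sided: double the smaller tail, capped at 1
        c_low = int((stat <= 0).sum())
        c_high = int((stat >= 0).sum())
        p = min(2 * (1 + min(c_low, c_high)) / (1 + gc.B), 1.0)
        return BootstrapTestResult(gc.index_name, observed, p, gc.alternative,
                                   gc.B, float(stat.mean()), float(stat.std(ddof=1)),
                                   flags)
    if observed == 0 and np.all(stat == 0):
        flags.append("degenerate: identical groups, p = 1 by convention")
    p = (1 + count) / (1 + gc.B)
    return BootstrapTestResult(gc.index_name, observed, p, gc.alternative, gc.B,
                               float(stat.mean()), float(stat.std(ddof=1)), flags)


def bootstrap_power(
    values_sym: np.ndarray,
    values_allo: np.ndarray,
    n_grid: list[int],
    alpha: float = 0.05,
    B: int = 1000,
    n_datasets: int = 200,
    seed: int = 0,
    alternative: str = "sym_greater",
) -> pd.Series:
    """Power per sample size: resample ``n`` values per group from the
    observed values and record the fraction of datasets with p < alpha."""
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    values_sym = np.asarray(values_sym, dtype=float)
    values_allo = np.asarray(values_allo, dtype=float)
    rng = np.random.default_rng(seed)
    power = {}
    for n in n_grid:
        if n > max(values_sym.size, values_allo.size):
            logger.info("power grid n=%d exceeds observed group sizes "
                        "(resampling with replacement)", n)
        hits = 0
        for _ in range(n_datasets):
            gc = GroupComparison(
                "power", rng.choice(values_sym, size=n, replace=True),
                rng.choice(values_allo, size=n, replace=True),
                alternative=alternative, B=B,
                seed=int(rng.integers(2 ** 31)),
            )
            if bootstrap_group_test(gc).p < alpha:
                hits += 1
        power[n] = hits / n_datasets
    return pd.Series(power, name="power")


def read_external_index_csv(path) -> pd.DataFrame:
    """Import adapter for externally produced per-population summaries
    (e.g. sibship-based selfing rates or Ne), keyed by population."""
    df = pd.read_csv(path)
    if "population" not in df.columns:
        raise ValueError("external index CSV must have a 'population' column")
    return df.set_index("population")


def run_group_comparisons(
    index_table: pd.DataFrame,
    ne_table: pd.DataFrame | None = None,
    selfing_table: pd.DataFrame | None = None,
    external_tables: list[pd.DataFrame] | None = None,
    B: int = 10_000,
    seed: int = 0,
    alternatives: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One bootstrap comparison per available index.

    Tables are merged on their population index; ``type`` must label
    every population.  Non-finite values (undefined estimates, infinite
    Ne) are dropped per index with the dropped count reported.
    """
    merged = index_table.copy()
    for extra in [ne_table, selfing_table, *(external_tables or [])]:
        if extra is None:
            continue
        cols = [c for c in extra.columns if c not in merged.columns]
        merged = merged.join(extra[cols], how="outer")
    if "type" not in merged.columns or merged["type"].isna().any():
        raise ValueError("every population needs a type label")
    sym_mask = merged["type"] == "sympatric"
    allo_mask = merged["type"] == "allopatric"
    if not sym_mask.any() or not allo_mask.any():
        raise ValueError("one group is empty: need both sympatric and allopatric "
                         "populations")
    alts = dict(DEFAULT_ALTERNATIVES)
    if alternatives:
        alts.update(alternatives)
    rows = []
    rng = np.random.default_rng(seed)
    for name, alternative in alts.items():
        if name not in merged.columns:
            logger.warning("index %s absent; skipped", name)
            continue
        col = pd.to_numeric(merged[name], errors="coerce")
        finite = np.isfinite(col)
        dropped = int((~finite).sum())
        sym = col[sym_mask & finite].to_numpy()
        allo = col[allo_mask & finite].to_numpy()
        if min(sym.size, allo.size) < 2:
            logger.warning("index %s: fewer than 2 finite values in a group; skipped",
                           name)
            continue
        res = bootstrap_group_test(GroupComparison(
            name, sym, allo, alternative=alternative, B=B,
            seed=int(rng.integers(2 ** 31)),
        ))
        rows.append({
            "index": name,
            "alternative": alternative,
            "n_sym": sym.size,
            "n_allo": allo.size,
            "n_dropped": dropped,
            "mean_sym": float(sym.mean()),
            "mean_allo": float(allo.mean()),
            "observed_diff": res.observed_diff,
            "p": res.p,
        })
    return pd.DataFrame(rows).set_index("index")
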