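"""Diploid multilocus genotype containers and text-format readers/writers.

Genotypes are unordered pairs of positive-integer allele identifiers;
``(a, b)`` and ``(b, a)`` are the same call and are canonicalised to
``(min, max)`` on construction.  A fully missing call is stored as
``(0, 0)``; half-missing input is coerced to missing with a logged
warning (no estimator downstream can use half a call).

Supported dialects: GenAlEx codominant CSV (missing code 0), STRUCTURE
one- or two-row text (missing code -9) and a tidy long CSV that also
carries population metadata.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("ripopgen")

#: Sentinel allele value for a missing call; a missing call is (0, 0).
MISSING = 0

VALID_POP_TYPES = ("sympatric", "allopatric")


class GenotypeIOError(ValueError):
    """Raised on malformed genotype input."""


def _canonicalise(calls: np.ndarray) -> np.ndarray:
    """Sort each allele pair ascending so (a,b) == (b,a)."""
    return np.sort(calls, axis=-1)


class GenotypeMatrix:
    """Individuals x loci diploid allele calls.

    Parameters
    ----------
    individual_ids : sequence of unique labels
    locus_ids : sequence of unique labels
    calls : int array, shape (n_individuals, n_loci, 2)
        Positive allele identifiers; (0, 0) marks a missing call.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.individual_ids = [str(i) for i in individual_ids]
        self.locus_ids = [str(l) for l in locus_ids]
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individual_ids), len(self.locus_ids), 2):
            raise GenotypeIOError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise GenotypeIOError("duplicate individual ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise GenotypeIOError("duplicate locus ids")
        calls = _canonicalise(calls)
        half = (calls[:, :, 0] == MISSING) & (calls[:, :, 1] != MISSING)
        if half.any():
            raise GenotypeIOError(
                "half-missing calls must be coerced to MISSING before construction"
            )
        if (calls < 0).any():
            raise GenotypeIOError("allele identifiers must be positive integers")
        self.calls = calls
        if self.n_individuals and self.n_loci:
            all_missing = self.missing_mask().all(axis=1)
            if all_missing.any():
                bad = [self.individual_ids[i] for i in np.nonzero(all_missing)[0]]
                raise GenotypeIOError(
                    f"individuals with no genotyped locus: {bad}"
                )

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def het_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is a heterozygote.

        Missing calls are False; use :meth:`missing_mask` to separate them.
        """
        return (~self.missing_mask()) & (self.calls[:, :, 0] != self.calls[:, :, 1])

    def row(self, index: int) -> "GenotypeMatrix":
        """Single-individual view (copy) preserving locus ids."""
        return GenotypeMatrix(
            [self.individual_ids[index]], self.locus_ids, self.calls[index : index + 1]
        )

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return GenotypeMatrix(self.individual_ids, list(locus_ids), self.calls[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, {self.n_loci} loci)"
        )


@dataclass
class PopulationMeta:
    """Per-population metadata: sympatric/allopatric label and planar km coordinates."""

    type: str | None = None
    x_km: float | None = None
    y_km: float | None = None
    sample_year: int | None = None

    def __post_init__(self) -> None:
        if self.type is not None and self.type not in VALID_POP_TYPES:
            raise GenotypeIOError(
                f"population type must be one of {VALID_POP_TYPES}, got {self.type!r}"
            )


class PopulationSet:
    """Ordered mapping of population id -> GenotypeMatrix plus metadata.

    All member populations must share an identical, identically ordered
    locus list.
    """

    def __init__(
        self,
        populations: dict[str, GenotypeMatrix],
        metadata: dict[str, PopulationMeta] | None = None,
    ) -> None:
        self.populations = dict(populations)
        if not all(isinstance(p, GenotypeMatrix) for p in self.populations.values()):
            raise GenotypeIOError("populations must map to GenotypeMatrix")
        loci = None
        for pid, pop in self.populations.items():
            if loci is None:
                loci = pop.locus_ids
            elif pop.locus_ids != loci:
                raise GenotypeIOError(
                    f"population {pid!r} has locus ids {pop.locus_ids}, expected {loci}"
                )
        self.metadata = {pid: PopulationMeta() for pid in self.populations}
        if metadata:
            for pid, meta in metadata.items():
                if pid not in self.populations:
                    raise GenotypeIOError(f"metadata for unknown population {pid!r}")
                self.metadata[pid] = meta

    @property
    def pop_ids(self) -> list[str]:
        return list(self.populations)

    @property
    def locus_ids(self) -> list[str]:
        if not self.populations:
            return []
        return next(iter(self.populations.values())).locus_ids

    def __len__(self) -> int:
        return len(self.populations)

    def __getitem__(self, pid: str) -> GenotypeMatrix:
        return self.populations[pid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationSet):
            return NotImplemented
        return (
            self.pop_ids == other.pop_ids
            and all(self.populations[p] == other.populations[p] for p in self.pop_ids)
            and self.metadata == other.metadata
        )

    def require_types(self) -> None:
        """Raise unless every population carries a sympatric/allopatric label."""
        missing = [p for p, m in self.metadata.items() if m.type is None]
        if missing:
            raise GenotypeIOError(f"populations without type label: {missing}")

    def ids_of_type(self, pop_type: str) -> list[str]:
        return [p for p, m in self.metadata.items() if m.type == pop_type]


@dataclass
class SeedFamily:
    """A maternal plant with its genotyped seed embryos and plot context."""

    plot_id: str
    population_id: str
    maternal: GenotypeMatrix
    embryos: GenotypeMatrix
    true_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.maternal.n_individuals != 1:
            raise GenotypeIOError("maternal must be a single-individual matrix")
        if self.maternal.locus_ids != self.embryos.locus_ids:
            raise GenotypeIOError("maternal and embryos must share locus ids")
        if self.true_labels is not None and len(self.true_labels) != self.embryos.n_individuals:
            raise GenotypeIOError("true_labels length must match embryo count")


@dataclass
class PlotSurvey:
    """Per-plot flower counts, pollinator visitation and seed outcrossing tallies."""

    plot_id: str
    population_id: str
    date: str
    focal_flowers: int
    congener_flowers: int
    pollinator_rate: float
    n_seeds: int
    n_outcrossed: int

    def __post_init__(self) -> None:
        if self.pollinator_rate < 0:
            raise GenotypeIOError("pollinator_rate must be >= 0")
        if self.n_outcrossed > self.n_seeds:
            raise GenotypeIOError("n_outcrossed cannot exceed n_seeds")
        if min(self.focal_flowers, self.congener_flowers, self.n_seeds, self.n_outcrossed) < 0:
            raise GenotypeIOError("counts must be non-negative")

    @property
    def relative_abundance(self) -> float:
        """Congener flowers / all flowers; undefined when both counts are zero."""
        total = self.focal_flowers + self.congener_flowers
        if total == 0:
            raise GenotypeIOError(
                f"plot {self.plot_id}: relative abundance undefined with zero flowers"
            )
        return self.congener_flowers / total


# ---------------------------------------------------------------------------
# shared parsing helpers


def _coerce_pair(a: int, b: int, missing_code: int, where: str) -> tuple[int, int]:
    """Map a raw allele pair to internal storage, coercing half-missing to MISSING."""
    am, bm = a == missing_code, b == missing_code
    if am and bm:
        return (MISSING, MISSING)
    if am or bm:
        logger.warning("half-missing call at %s coerced to MISSING", where)
        return (MISSING, MISSING)
    if a <= 0 or b <= 0:
        raise GenotypeIOError(f"non-positive allele identifier at {where}: ({a}, {b})")
    return (a, b)


def _build_population_set(
    rows: list[tuple[str, str, list[tuple[int, int]]]],
    locus_ids: list[str],
    metadata: dict[str, PopulationMeta] | None = None,
) -> PopulationSet:
    """Assemble (individual, population, calls) rows into a PopulationSet."""
    by_pop: dict[str, list[tuple[str, list[tuple[int, int]]]]] = {}
    for ind, pop, calls in rows:
        by_pop.setdefault(pop, []).append((ind, calls))
    pops: dict[str, GenotypeMatrix] = {}
    for pop, members in by_pop.items():
        ids = [m[0] for m in members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeIOError(f"duplicate individual id(s) in {pop!r}: {dupes}")
        arr = np.array([m[1] for m in members], dtype=np.int64)
        pops[pop] = GenotypeMatrix(ids, locus_ids, arr)
    ps = PopulationSet(pops, metadata)
    logger.info(
        "read %d individuals in %d populations (%d loci)",
        sum(p.n_individuals for p in pops.values()), len(pops), len(locus_ids),
    )
    return ps


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV


def write_genalex(ps: PopulationSet, path, title: str = "ripopgen export") -> None:
    """Write a codominant two-columns-per-locus GenAlEx CSV (missing code 0)."""
    loci = ps.locus_ids
    sizes = [ps[p].n_individuals for p in ps.pop_ids]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([len(loci), sum(sizes), len(ps.pop_ids), *sizes])
        w.writerow([title, "", "", *ps.pop_ids])
        header = ["Ind", "Pop"]
        for l in loci:
            header += [l, ""]
        w.writerow(header)
        for pid in ps.pop_ids:
            pop = ps[pid]
            for i, ind in enumerate(pop.individual_ids):
                row = [ind, pid]
                for j in range(pop.n_loci):
                    row += [int(pop.calls[i, j, 0]), int(pop.calls[i, j, 1])]
                w.writerow(row)


def read_genalex(path) -> PopulationSet:
    """Read a codominant GenAlEx CSV; allele code 0 is missing."""
    with open(path, newline="") as fh:
        raw = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if len(raw) < 3:
        raise GenotypeIOError("GenAlEx file must have two header rows and a column row")
    try:
        n_loci = int(raw[0][0])
        n_samples = int(raw[0][1])
        n_pops = int(raw[0][2])
    except (ValueError, IndexError) as exc:
        raise GenotypeIOError(f"malformed GenAlEx header row: {raw[0]!r}") from exc
    colrow = raw[2]
    allele_cols = [c for c in colrow[2:] if True]
    if len(allele_cols) < 2 * n_loci:
        raise GenotypeIOError(
            f"expected {2 * n_loci} allele columns, found {len(allele_cols)}"
        )
    locus_ids = [colrow[2 + 2 * j].strip() for j in range(n_loci)]
    if any(not l for l in locus_ids):
        raise GenotypeIOError("empty locus name in GenAlEx column header")
    rows = []
    for lineno, r in enumerate(raw[3:], start=4):
        if len(r) < 2 + 2 * n_loci:
            raise GenotypeIOError(f"line {lineno}: too few columns")
        ind, pop = r[0].strip(), r[1].strip()
        calls = []
        for j in range(n_loci):
            try:
                a = int(r[2 + 2 * j] or 0)
                b = int(r[3 + 2 * j] or 0)
            except ValueError as exc:
                raise GenotypeIOError(
                    f"line {lineno}, locus {locus_ids[j]}: non-integer allele"
                ) from exc
            calls.append(_coerce_pair(a, b, 0, f"line {lineno} locus {locus_ids[j]}"))
        rows.append((ind, pop, calls))
    if len(rows) != n_samples:
        logger.warning(
            "GenAlEx header declares %d samples but %d rows read", n_samples, len(rows)
        )
    ps = _build_population_set(rows, locus_ids)
    if len(ps) != n_pops:
        logger.warning(
            "GenAlEx header declares %d populations but %d found", n_pops, len(ps)
        )
    return ps


# ---------------------------------------------------------------------------
# STRUCTURE text


def write_structure(ps: PopulationSet, path, rows_per_individual: int = 2,
                    missing_code: int = -9) -> None:
    """Write STRUCTURE-format text with a locus-name header line."""
    if rows_per_individual not in (1, 2):
        raise GenotypeIOError("rows_per_individual must be 1 or 2")
    pop_index = {p: i + 1 for i, p in enumerate(ps.pop_ids)}
    with open(path, "w") as fh:
        fh.write("\t".join(ps.locus_ids) + "\n")
        for pid in ps.pop_ids:
            pop = ps[pid]
            calls = pop.calls.copy()
            calls[calls == MISSING] = missing_code
            for i, ind in enumerate(pop.individual_ids):
                if rows_per_individual == 2:
                    for k in (0, 1):
                        vals = "\t".join(str(int(v)) for v in calls[i, :, k])
                        fh.write(f"{ind}\t{pop_index[pid]}\t{vals}\n")
                else:
                    vals = "\t".join(
                        f"{int(calls[i, j, 0])}\t{int(calls[i, j, 1])}"
                        for j in range(pop.n_loci)
                    )
                    fh.write(f"{ind}\t{pop_index[pid]}\t{vals}\n")


def read_structure(path, rows_per_individual: int = 2, missing_code: int = -9,
                   has_header: bool = True) -> PopulationSet:
    """Read STRUCTURE one-row or two-row text (default missing code -9).

    Population column values become population ids (``pop<k>`` labels).
    """
    if rows_per_individual not in (1, 2):
        raise GenotypeIOError("rows_per_individual must be 1 or 2")
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeIOError("empty STRUCTURE file")
    locus_ids: list[str] | None = None
    if has_header:
        locus_ids = lines[0]
        lines = lines[1:]
    if rows_per_individual == 2 and len(lines) % 2 != 0:
        raise GenotypeIOError(
            f"two-row layout declared but {len(lines)} data lines (odd count)"
        )
    rows = []
    if rows_per_individual == 2:
        for i in range(0, len(lines), 2):
            r1, r2 = lines[i], lines[i + 1]
            if r1[0] != r2[0] or len(r1) != len(r2):
                raise GenotypeIOError(
                    f"rows {i + 1}/{i + 2}: paired rows disagree on id or length"
                )
            n_loci = len(r1) - 2
            if locus_ids is None:
                locus_ids = [f"L{j + 1}" for j in range(n_loci)]
            if n_loci != len(locus_ids):
                raise GenotypeIOError(f"row {i + 1}: expected {len(locus_ids)} loci")
            calls = [
                _coerce_pair(int(r1[2 + j]), int(r2[2 + j]), missing_code,
                             f"individual {r1[0]} locus {locus_ids[j]}")
                for j in range(n_loci)
            ]
            rows.append((r1[0], f"pop{r1[1]}", calls))
    else:
        for i, r in enumerate(lines):
            n_loci = (len(r) - 2) // 2
            if len(r) != 2 + 2 * n_loci:
                raise GenotypeIOError(f"row {i + 1}: odd allele column count")
            if locus_ids is None:
                locus_ids = [f"L{j + 1}" for j in range(n_loci)]
            if n_loci != len(locus_ids):
                raise GenotypeIOError(f"row {i + 1}: expected {len(locus_ids)} loci")
            calls = [
                _coerce_pair(int(r[2 + 2 * j]), int(r[3 + 2 * j]), missing_code,
                             f"individual {r[0]} locus {locus_ids[j]}")
                for j in range(n_loci)
            ]
            rows.append((r[0], f"pop{r[1]}", calls))
    assert locus_ids is not None
    return _build_population_set(rows, locus_ids)


# ---------------------------------------------------------------------------
# long (tidy) CSV — the only dialect that carries metadata

_LONG_HEADER = [
    "population", "pop_type", "x_km", "y_km", "sample_year",
    "individual", "locus", "allele1", "allele2",
]


def _fmt_opt(v) -> str:
    return "" if v is None else repr(v) if isinstance(v, float) else str(v)


def write_long_csv(ps: PopulationSet, path) -> None:
    """Write one row per (population, individual, locus); empty cells mean missing."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LONG_HEADER)
        for pid in ps.pop_ids:
            pop, meta = ps[pid], ps.metadata[pid]
            for i, ind in enumerate(pop.individual_ids):
                for j, locus in enumerate(pop.locus_ids):
                    a, b = (int(v) for v in pop.calls[i, j])
                    w.writerow([
                        pid, meta.type or "", _fmt_opt(meta.x_km), _fmt_opt(meta.y_km),
                        _fmt_opt(meta.sample_year), ind, locus,
                        "" if a == MISSING else a, "" if b == MISSING else b,
                    ])


def read_long_csv(path) -> PopulationSet:
    """Read the tidy dialect written by :func:`write_long_csv`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _LONG_HEADER:
            raise GenotypeIOError(f"unexpected long-CSV header: {header}")
        raw = [r for r in reader if any(c.strip() for c in r)]
    # preserve order of first appearance for pops, individuals and loci
    locus_ids: list[str] = []
    metadata: dict[str, PopulationMeta] = {}
    per_ind: dict[tuple[str, str], dict[str, tuple[int, int]]] = {}
    for lineno, r in enumerate(raw, start=2):
        pid, ptype, x, y, year, ind, locus, a1, a2 = (c.strip() for c in r)
        if locus not in locus_ids:
            locus_ids.append(locus)
        if pid not in metadata:
            metadata[pid] = PopulationMeta(
                type=ptype or None,
                x_km=float(x) if x else None,
                y_km=float(y) if y else None,
                sample_year=int(year) if year else None,
            )
        if a1 == "" and a2 == "":
            pair = (MISSING, MISSING)
        elif a1 == "" or a2 == "":
            logger.warning("half-missing call at line %d coerced to MISSING", lineno)
            pair = (MISSING, MISSING)
        else:
            pair = _coerce_pair(int(a1), int(a2), MISSING, f"line {lineno}")
        per_ind.setdefault((pid, ind), {})[locus] = pair
    rows = []
    for (pid, ind), by_locus in per_ind.items():
        calls = [by_locus.get(l, (MISSING, MISSING)) for l in locus_ids]
        rows.append((ind, pid, calls))
    return _build_population_set(rows, locus_ids, metadata)


# ---------------------------------------------------------------------------
# seed-family and plot-survey CSVs (inputs to the outcrossing classifier/GLMM)


def write_seed_families_csv(families: Iterable[SeedFamily], path) -> None:
    """Long CSV: one row per (family member, locus)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "population_id", "family", "role", "individual",
                    "locus", "allele1", "allele2", "true_label"])
        for fam_idx, fam in enumerate(families):
            members = [("mother", fam.maternal, None)]
            for e in range(fam.embryos.n_individuals):
                label = fam.true_labels[e] if fam.true_labels else None
                members.append((f"embryo", fam.embryos.row(e), (e, label)))
            for role, gm, extra in members:
                ind = gm.individual_ids[0]
                label = extra[1] if extra else None
                for j, locus in enumerate(gm.locus_ids):
                    a, b = (int(v) for v in gm.calls[0, j])
                    w.writerow([
                        fam.plot_id, fam.population_id, fam_idx, role, ind, locus,
                        "" if a == MISSING else a, "" if b == MISSING else b,
                        label or "",
                    ])


def read_seed_families_csv(path) -> list[SeedFamily]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        raw = [r for r in reader if any(c.strip() for c in r)]
    loci: list[str] = []
    fams: dict[str, dict] = {}
    for r in raw:
        plot, popid, fam, role, ind, locus, a1, a2, label = (c.strip() for c in r)
        if locus not in loci:
            loci.append(locus)
        entry = fams.setdefault(fam, {"plot": plot, "pop": popid, "mother": {},
                                      "embryos": {}, "labels": {}})
        pair = (
            (MISSING, MISSING) if a1 == "" or a2 == ""
            else _coerce_pair(int(a1), int(a2), MISSING, f"family {fam} {ind}")
        )
        if role == "mother":
            entry["mother"].setdefault(ind, {})[locus] = pair
        else:
            entry["embryos"].setdefault(ind, {})[locus] = pair
            if label:
                entry["labels"][ind] = label
    out = []
    for fam, entry in fams.items():
        (mid, mcalls), = entry["mother"].items()
        maternal = GenotypeMatrix(
            [mid], loci,
            np.array([[mcalls.get(l, (MISSING, MISSING)) for l in loci]]),
        )
        eids = list(entry["embryos"])
        ecalls = np.array(
            [[entry["embryos"][e].get(l, (MISSING, MISSING)) for l in loci] for e in eids]
        )
        labels = [entry["labels"][e] for e in eids] if entry["labels"] else None
        out.append(SeedFamily(entry["plot"], entry["pop"],
                              maternal, GenotypeMatrix(eids, loci, ecalls), labels))
    return out


PLOT_HEADER = ["plot_id", "population_id", "date", "focal_flowers",
               "congener_flowers", "pollinator_rate", "n_seeds", "n_outcrossed"]


def write_plot_surveys_csv(plots: Iterable[PlotSurvey], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PLOT_HEADER)
        for p in plots:
            w.writerow([p.plot_id, p.population_id, p.date, p.focal_flowers,
                        p.congener_flowers, repr(p.pollinator_rate), p.n_seeds,
                        p.n_outcrossed])


def read_plot_surveys_csv(path) -> list[PlotSurvey]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != PLOT_HEADER:
            raise GenotypeIOError(f"unexpected plot-survey header: {header}")
        return [
            PlotSurvey(r[0], r[1], r[2], int(r[3]), int(r[4]), float(r[5]),
                       int(r[6]), int(r[7]))
            for r in reader if any(c.strip() for c in r)
        ]


# ---------------------------------------------------------------------------
# coordinate projection utility (documented pre-processing, not analysis)


def project_lonlat_km(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of lon/lat degrees to planar km.

    Reference latitude is the mean latitude; adequate at the tens-of-km
    extent this toolkit targets.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    r_earth = 6371.0
    lat0 = np.deg2rad(lat.mean())
    x = np.deg2rad(lon) * r_earth * np.cos(lat0)
    y = np.deg2rad(lat) * r_earth
    return x, y
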