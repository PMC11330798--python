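"""Pedigree ingestion, validation, subgroups, and generation statistics.

A :class:`Pedigree` is a topologically sorted table of animals (parents
always precede offspring) with integer parent indices, so downstream
recursions (inbreeding, gene origin, gene dropping) are simple forward or
backward passes over arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # sentinel used in input files for an unknown parent

_PEDIGREE_COLUMNS = ["animal", "sire", "dam", "birth_year", "flock", "sex"]


class PedigreeError(ValueError):
    """Raised on structurally invalid pedigrees (cycles, sex conflicts, duplicates)."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str | None
    dam_id: str | None
    birth_year: int | None
    flock_id: str | None
    sex: str  # "male", "female", or "unknown"


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``animal, sire, dam, birth_year, flock, sex`` in topological
        order; missing parents/metadata are ``None``/``NaN``.
    sire_idx, dam_idx : numpy.ndarray of int
        Positional parent indices, ``-1`` for a missing parent.
    """

    df: pd.DataFrame
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.df["animal"])}
        n = len(self.df)
        for name, par in (("sire", self.sire_idx), ("dam", self.dam_idx)):
            bad = (par >= np.arange(n)) & (par >= 0)
            if bad.any():
                raise PedigreeError(
                    f"pedigree not topologically sorted: {name} of "
                    f"{self.df['animal'].iloc[int(np.argmax(bad))]!r} does not precede it"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy()

    @property
    def birth_year(self) -> np.ndarray:
        return self.df["birth_year"].to_numpy(dtype=float)

    @property
    def flock(self) -> np.ndarray:
        return self.df["flock"].to_numpy()

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def positions(self, ids: Iterable) -> np.ndarray:
        return np.asarray([self.index[a] for a in ids], dtype=np.int64)

    def ancestor_closure(self, ids: Iterable) -> np.ndarray:
        """Positions of ``ids`` and all their ancestors, ascending (topological)."""
        seen = set(int(i) for i in self.positions(ids))
        stack = list(seen)
        while stack:
            i = stack.pop()
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0 and p not in seen:
                    seen.add(int(p))
                    stack.append(int(p))
        return np.asarray(sorted(seen), dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


def _normalise_id(x) -> str | None:
    if x is None:
        return None
    s = str(x).strip()
    if s in ("", "0", "nan", "NA", "None", "."):
        return None
    return s


def load_pedigree(source) -> Pedigree:
    """Build a validated, topologically sorted :class:`Pedigree`.

    ``source`` may be a path to a CSV/TSV file with header
    ``animal,sire,dam,birth_year,flock,sex``, a DataFrame with those
    columns, or an iterable of ``(animal, sire, dam[, birth_year, flock,
    sex])`` tuples. A parent id that never appears as an animal row is
    materialised as a founder record with missing metadata.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str, bytes)) or hasattr(source, "read"):
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    else:
        rows = [tuple(r) + (None,) * (6 - len(r)) for r in source]
        df = pd.DataFrame(rows, columns=_PEDIGREE_COLUMNS)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing_cols = [c for c in ("animal", "sire", "dam") if c not in df.columns]
    if missing_cols:
        raise PedigreeError(f"pedigree input lacks required columns: {missing_cols}")
    for c in ("birth_year", "flock", "sex"):
        if c not in df.columns:
            df[c] = None

    animal = df["animal"].map(_normalise_id)
    if animal.isna().any():
        raise PedigreeError("blank animal id in pedigree input")
    if animal.duplicated().any():
        dup = animal[animal.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup!r}")
    sire = df["sire"].map(_normalise_id)
    dam = df["dam"].map(_normalise_id)

    def _year(x):
        s = _normalise_id(x)
        return None if s is None else int(float(s))

    year = df["birth_year"].map(_year)
    flock = df["flock"].map(_normalise_id)
    sex = df["sex"].map(lambda x: {"m": "male", "male": "male", "1": "male",
                                   "f": "female", "female": "female", "2": "female"}
                        .get(str(x).strip().lower(), "unknown"))

    recs: dict[str, PedigreeRecord] = {}
    for a, s, d, y, fl, sx in zip(animal, sire, dam, year, flock, sex):
        recs[a] = PedigreeRecord(a, s, d, y, fl, sx)
    # materialise implied founders
    used_as_sire = {s for s in sire if s is not None}
    used_as_dam = {d for d in dam if d is not None}
    both = used_as_sire & used_as_dam
    if both:
        raise PedigreeError(f"animal used as both sire and dam: {sorted(both)[0]!r}")
    for p in used_as_sire | used_as_dam:
        if p not in recs:
            recs[p] = PedigreeRecord(
                p, None, None, None, None,
                "male" if p in used_as_sire else "female")
    for r in recs.values():
        if r.sire_id is not None and recs[r.sire_id].sex == "female":
            raise PedigreeError(f"sire {r.sire_id!r} recorded as female")
        if r.dam_id is not None and recs[r.dam_id].sex == "male":
            raise PedigreeError(f"dam {r.dam_id!r} recorded as male")

    order = _topological_order(recs)
    pos = {a: i for i, a in enumerate(order)}
    out = pd.DataFrame(
        {
            "animal": order,
            "sire": [recs[a].sire_id for a in order],
            "dam": [recs[a].dam_id for a in order],
            "birth_year": [recs[a].birth_year for a in order],
            "flock": [recs[a].flock_id for a in order],
            "sex": [recs[a].sex for a in order],
        }
    )
    sire_idx = np.asarray([pos[recs[a].sire_id] if recs[a].sire_id else -1 for a in order])
    dam_idx = np.asarray([pos[recs[a].dam_id] if recs[a].dam_id else -1 for a in order])
    return Pedigree(out, sire_idx, dam_idx, pos)


def _topological_order(recs: Mapping[str, PedigreeRecord]) -> list[str]:
    """Kahn's algorithm over parent->offspring edges; cycle -> PedigreeError."""
    children: dict[str, list[str]] = {a: [] for a in recs}
    indeg = {a: 0 for a in recs}
    for r in recs.values():
        for p in (r.sire_id, r.dam_id):
            if p is not None:
                children[p].append(r.animal_id)
                indeg[r.animal_id] += 1
    ready = sorted(a for a, k in indeg.items() if k == 0)
    order: list[str] = []
    while ready:
        a = ready.pop()
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(recs):
        on_cycle = next(a for a, k in indeg.items() if k > 0)
        raise PedigreeError(f"pedigree cycle detected involving {on_cycle!r}")
    return order


# ---------------------------------------------------------------------------
# generation statistics


@dataclass
class GenerationStats:
    max_generations: np.ndarray
    complete_generations: np.ndarray
    equivalent_generations: np.ndarray

    def summary(self, include_founders: bool = True) -> dict:
        """Population means and maxima of the three depth measures.

        ``include_founders=False`` averages over non-founder animals only
        (founders contribute zeros to all three measures).
        """
        mask = np.ones(len(self.max_generations), bool)
        if not include_founders:
            mask = self.max_generations > 0
        return {
            "mean_max_generations": float(self.max_generations[mask].mean()),
            "max_max_generations": float(self.max_generations.max()),
            "mean_complete_generations": float(self.complete_generations[mask].mean()),
            "max_complete_generations": float(self.complete_generations.max()),
            "mean_equivalent_generations": float(self.equivalent_generations[mask].mean()),
            "max_equivalent_generations": float(self.equivalent_generations.max()),
        }


def generation_stats(ped: Pedigree) -> GenerationStats:
    """Per-animal pedigree-depth measures.

    * ``max_generations``: distance to the furthest known ancestor.
    * ``complete_generations``: deepest generation at which every ancestor
      is known, ``complete(i) = 1 + min(complete(sire), complete(dam))``
      and 0 when a parent is missing.
    * ``equivalent_generations``: sum of (1/2)^n over all known ancestors,
      the expected fraction of the genome accounted for by the recorded
      pedigree; recursion ``t_i = sum over known parents of (1 + t_p)/2``.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    maxg = np.zeros(n, dtype=np.int64)
    comp = np.zeros(n, dtype=np.int64)
    equi = np.zeros(n, dtype=float)
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0:
            maxg[i] = maxg[si] + 1
            equi[i] += (1.0 + equi[si]) / 2.0
        if di >= 0:
            maxg[i] = max(maxg[i], maxg[di] + 1)
            equi[i] += (1.0 + equi[di]) / 2.0
        if si >= 0 and di >= 0:
            comp[i] = 1 + min(comp[si], comp[di])
    return GenerationStats(maxg, comp, equi)


# ---------------------------------------------------------------------------
# generation interval

_PATHS = (("male", "male", "sire_son"), ("male", "female", "sire_daughter"),
          ("female", "male", "dam_son"), ("female", "female", "dam_daughter"))


def generation_interval(ped: Pedigree) -> dict:
    """Four-path generation interval from parent/offspring birth years.

    Returns mean birth-year difference and its standard error for the
    sire-son, sire-daughter, dam-son and dam-daughter paths, plus the
    overall mean over all retained parent-offspring pairs (equivalently the
    path means weighted by path counts). Pairs lacking either birth year
    are excluded.
    """
    years = ped.birth_year
    sex = ped.df["sex"].to_numpy()
    diffs: dict[str, list[float]] = {name: [] for _, _, name in _PATHS}
    for i in range(len(ped)):
        if not np.isfinite(years[i]):
            continue
        for par in (ped.sire_idx[i], ped.dam_idx[i]):
            if par < 0 or not np.isfinite(years[par]):
                continue
            for psex, osex, name in _PATHS:
                if sex[par] == psex and sex[i] == osex:
                    diffs[name].append(years[i] - years[par])
    all_pairs = [v for vals in diffs.values() for v in vals]
    if not all_pairs:
        raise PedigreeError("no parent-offspring pair with both birth years known")

    def _stats(v: Sequence[float]) -> dict:
        a = np.asarray(v, dtype=float)
        se = float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan")
        return {"mean": float(a.mean()), "se": se, "n": len(a)}

    out = {name: (_stats(v) if v else {"mean": float("nan"), "se": float("nan"), "n": 0})
           for name, v in diffs.items()}
    out["overall"] = _stats(all_pairs)
    return out


# ---------------------------------------------------------------------------
# subgroups


@dataclass
class SubgroupSpec:
    """Declarative filter resolving to a set of animal ids.

    Filters compose by intersection; ``sires_of`` replaces the base set by
    the distinct sires of its members.
    """

    name: str
    birth_year_range: tuple[int, int] | None = None
    min_complete_generations: int | None = None
    id_whitelist: set | None = None
    sires_of: "SubgroupSpec | None" = None


def resolve_subgroup(ped: Pedigree, spec: SubgroupSpec,
                     stats: GenerationStats | None = None) -> set:
    if spec.sires_of is not None:
        base = resolve_subgroup(ped, spec.sires_of, stats)
        pos = ped.positions(base)
        sires = ped.sire_idx[pos]
        return set(ped.animals[np.unique(sires[sires >= 0])])
    mask = np.ones(len(ped), dtype=bool)
    if spec.birth_year_range is not None:
        lo, hi = spec.birth_year_range
        y = ped.birth_year
        mask &= np.isfinite(y) & (y >= lo) & (y <= hi)
    if spec.min_complete_generations is not None:
        if stats is None:
            stats = generation_stats(ped)
        mask &= stats.complete_generations >= spec.min_complete_generations
    ids = set(ped.animals[mask])
    if spec.id_whitelist is not None:
        ids &= set(spec.id_whitelist)
    return ids
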