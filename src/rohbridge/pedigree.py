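"""Pedigree data model, pedigree inbreeding and pedigree-depth statistics.

The pedigree is a directed acyclic graph of animal records with optional
sire/dam links.  Inbreeding of an animal is the kinship of its parents,
computed with the Meuwissen & Luo indirect algorithm over the diagonal
factorisation of the numerator relationship matrix, which scales to
herd-book-sized pedigrees (O(n * depth) rather than exponential path
enumeration).  Depth/completeness statistics (FullGen, MaxGen, EquiGen,
fraction with a complete first generation) quantify how much genealogy is
actually recorded, and Wright's sex-ratio formula gives an effective
population size from the counts of distinct sires and dams.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnimalRecord",
    "Pedigree",
    "PedigreeError",
    "load_pedigree",
    "inbreeding_ped",
    "depth_metrics",
    "pct_complete_first_gen",
    "effective_size",
    "effective_size_from_delta_f",
    "pedigree_metrics_table",
]

#: Sentinels in input files that mean "parent unknown".
UNKNOWN_SENTINELS = {"", "0", "NA", "NaN", "nan", ".", "-", "na", None}


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycle, duplicate id, self-parentage...)."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: its identifier, parent links and optional metadata."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"  # {male, female, unknown}
    breed: str = ""
    birth_order: int | None = None

    def __post_init__(self):
        if self.id in (self.sire, self.dam):
            raise PedigreeError(f"animal {self.id!r} listed as its own parent")
        if self.sire is not None and self.sire == self.dam:
            raise PedigreeError(
                f"animal {self.id!r} has identical sire and dam {self.sire!r}"
            )


@dataclass
class Pedigree:
    """A validated, topologically ordered collection of animal records.

    ``order`` lists animal ids with every parent preceding its offspring;
    ``index`` maps id -> position in ``order``.  ``sire_idx``/``dam_idx``
    are integer parent pointers into ``order`` (-1 for unknown), the form
    the numeric algorithms consume.
    """

    records: dict[str, AnimalRecord]
    order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.order:
            self.order = _toposort(self.records)
        self.index = {a: i for i, a in enumerate(self.order)}
        n = len(self.order)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, a in enumerate(self.order):
            r = self.records[a]
            if r.sire is not None:
                self.sire_idx[i] = self.index[r.sire]
            if r.dam is not None:
                self.dam_idx[i] = self.index[r.dam]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self.records

    def parents(self, animal_id: str) -> tuple[str | None, str | None]:
        r = self.records[animal_id]
        return r.sire, r.dam


def _normalize_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in UNKNOWN_SENTINELS else s


def _toposort(records: dict[str, AnimalRecord]) -> list[str]:
    """Kahn's algorithm; raises with an offending id chain on a cycle."""
    children: dict[str, list[str]] = {a: [] for a in records}
    indeg = {a: 0 for a in records}
    for a, r in records.items():
        for p in (r.sire, r.dam):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    # stable order: founders in input order, ties broken by insertion order
    queue = [a for a in records if indeg[a] == 0]
    out: list[str] = []
    head = 0
    while head < len(queue):
        a = queue[head]
        head += 1
        out.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != len(records):
        cyc = _find_cycle(records, {a for a in records if a not in set(out)})
        raise PedigreeError("pedigree contains a cycle: " + " -> ".join(cyc))
    return out


def _find_cycle(records, remaining):
    start = next(iter(remaining))
    seen, chain = {}, []
    a = start
    while a not in seen:
        seen[a] = len(chain)
        chain.append(a)
        r = records[a]
        a = next(p for p in (r.sire, r.dam) if p in remaining)
    return chain[seen[a]:] + [a]


def load_pedigree(
    rows,
    *,
    id_col: str = "id",
    sire_col: str = "sire",
    dam_col: str = "dam",
    unknown: str = "0",
) -> Pedigree:
    """Build a :class:`Pedigree` from tabular records.

    ``rows`` is a DataFrame, a path to a CSV/TSV file, or an iterable of
    mappings with at least ``id``, ``sire`` and ``dam`` entries
    (``sex``/``breed`` optional).  Unknown-parent sentinels (empty, "0",
    "NA", the configurable ``unknown`` token) map to no link.  Parents that
    are referenced but have no row of their own are added as founder
    records.  Duplicate ids and cycles are fatal.
    """
    if isinstance(rows, (str,)) or hasattr(rows, "__fspath__"):
        sep = "\t" if str(rows).endswith((".tsv", ".txt")) else ","
        rows = pd.read_csv(rows, sep=sep, dtype=str)
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")

    sentinels = UNKNOWN_SENTINELS | {unknown}
    records: dict[str, AnimalRecord] = {}
    for n, row in enumerate(rows):
        aid = str(row[id_col]).strip()
        if aid in sentinels:
            raise PedigreeError(f"row {n}: missing animal id")
        if aid in records:
            raise PedigreeError(f"duplicate animal id {aid!r}")
        sire = _normalize_parent(row.get(sire_col))
        dam = _normalize_parent(row.get(dam_col))
        sire = None if sire in sentinels else sire
        dam = None if dam in sentinels else dam
        sex = str(row.get("sex", "unknown") or "unknown").strip().lower()
        if sex in ("m", "1"):
            sex = "male"
        elif sex in ("f", "2"):
            sex = "female"
        elif sex not in ("male", "female"):
            sex = "unknown"
        records[aid] = AnimalRecord(
            id=aid, sire=sire, dam=dam, sex=sex,
            breed=str(row.get("breed", "") or ""), birth_order=n,
        )
    # implicit founders for referenced-but-unlisted parents
    for r in list(records.values()):
        for p, sx in ((r.sire, "male"), (r.dam, "female")):
            if p is not None and p not in records:
                records[p] = AnimalRecord(id=p, sex=sx)
    return Pedigree(records=records)


def inbreeding_ped(p: Pedigree) -> dict[str, float]:
    """Pedigree inbreeding coefficient F_PED for every animal.

    F_PED(i) is the kinship of i's recorded parents; any unknown parent
    contributes kinship 0, so animals with a missing parent get F_PED = 0.
    Uses the Meuwissen-Luo indirect method: A = L D L' where L holds
    expected gametic contributions and D_jj is the within-family Mendelian
    sampling variance, so a_sd = sum_j L_sj L_dj D_jj is accumulated by an
    upward traversal from the two parents only.
    """
    n = len(p.order)
    sire, dam = p.sire_idx, p.dam_idx
    f = np.zeros(n)
    # D_jj = 0.5 - 0.25 (F_s + F_d), with F = -1 for an unknown parent
    d = np.empty(n)
    for i in range(n):
        fs = f[sire[i]] if sire[i] >= 0 else -1.0
        fd = f[dam[i]] if dam[i] >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if sire[i] < 0 or dam[i] < 0:
            continue
        if i and sire[i] == sire[i - 1] and dam[i] == dam[i - 1]:
            f[i] = f[i - 1]  # full sibs share F
            continue
        # accumulate a_sd by popping ancestors in reverse topological order
        coef_s = {sire[i]: 1.0}
        coef_d = {dam[i]: 1.0}
        heap = [-sire[i], -dam[i]]
        heapq.heapify(heap)
        in_heap = {sire[i], dam[i]}
        a_sd = 0.0
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            cs = coef_s.pop(j, 0.0)
            cd = coef_d.pop(j, 0.0)
            a_sd += cs * cd * d[j]
            for par in (sire[j], dam[j]):
                if par < 0:
                    continue
                if cs:
                    coef_s[par] = coef_s.get(par, 0.0) + 0.5 * cs
                if cd:
                    coef_d[par] = coef_d.get(par, 0.0) + 0.5 * cd
                if par not in in_heap:
                    in_heap.add(par)
                    heapq.heappush(heap, -par)
        f[i] = 0.5 * a_sd
    return {a: float(f[i]) for i, a in enumerate(p.order)}


def _depth_arrays(p: Pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(p.order)
    sire, dam = p.sire_idx, p.dam_idx
    fullgen = np.zeros(n, dtype=np.int64)
    maxgen = np.zeros(n, dtype=np.int64)
    equigen = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            fullgen[i] = 1 + min(fullgen[s], fullgen[d])
        known = [j for j in (s, d) if j >= 0]
        if known:
            maxgen[i] = 1 + max(maxgen[j] for j in known)
            equigen[i] = sum(0.5 * (1.0 + equigen[j]) for j in known)
    return fullgen, maxgen, equigen


def depth_metrics(p: Pedigree, animal_id: str) -> dict[str, float]:
    """FullGen, MaxGen and EquiGen for one animal.

    FullGen: deepest generation g in which *all* 2^g ancestors are recorded.
    MaxGen: generation distance to the furthest recorded ancestor (a parent
    is at distance 1; a founder scores 0).
    EquiGen: sum over all recorded ancestors of (1/2)^g — the number of
    equivalent complete generations.
    """
    if animal_id not in p:
        raise KeyError(f"unknown animal id {animal_id!r}")
    fullgen, maxgen, equigen = _depth_arrays(p)
    i = p.index[animal_id]
    return {
        "fullgen": int(fullgen[i]),
        "maxgen": int(maxgen[i]),
        "equigen": float(equigen[i]),
    }


def pct_complete_first_gen(p: Pedigree) -> float:
    """Fraction of animals with both parents recorded."""
    if len(p) == 0:
        raise PedigreeError("empty pedigree")
    both = np.sum((p.sire_idx >= 0) & (p.dam_idx >= 0))
    return float(both) / len(p)


def effective_size(p: Pedigree) -> float:
    """Wright's sex-ratio effective size Ne = 4*Nm*Nf / (Nm + Nf).

    Nm and Nf are the counts of distinct animals appearing as sires and as
    dams.  Returns NaN when either count is zero (founder-only pedigrees).
    """
    nm = len({r.sire for r in p.records.values() if r.sire is not None})
    nf = len({r.dam for r in p.records.values() if r.dam is not None})
    if nm == 0 or nf == 0:
        return float("nan")
    return 4.0 * nm * nf / (nm + nf)


def effective_size_from_delta_f(delta_f: float) -> float:
    """Alternative Ne from the per-generation inbreeding rate: 1/(2*dF)."""
    if delta_f <= 0:
        return float("nan")
    return 1.0 / (2.0 * delta_f)


def pedigree_metrics_table(p: Pedigree) -> pd.DataFrame:
    """Per-animal table of f_ped, fullgen, maxgen, equigen (+ breed, sex)."""
    f = inbreeding_ped(p)
    fullgen, maxgen, equigen = _depth_arrays(p)
    rows = []
    for i, a in enumerate(p.order):
        r = p.records[a]
        rows.append({
            "id": a, "breed": r.breed, "sex": r.sex,
            "f_ped": f[a], "fullgen": int(fullgen[i]),
            "maxgen": int(maxgen[i]), "equigen": float(equigen[i]),
        })
    return pd.DataFrame(rows)
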