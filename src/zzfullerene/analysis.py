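"""Statistical analyses over per-isomer invariants and external energy tables.

The package computes topological invariants; isomer energies come from
quantum-chemical calculations outside its scope and are consumed as TSV
tables (columns ``n  m  energy  unit``).  The analyses offered here mirror
the standard questions asked of fullerene invariants: how Clar numbers
populate an isomer set, how Clar counts relate to Kekule counts, whether the
most stable isomer maximizes K (the Zhang-Ye-Liu hypothesis) or C (its Clar
count variant) within the maximal-Clar-number class, and whether ZZ
polynomials separate all isomers (uniqueness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spiral import IsomerLabel
from .zz_engine import InvariantRecord

__all__ = [
    "IsomerEnergyRecord",
    "PopulationTable",
    "CorrelationReport",
    "HypothesisVerdict",
    "clar_population",
    "ck_statistics",
    "zhang_hypothesis",
    "modified_zhang_hypothesis",
    "uniqueness_check",
    "read_energy_table",
    "write_energy_table",
    "rank_by_energy",
    "records_to_frame",
    "HARTREE_TO_KCAL",
]

HARTREE_TO_KCAL = 627.5094740631

_UNITS = {"hartree", "kcal/mol"}


@dataclass(frozen=True)
class IsomerEnergyRecord:
    """Externally computed total energy of one isomer."""

    label: IsomerLabel
    energy: float
    unit: str = "kcal/mol"
    homo_lumo_gap_ev: float | None = None
    open_shell: bool = False

    def __post_init__(self):
        if self.unit not in _UNITS:
            raise ValueError(f"unknown energy unit {self.unit!r}; use {_UNITS}")
        if not np.isfinite(self.energy):
            raise ValueError(f"non-finite energy for {self.label}")

    @property
    def energy_kcal(self) -> float:
        if self.unit == "hartree":
            return self.energy * HARTREE_TO_KCAL
        return self.energy


@dataclass
class PopulationTable:
    """Isomer counts per Clar-number value, with integer percentages."""

    n: int
    counts: dict[int, int]
    most_stable_class: int | None = None  # Cl of the minimum-energy isomer

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[int, int]:
        """Percent of isomers per Cl class, rounded half away from zero."""
        tot = self.total
        return {
            cl: int(np.floor(100 * c / tot + 0.5)) for cl, c in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Cl": cl, "count": c, "percent": self.percentages[cl]}
            for cl, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    """Clar-count-vs-Kekule-count statistics over one isomer set."""

    n: int
    r_squared_ck: float
    min_ck_ratio: float
    max_ck_ratio: float
    wedge: pd.DataFrame = field(repr=False)  # columns: m, K, C, Cl
    r_squared_ek: float | None = None
    r_squared_ec: float | None = None


@dataclass
class HypothesisVerdict:
    """Outcome of a stability-hypothesis check.

    ``candidates`` is the set of labels maximizing the invariant within the
    maximal-Clar-number class; ``most_stable`` the set of minimum-energy
    labels (ties are reported, never broken silently).
    """

    invariant: str  # "K" or "C"
    max_clar_number: int
    candidates: frozenset[IsomerLabel]
    candidate_value: int
    most_stable: frozenset[IsomerLabel]
    holds: bool


def _require_labels(records: list[InvariantRecord]) -> dict[IsomerLabel, InvariantRecord]:
    out = {}
    for r in records:
        if r.m is None:
            raise ValueError(f"record {r.name!r} has no n:m label")
        out[IsomerLabel(r.n, r.m)] = r
    return out


def clar_population(records: list[InvariantRecord]) -> PopulationTable:
    """Histogram of Clar numbers over one fullerene's isomer set."""
    ns = {r.n for r in records}
    if len(ns) > 1:
        raise ValueError(f"records mix atom counts {sorted(ns)}")
    counts: dict[int, int] = {}
    for r in records:
        counts[r.clar_number] = counts.get(r.clar_number, 0) + 1
    return PopulationTable(n=ns.pop() if ns else 0, counts=counts)


def _r_squared(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ck_statistics(records: list[InvariantRecord],
                  energies: list[IsomerEnergyRecord] | None = None) -> CorrelationReport:
    """C-vs-K correlation, the C/K ratio range, and the wedge export.

    The lower boundary of the C-vs-K wedge is summarized as the minimum C/K
    ratio over the set (the simplest reading of a linear lower bound through
    the origin); energies, when given, add R^2(E,K) and R^2(E,C).
    """
    if not records:
        raise ValueError("no records")
    ks = [r.kekule for r in records]
    cs = [r.clar_count for r in records]
    for r in records:
        if r.clar_count < r.kekule:
            raise ValueError(f"record {r.name!r} has C < K; invariants corrupt")
    ratios = [c / k for c, k in zip(cs, ks) if k > 0]
    wedge = pd.DataFrame(
        {
            "m": [r.m for r in records],
            "K": ks,
            "C": cs,
            "Cl": [r.clar_number for r in records],
        }
    )
    rep = CorrelationReport(
        n=records[0].n,
        r_squared_ck=_r_squared(ks, cs),
        min_ck_ratio=min(ratios),
        max_ck_ratio=max(ratios),
        wedge=wedge,
    )
    if energies is not None:
        by_label = _require_labels(records)
        es, eks, ecs = [], [], []
        for er in energies:
            rec = by_label.get(er.label)
            if rec is not None:
                es.append(er.energy_kcal)
                eks.append(rec.kekule)
                ecs.append(rec.clar_count)
        rep.r_squared_ek = _r_squared(eks, es)
        rep.r_squared_ec = _r_squared(ecs, es)
    return rep


def _hypothesis(records, energies, use_clar_count: bool) -> HypothesisVerdict:
    by_label = _require_labels(records)
    e_by_label = {}
    for er in energies:
        if er.label in e_by_label:
            raise ValueError(f"duplicate energy entry for {er.label}")
        e_by_label[er.label] = er.energy_kcal
    missing = set(by_label) - set(e_by_label)
    if missing:
        raise ValueError(
            f"energies missing for {len(missing)} isomers, e.g. {sorted(missing, key=str)[:3]}"
        )
    max_cl = max(r.clar_number for r in by_label.values())
    pool = {lab: r for lab, r in by_label.items() if r.clar_number == max_cl}
    value = lambda r: r.clar_count if use_clar_count else r.kekule  # noqa: E731
    best = max(value(r) for r in pool.values())
    candidates = frozenset(lab for lab, r in pool.items() if value(r) == best)
    e_min = min(e_by_label[lab] for lab in by_label)
    most_stable = frozenset(
        lab for lab in by_label if e_by_label[lab] == e_min
    )
    return HypothesisVerdict(
        invariant="C" if use_clar_count else "K",
        max_clar_number=max_cl,
        candidates=candidates,
        candidate_value=best,
        most_stable=most_stable,
        holds=bool(candidates & most_stable),
    )


def zhang_hypothesis(records, energies) -> HypothesisVerdict:
    """Does the minimum-energy isomer maximize K within the maximal-Cl class?

    The Zhang-Ye-Liu observation, originally made for C60 where the
    icosahedral cage (K = 12,500, Cl = 8) is both the most stable isomer and
    the K-maximizer among the eighteen Cl = 8 isomers.
    """
    return _hypothesis(records, energies, use_clar_count=False)


def modified_zhang_hypothesis(records, energies) -> HypothesisVerdict:
    """Variant with the Clar count C in place of the Kekule count K."""
    return _hypothesis(records, energies, use_clar_count=True)


def uniqueness_check(records: list[InvariantRecord]) -> list[list[InvariantRecord]]:
    """Group records by their full ZZ coefficient vector; return collisions.

    An empty result supports using ZZ polynomials as unique isomer labels.
    """
    groups: dict[tuple, list[InvariantRecord]] = {}
    for r in records:
        groups.setdefault((r.n, r.coeffs), []).append(r)
    return [g for g in groups.values() if len(g) > 1]


def rank_by_energy(records: list[InvariantRecord],
                   energies: list[IsomerEnergyRecord]) -> list[IsomerLabel]:
    """Labels sorted by ascending energy (stable sort after unit normalization)."""
    by_label = _require_labels(records)
    e_by_label = {}
    for er in energies:
        if er.label in e_by_label:
            raise ValueError(f"duplicate energy entry for {er.label}")
        e_by_label[er.label] = er.energy_kcal
    known = [lab for lab in by_label if lab in e_by_label]
    return sorted(known, key=lambda lab: e_by_label[lab])


def read_energy_table(path) -> list[IsomerEnergyRecord]:
    """Read an energy TSV with columns ``n  m  energy  unit``."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["n", "m", "energy", "unit"], header=None)
    if df.iloc[0]["n"] == "n":  # tolerate a header row
        df = df.iloc[1:]
    out = []
    for _, row in df.iterrows():
        out.append(
            IsomerEnergyRecord(
                IsomerLabel(int(row["n"]), int(row["m"])),
                float(row["energy"]),
                str(row["unit"]),
            )
        )
    return out


def write_energy_table(records: list[IsomerEnergyRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write(f"{r.label.n}\t{r.label.m}\t{r.energy!r}\t{r.unit}\n")


def records_to_frame(records: list[InvariantRecord]) -> pd.DataFrame:
    """Invariant records as a DataFrame (mirrors the invariants TSV layout)."""
    return pd.DataFrame(
        {
            "n": [r.n for r in records],
            "m": [r.m for r in records],
            "K": [r.kekule for r in records],
            "C": [r.clar_count for r in records],
            "Cl": [r.clar_number for r in records],
            "cCl": [r.clar_formulas for r in records],
            "coeffs": [" ".join(map(str, r.coeffs)) for r in records],
        }
    )
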