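"""Subunit stoichiometry from measured oligomer masses.

Given monomer masses and a measured complex mass, enumerate candidate
compositions and rank them by closeness.  Ring-geometry constraints (e.g.
"this subunit comes in whole hexamer units", "that one in 0-2 copies")
are first-class: the hexamer-vs-heptamer question turns exactly on whether
an unconstrained best-fit composition survives the geometric constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

__all__ = ["SubunitSpec", "Composition", "nmer_mass", "infer_composition"]


@dataclass(frozen=True)
class SubunitSpec:
    """A protein chain: name and monomer mass in kDa."""

    name: str
    monomer_mass_kda: float

    def __post_init__(self) -> None:
        if self.monomer_mass_kda <= 0:
            raise ValueError(f"subunit {self.name!r}: monomer mass must be positive")


@dataclass(frozen=True)
class Composition:
    """A candidate subunit composition for a measured mass."""

    counts: tuple[tuple[str, int], ...]
    total_mass_kda: float
    percent_difference: float  # 100*(total - measured)/measured
    constraint_tag: str = ""

    @property
    def n_subunits(self) -> int:
        return sum(n for _, n in self.counts)

    def count(self, name: str) -> int:
        return dict(self.counts).get(name, 0)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention for kDa)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def nmer_mass(subunit: SubunitSpec, n: int) -> tuple[float, float]:
    """(reported, exact) mass of an n-mer in kDa.

    The reported value is rounded to 3 significant figures, matching the
    precision at which oligomer masses are usually quoted; the exact
    product is returned alongside.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    exact = n * subunit.monomer_mass_kda
    return round_sig(exact, 3), exact


def _allowed_counts(
    name: str,
    constraints: Mapping[str, object] | None,
    max_count: int,
) -> list[int]:
    if constraints and name in constraints:
        rule = constraints[name]
        if isinstance(rule, Mapping) and "multiple_of" in rule:
            step = int(rule["multiple_of"])  # e.g. whole rings of 6
            top = int(rule.get("max", max_count))
            return [k for k in range(0, top + 1, step)]
        if isinstance(rule, Iterable):
            return sorted(int(k) for k in rule)
        raise ValueError(f"unrecognised constraint for {name!r}: {rule!r}")
    return list(range(0, max_count + 1))


def infer_composition(
    measured_mass_kda: float,
    subunits: Sequence[SubunitSpec],
    constraints: Mapping[str, object] | None = None,
    max_count: int = 16,
    top_n: int = 5,
) -> list[Composition]:
    """Exhaustively enumerate compositions and rank by |percent difference|.

    ``constraints`` maps a subunit name either to an explicit iterable of
    allowed counts (e.g. ``{0, 1, 2}``) or to ``{"multiple_of": 6}`` for
    whole-ring units.  Ties in percent difference are broken in favour of
    fewer total subunits.  The search is deliberately brute force: the
    lattice is tiny and exactness matters more than speed.
    """
    if measured_mass_kda <= 0:
        raise ValueError("measured mass must be positive")
    if not subunits:
        raise ValueError("need at least one subunit")

    count_sets = [_allowed_counts(s.name, constraints, max_count) for s in subunits]
    tag = "" if not constraints else ";".join(
        f"{name}:{constraints[name]}" for name in sorted(constraints)
    )

    results: list[Composition] = []
    for combo in product(*count_sets):
        if all(k == 0 for k in combo):
            continue
        total = sum(k * s.monomer_mass_kda for k, s in zip(combo, subunits))
        pct = 100.0 * (total - measured_mass_kda) / measured_mass_kda
        results.append(
            Composition(
                counts=tuple((s.name, k) for s, k in zip(subunits, combo)),
                total_mass_kda=total,
                percent_difference=pct,
                constraint_tag=tag,
            )
        )
    if not results:
        names = ", ".join(s.name for s in subunits)
        raise ValueError(
            f"no feasible composition for {names} under constraints {constraints!r}"
        )
    results.sort(key=lambda comp: (abs(comp.percent_difference), comp.n_subunits))
    return results[:top_n]
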