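"""Assignment of overall PTM compositions to measured intact-protein masses.

Given a measured zero-charge mass, the backbone mass and a mass tolerance,
find every glycan/PTM composition within per-building-block count bounds
whose total average mass matches the PTM mass delta. This is a bounded
integer search (a small knapsack): depth-first over building blocks in
descending mass order with remaining-mass pruning, which is exact and fast
at glycoprotein-scale bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compositions import (
    DEFAULT_TABLE,
    GlycanComposition,
    MonosaccharideTable,
)
from .proteoforms import ZeroChargeSpectrum

__all__ = [
    "AssignmentQuery",
    "CandidateComposition",
    "SearchBounds",
    "PeakAnnotation",
    "assign_composition",
    "annotate_spectrum",
]

#: Default count bounds for an rhEPO-scale glycoprotein: generous enough to
#: cover tetra-antennary N-glycans on several sites, tight enough to keep
#: the search exact and the candidate list short.
_DEFAULT_BOUNDS = {
    "Hex": 30,
    "HexNAc": 25,
    "dHex": 6,
    "Neu5Ac": 20,
    "Acetyl": 4,
    "Hydroxyl": 4,
    "Pho": 2,
}


@dataclass(frozen=True)
class AssignmentQuery:
    """A measured intact mass to explain relative to a known backbone."""

    measured_mass: float
    backbone_mass: float
    tolerance: float = 50.0
    unit: str = "ppm"  # "ppm" | "da"

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.unit not in ("ppm", "da"):
            raise ValueError(f"unknown tolerance unit {self.unit!r}")

    @property
    def delta(self) -> float:
        """Target PTM mass: measured minus backbone."""
        return self.measured_mass - self.backbone_mass

    @property
    def tolerance_da(self) -> float:
        if self.unit == "da":
            return self.tolerance
        return self.tolerance * 1e-6 * self.measured_mass


@dataclass(frozen=True)
class CandidateComposition:
    """One composition explaining a measured mass, with its mass error."""

    composition: GlycanComposition
    theoretical_mass: float
    error_ppm: float
    error_da: float

    @property
    def total_residues(self) -> int:
        return sum(self.composition.values())


@dataclass(frozen=True)
class SearchBounds:
    """Per-building-block maximum counts and structural constraints.

    With ``acetyl_hydroxyl_on_sia`` (default on) the combined Acetyl +
    Hydroxyl count may not exceed the sialic-acid count, reflecting that
    O-acetylation and the -CH3 -> -CH2OH replacement decorate sialic acids.

    ``hex_hexnac_offset``, when set, requires Hex - HexNAc to equal the
    given value. For a glycoprotein whose N-glycans are all complex-type
    (each contributes Hex = HexNAc + 1) and whose O-glycans are core-1
    (Hex = HexNAc), the offset equals the number of occupied N-sites — a
    strong stoichiometric filter available once the site-level glycan
    repertoire is known. Off by default: intact-mass-only searches cannot
    assume it.
    """

    max_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    acetyl_hydroxyl_on_sia: bool = True
    hex_hexnac_offset: int | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.max_counts.values()):
            raise ValueError("count bounds must be >= 0")

    def n_combinations(self) -> int:
        n = 1
        for v in self.max_counts.values():
            n *= v + 1
        return n

    def admits(self, comp: GlycanComposition) -> bool:
        for name, count in comp.items():
            if count > self.max_counts.get(name, 0):
                return False
        if self.acetyl_hydroxyl_on_sia:
            if comp["Acetyl"] + comp["Hydroxyl"] > comp["Neu5Ac"] + comp["Neu5Gc"]:
                return False
        if self.hex_hexnac_offset is not None:
            if comp["Hex"] - comp["HexNAc"] != self.hex_hexnac_offset:
                return False
        return True

    @classmethod
    def rhepo(cls) -> "SearchBounds":
        """Bounds for the rhEPO main glycoform ladder.

        Restricts the search to the four building blocks of the observed
        repertoire (Hex, HexNAc, Fuc, Sia) and switches on the
        complex-N-glycan stoichiometry filter (three occupied N-sites:
        Hex - HexNAc = 3). To annotate the +42/+16 Da satellite peaks,
        widen with nonzero Acetyl/Hydroxyl bounds.
        """
        return cls(
            max_counts={"Hex": 30, "HexNAc": 25, "dHex": 6, "Neu5Ac": 20},
            hex_hexnac_offset=3,
        )


@dataclass(frozen=True)
class PeakAnnotation:
    """Ranked candidate compositions for one zero-charge peak."""

    mass: float
    abundance: float
    candidates: tuple[CandidateComposition, ...]
    reason: str | None = None  # set when no assignment was attempted
    delta_to_previous: float | None = None
    ladder_step: str | None = None  # building block matching that delta


def assign_composition(
    query: AssignmentQuery,
    bounds: SearchBounds | None = None,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> list[CandidateComposition]:
    """All compositions within bounds matching the query mass delta.

    Complete with respect to the bounds: every count tuple whose total mass
    lies within tolerance of (measured - backbone) is returned, ranked by
    absolute ppm error, then by total residue count, then by canonical
    composition string (a deterministic tie-break). A negative target delta
    beyond tolerance yields an empty list.
    """
    bounds = bounds if bounds is not None else SearchBounds()
    tol = query.tolerance_da
    target = query.delta
    if target < -tol:
        return []

    names = sorted(bounds.max_counts, key=lambda n: table[n], reverse=True)
    masses = [table[n] for n in names]
    maxima = [bounds.max_counts[n] for n in names]
    # max mass attainable from blocks i.. onward, for pruning
    tail_max = np.zeros(len(names) + 1)
    for i in range(len(names) - 1, -1, -1):
        tail_max[i] = tail_max[i + 1] + masses[i] * maxima[i]

    lo, hi = target - tol, target + tol
    results: list[CandidateComposition] = []
    counts = [0] * len(names)

    def dfs(i: int, acc: float) -> None:
        if acc > hi:
            return
        if acc + tail_max[i] < lo:
            return
        if i == len(names):
            if acc >= lo:
                comp = GlycanComposition(dict(zip(names, counts)))
                if bounds.admits(comp):
                    err_da = acc - target
                    results.append(
                        CandidateComposition(
                            composition=comp,
                            theoretical_mass=query.backbone_mass + acc,
                            error_ppm=-err_da / query.measured_mass * 1e6,
                            error_da=-err_da,
                        )
                    )
            return
        for c in range(maxima[i] + 1):
            counts[i] = c
            dfs(i + 1, acc + c * masses[i])
        counts[i] = 0

    dfs(0, 0.0)
    # |ppm| rounded so that exactly isobaric candidates (e.g. Hex vs
    # Fuc+Hydroxyl) compare as ties despite float summation order, letting
    # the residue-count tie-break decide
    results.sort(
        key=lambda c: (round(abs(c.error_ppm), 6), c.total_residues, str(c.composition))
    )
    return results


def annotate_spectrum(
    peaks: ZeroChargeSpectrum,
    backbone_mass: float,
    bounds: SearchBounds | None = None,
    tolerance: float = 50.0,
    unit: str = "ppm",
    table: MonosaccharideTable = DEFAULT_TABLE,
    ladder_tol: float = 0.5,
) -> list[PeakAnnotation]:
    """Annotate every peak of a zero-charge spectrum with candidates.

    Each peak is assigned independently; peaks below the backbone mass get
    an empty annotation with a reason. Adjacent-peak mass deltas are
    compared against single-residue masses (within ``ladder_tol`` Da) so
    that e.g. 162.14-Da hexose ladders are flagged.
    """
    bounds = bounds if bounds is not None else SearchBounds()
    out: list[PeakAnnotation] = []
    prev_mass: float | None = None
    for m, a in zip(peaks.masses, peaks.abundances):
        delta_prev = None if prev_mass is None else float(m - prev_mass)
        step = None
        if delta_prev is not None:
            for name in table:
                if abs(delta_prev - table[name]) <= ladder_tol:
                    step = name
                    break
        q = AssignmentQuery(float(m), backbone_mass, tolerance, unit)
        if m < backbone_mass - q.tolerance_da:
            out.append(
                PeakAnnotation(float(m), float(a), (), reason="below backbone mass",
                               delta_to_previous=delta_prev, ladder_step=step)
            )
        else:
            cands = assign_composition(q, bounds, table)
            out.append(
                PeakAnnotation(float(m), float(a), tuple(cands),
                               reason=None if cands else "no composition within tolerance",
                               delta_to_previous=delta_prev, ladder_step=step)
            )
        prev_mass = float(m)
    return out
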