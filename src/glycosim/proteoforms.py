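"""Proteoform combinatorics under the site-independence model.

A glycoprotein is modelled as a backbone of mass ``M_pp`` plus ``n``
modification sites. Site ``i`` carries ``k_i`` possible isoforms (including
the unoccupied state) with mass deltas ``m_ij`` and raw abundances ``A_ij``
(XIC areas from site-resolved middle-down proteomics). Assuming sites are
modified independently, a proteoform obtained by choosing isoform ``j_i`` at
every site has

    mass         M = M_pp + sum_i m_{i,j_i}
    probability  P = prod_i P_{i,j_i},   P_ij = A_ij / sum_j' A_ij'

Enumerating (or convolving) all combinations and collapsing equal masses
yields the zero-charge "pseudo-native" spectrum: the mass-domain proteoform
distribution that a native MS measurement of the intact protein should
reproduce if the site-level picture is complete.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mass as _pytmass

from .compositions import DEFAULT_TABLE, GlycanComposition, MonosaccharideTable

__all__ = [
    "ModificationIsoform",
    "SiteTable",
    "ProteinModel",
    "Proteoform",
    "ZeroChargeSpectrum",
    "normalize_site",
    "backbone_mass_from_sequence",
    "enumerate_proteoforms",
    "build_zero_charge_spectrum",
    "site_convolution",
    "CombinatorialExplosionError",
    "DegenerateSiteError",
]

#: Average mass of one hydrogen atom (Da); two are lost per disulfide bridge.
HYDROGEN_AVG = 1.00794


class DegenerateSiteError(ValueError):
    """All isoform abundances at a site are zero: cannot normalize."""


class CombinatorialExplosionError(RuntimeError):
    """Unpruned enumeration would exceed the combination cap."""


@dataclass(frozen=True)
class ModificationIsoform:
    """One PTM state of a site: a labelled mass delta with a raw abundance.

    ``delta`` is either a :class:`GlycanComposition` or a raw mass delta in
    Da (for non-glycan PTMs injected without composition bookkeeping). The
    unoccupied state is an isoform of mass 0.
    """

    label: str
    delta: GlycanComposition | float
    abundance: float

    def __post_init__(self):
        if self.abundance < 0:
            raise ValueError(f"isoform {self.label!r}: abundance must be >= 0")

    def mass(self, table: MonosaccharideTable = DEFAULT_TABLE) -> float:
        if isinstance(self.delta, GlycanComposition):
            return self.delta.mass(table)
        return float(self.delta)

    @property
    def composition(self) -> GlycanComposition | None:
        return self.delta if isinstance(self.delta, GlycanComposition) else None


@dataclass(frozen=True)
class SiteTable:
    """All observed PTM isoforms at one modification site."""

    site_id: str
    isoforms: tuple[ModificationIsoform, ...]
    kind: str = "N"  # N-, O- or C-linked site ("N" | "O" | "C")

    def __post_init__(self):
        object.__setattr__(self, "isoforms", tuple(self.isoforms))
        if len(self.isoforms) < 1:
            raise ValueError(f"site {self.site_id!r}: needs at least one isoform")
        labels = [iso.label for iso in self.isoforms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"site {self.site_id!r}: duplicate isoform labels")
        if not any(iso.abundance > 0 for iso in self.isoforms):
            raise DegenerateSiteError(f"site {self.site_id!r}: all abundances are zero")

    @property
    def k(self) -> int:
        return len(self.isoforms)

    def masses(self, table: MonosaccharideTable = DEFAULT_TABLE) -> np.ndarray:
        return np.array([iso.mass(table) for iso in self.isoforms])


@dataclass(frozen=True)
class ProteinModel:
    """Backbone mass plus independent modification-site tables."""

    name: str
    backbone_mass: float
    sites: tuple[SiteTable, ...] = ()
    table: MonosaccharideTable = field(default_factory=lambda: DEFAULT_TABLE, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.backbone_mass > 0:
            raise ValueError("backbone_mass must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_combinations(self) -> int:
        return math.prod(site.k for site in self.sites) if self.sites else 1

    def with_sites(self, sites) -> "ProteinModel":
        return replace(self, sites=tuple(sites))


@dataclass(frozen=True)
class Proteoform:
    """One fully specified modification state of the protein."""

    total_mass: float
    probability: float
    choices: tuple[str, ...] | None = None  # per-site isoform labels


@dataclass(frozen=True)
class ZeroChargeSpectrum:
    """Sorted (mass, relative abundance) proteoform peaks.

    ``retained_probability`` tracks how much of the full probability mass
    survived pruning; it equals 1 for exhaustive construction. Abundances
    are never renormalized, so conservation losses stay visible.
    """

    masses: np.ndarray
    abundances: np.ndarray
    retained_probability: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if m.shape != a.shape or m.ndim != 1:
            raise ValueError("masses and abundances must be 1-D arrays of equal length")
        if m.size and np.any(np.diff(m) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("abundances must be >= 0")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)

    def __len__(self) -> int:
        return self.masses.size

    @property
    def modal_mass(self) -> float:
        """Mass of the most abundant proteoform peak."""
        if not len(self):
            raise ValueError("empty spectrum has no modal mass")
        return float(self.masses[np.argmax(self.abundances)])


def normalize_site(site: SiteTable) -> np.ndarray:
    """Per-site normalized relative abundances ``P_ij = A_ij / sum_j A_ij``."""
    a = np.array([iso.abundance for iso in site.isoforms], dtype=float)
    total = a.sum()
    if total <= 0:
        raise DegenerateSiteError(f"site {site.site_id!r}: all abundances are zero")
    return a / total


def backbone_mass_from_sequence(sequence: str, n_disulfides: int = 0) -> float:
    """Average mass of a polypeptide in Da, corrected for disulfide bridges.

    Sum of residue average masses plus one water, minus two hydrogen atoms
    per disulfide bridge. Raises on unknown one-letter codes, naming the
    offending position.
    """
    sequence = sequence.strip().upper()
    for pos, aa in enumerate(sequence, start=1):
        if aa not in _pytmass.std_aa_mass:
            raise ValueError(f"unknown residue code {aa!r} at position {pos}")
    m = _pytmass.calculate_mass(sequence=sequence, average=True)
    return float(m - 2 * HYDROGEN_AVG * n_disulfides)


def enumerate_proteoforms(
    protein: ProteinModel,
    prune_threshold: float = 0.0,
    max_combinations: int = 2_000_000,
    with_choices: bool = False,
) -> list[Proteoform]:
    """Enumerate every isoform combination with probability >= threshold.

    Exhaustive nested product over sites. For models whose combination count
    exceeds ``max_combinations`` a :class:`CombinatorialExplosionError` is
    raised pointing at :func:`site_convolution`, which scales to many-site
    proteins by merging isobaric intermediates.
    """
    if not 0 <= prune_threshold < 1:
        raise ValueError("prune_threshold must be in [0, 1)")
    if protein.n_combinations > max_combinations:
        raise CombinatorialExplosionError(
            f"{protein.n_combinations} combinations exceed the cap "
            f"({max_combinations}); use site_convolution for many-site models"
        )
    per_site_masses = [site.masses(protein.table) for site in protein.sites]
    per_site_probs = [normalize_site(site) for site in protein.sites]
    per_site_labels = [[iso.label for iso in site.isoforms] for site in protein.sites]

    out: list[Proteoform] = []
    for combo in itertools.product(*(range(s.k) for s in protein.sites)):
        p = 1.0
        m = protein.backbone_mass
        for i, j in enumerate(combo):
            p *= per_site_probs[i][j]
            m += per_site_masses[i][j]
        if p >= prune_threshold:
            choices = (
                tuple(per_site_labels[i][j] for i, j in enumerate(combo))
                if with_choices
                else None
            )
            out.append(Proteoform(total_mass=m, probability=p, choices=choices))
    return out


def _merge_sorted(masses: np.ndarray, probs: np.ndarray, merge_tol: float):
    """Merge already-sorted peaks within merge_tol of the running
    probability-weighted cluster mean; returns (masses, probs)."""
    if masses.size == 0:
        return masses, probs
    out_m: list[float] = []
    out_p: list[float] = []
    cm, cp = masses[0], probs[0]
    for m, p in zip(masses[1:], probs[1:]):
        if m - cm <= merge_tol:
            tot = cp + p
            cm = (cm * cp + m * p) / tot if tot > 0 else (cm + m) / 2
            cp = tot
        else:
            out_m.append(cm)
            out_p.append(cp)
            cm, cp = m, p
    out_m.append(cm)
    out_p.append(cp)
    return np.array(out_m), np.array(out_p)


def build_zero_charge_spectrum(
    proteoforms: list[Proteoform],
    merge_tol: float = 0.01,
    retained_probability: float | None = None,
) -> ZeroChargeSpectrum:
    """Collapse proteoforms into a sorted zero-charge peak list.

    Proteoforms within ``merge_tol`` Da (positional isomers have delta 0)
    merge into one peak at the probability-weighted mean mass with summed
    probability. Total abundance is conserved.
    """
    if merge_tol < 0:
        raise ValueError("merge_tol must be >= 0")
    if not proteoforms:
        return ZeroChargeSpectrum(np.array([]), np.array([]), 0.0)
    masses = np.array([f.total_mass for f in proteoforms])
    probs = np.array([f.probability for f in proteoforms])
    order = np.argsort(masses, kind="stable")
    masses, probs = _merge_sorted(masses[order], probs[order], merge_tol)
    if retained_probability is None:
        retained_probability = float(probs.sum())
    return ZeroChargeSpectrum(masses, probs, retained_probability)


def site_convolution(
    protein: ProteinModel,
    merge_tol: float = 0.01,
    prune_threshold: float = 1e-8,
) -> ZeroChargeSpectrum:
    """Zero-charge spectrum by iterated per-site convolution.

    Convolves the per-site (mass delta, P) distributions one site at a time,
    merging peaks within ``merge_tol`` Da and dropping peaks below
    ``prune_threshold`` after each step. Equivalent to exhaustive
    enumeration followed by merging, but scales to proteins with dozens of
    sites (e.g. 17 binary C-mannosylation sites) because isobaric
    intermediates collapse at every stage. ``retained_probability`` reports
    the probability mass surviving pruning; no renormalization is applied.
    """
    if merge_tol < 0:
        raise ValueError("merge_tol must be >= 0")
    masses = np.array([protein.backbone_mass])
    probs = np.array([1.0])
    for site in protein.sites:
        dm = site.masses(protein.table)
        dp = normalize_site(site)
        masses = (masses[:, None] + dm[None, :]).ravel()
        probs = (probs[:, None] * dp[None, :]).ravel()
        order = np.argsort(masses, kind="stable")
        masses, probs = _merge_sorted(masses[order], probs[order], merge_tol)
        if prune_threshold > 0:
            keep = probs >= prune_threshold
            masses, probs = masses[keep], probs[keep]
    return ZeroChargeSpectrum(masses, probs, float(probs.sum()))
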