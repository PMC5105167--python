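"""In-silico glycosidase treatments of a protein model.

Applied at the model level (before spectrum construction) these mirror the
wet-lab simplification experiments: sialidase strips all terminal sialic
acids, PNGase F releases whole N-glycans. Comparing a treated construction
against a treated measurement removes the corresponding source of
heterogeneity from both sides.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

from .compositions import GlycanComposition
from .proteoforms import ModificationIsoform, ProteinModel, SiteTable

__all__ = ["apply_sialidase", "apply_pngasef", "PNGASEF_DEAMIDATION_SHIFT"]

#: Asn -> Asp mass shift (Da) left behind by enzymatic N-glycan release.
PNGASEF_DEAMIDATION_SHIFT = 0.9840

#: Building blocks removed by sialidase: the sialic acids themselves plus
#: their O-acetyl / glycolyl decorations, which leave with them.
_SIALIDASE_TARGETS = ("Neu5Ac", "Neu5Gc", "Acetyl", "Hydroxyl")


def _merge_identical(isoforms: list[ModificationIsoform]) -> list[ModificationIsoform]:
    """Sum abundances of isoforms that became identical in delta."""
    merged: dict[object, ModificationIsoform] = {}
    for iso in isoforms:
        key = iso.delta if isinstance(iso.delta, GlycanComposition) else round(float(iso.delta), 9)
        if key in merged:
            prev = merged[key]
            merged[key] = ModificationIsoform(
                label=prev.label, delta=prev.delta, abundance=prev.abundance + iso.abundance
            )
        else:
            merged[key] = iso
    return list(merged.values())


def apply_sialidase(protein: ProteinModel) -> ProteinModel:
    """Remove all sialic acids (and their decorations) from every isoform.

    Composition deltas have their Neu5Ac/Neu5Gc counts — and the Acetyl /
    Hydroxyl modifications riding on them — set to zero; isoforms that
    become identical are merged by summing abundances. Raw-mass isoforms
    carry no composition to edit and pass through unchanged with a warning.
    """
    new_sites = []
    for site in protein.sites:
        isoforms = []
        for iso in site.isoforms:
            comp = iso.composition
            if comp is None:
                if iso.mass(protein.table) != 0:
                    warnings.warn(
                        f"site {site.site_id!r}, isoform {iso.label!r}: raw mass delta "
                        "cannot be desialylated in silico; passed through unchanged",
                        stacklevel=2,
                    )
                isoforms.append(iso)
            else:
                isoforms.append(
                    ModificationIsoform(
                        label=iso.label,
                        delta=comp.without(*_SIALIDASE_TARGETS),
                        abundance=iso.abundance,
                    )
                )
        new_sites.append(SiteTable(site.site_id, tuple(_merge_identical(isoforms)), site.kind))
    return protein.with_sites(new_sites)


def apply_pngasef(
    protein: ProteinModel,
    site_kinds: Mapping[str, str] | None = None,
    deamidation_shift: bool = True,
) -> ProteinModel:
    """Release all N-glycans; O- and C-linked sites are untouched.

    Each N-site collapses to a single unmodified isoform. With
    ``deamidation_shift`` (default on), every *occupied* N-isoform leaves a
    +0.9840 Da Asn->Asp scar, so a partially occupied site becomes a 0 /
    +0.9840 Da mixture weighted by its occupancy. ``site_kinds`` overrides
    the per-site ``kind`` annotation.
    """
    kinds = dict(site_kinds or {})
    new_sites = []
    for site in protein.sites:
        kind = kinds.get(site.site_id, site.kind)
        if kind != "N":
            new_sites.append(site)
            continue
        isoforms = []
        for iso in site.isoforms:
            occupied = iso.mass(protein.table) != 0
            scar = PNGASEF_DEAMIDATION_SHIFT if (deamidation_shift and occupied) else 0.0
            isoforms.append(
                ModificationIsoform(
                    label="deglycosylated" if occupied else iso.label,
                    delta=GlycanComposition() if scar == 0 else scar,
                    abundance=iso.abundance,
                )
            )
        new_sites.append(SiteTable(site.site_id, tuple(_merge_identical(isoforms)), kind))
    return protein.with_sites(new_sites)
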