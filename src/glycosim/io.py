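"""Readers and writers for the package's text interchange formats.

Site tables are CSV with columns ``protein,site,kind,isoform_label,
composition,abundance`` (empty composition = unmodified isoform; a raw
mass delta may be given as ``+123.45``). The backbone mass travels in a
``# backbone_mass = <Da>`` comment line so that one file fully specifies a
model. Spectra are two-column delimited text (m/z, intensity); mzML is
supported read-only through pyteomics.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import GlycanComposition, parse_composition
from .projection import MzSpectrum
from .proteoforms import ModificationIsoform, ProteinModel, SiteTable, ZeroChargeSpectrum

__all__ = [
    "read_site_table",
    "write_site_table",
    "read_spectrum",
    "write_spectrum",
    "read_zero_charge",
    "write_zero_charge",
]

_SITE_COLUMNS = ["protein", "site", "kind", "isoform_label", "composition", "abundance"]


class FormatError(ValueError):
    """Malformed input file."""


def _parse_delta(text: str) -> GlycanComposition | float:
    text = (text or "").strip()
    if not text:
        return GlycanComposition()
    if text.startswith(("+", "-")):
        try:
            return float(text)
        except ValueError:
            raise FormatError(f"bad raw mass delta {text!r}") from None
    return parse_composition(text)


def read_site_table(path: str | Path, backbone_mass: float | None = None) -> ProteinModel:
    """Load a protein model from a site-table CSV.

    Rows are grouped by site id in first-appearance order. The backbone
    mass is taken from a ``# backbone_mass = X`` comment unless overridden
    by the argument. Malformed rows and duplicate (site, label) pairs raise
    with the offending line identified.
    """
    path = Path(path)
    header_mass = None
    lines = path.read_text().splitlines()
    data_lines = []
    for raw in lines:
        s = raw.strip()
        if s.startswith("#"):
            if "backbone_mass" in s and "=" in s:
                header_mass = float(s.split("=", 1)[1])
            continue
        if s:
            data_lines.append(raw)
    if backbone_mass is None:
        backbone_mass = header_mass
    if backbone_mass is None:
        raise FormatError(
            f"{path}: no backbone mass; add a '# backbone_mass = <Da>' line or pass it explicitly"
        )
    try:
        df = pd.read_csv(_io.StringIO("\n".join(data_lines)), dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; expected {_SITE_COLUMNS}")

    name = df["protein"].iloc[0] if len(df) else path.stem
    site_order: list[str] = []
    grouped: dict[str, list[tuple[str, ModificationIsoform]]] = {}
    kinds: dict[str, str] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            abundance = float(row.abundance)
            delta = _parse_delta(row.composition)
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        site = str(row.site)
        if site not in grouped:
            grouped[site] = []
            site_order.append(site)
            kinds[site] = str(row.kind) or "N"
        if any(lbl == row.isoform_label for lbl, _ in grouped[site]):
            raise FormatError(
                f"{path}: line {lineno}: duplicate isoform label {row.isoform_label!r} "
                f"at site {site!r}"
            )
        grouped[site].append(
            (row.isoform_label, ModificationIsoform(str(row.isoform_label), delta, abundance))
        )
    sites = tuple(
        SiteTable(site, tuple(iso for _, iso in grouped[site]), kinds[site])
        for site in site_order
    )
    return ProteinModel(name=str(name), backbone_mass=float(backbone_mass), sites=sites)


def write_site_table(protein: ProteinModel, path: str | Path) -> None:
    """Write a model as site-table CSV (round trips with read_site_table)."""
    rows = []
    for site in protein.sites:
        for iso in site.isoforms:
            if iso.composition is not None:
                comp = str(iso.composition)
            else:
                comp = f"{float(iso.delta):+.6g}"
            rows.append(
                {
                    "protein": protein.name,
                    "site": site.site_id,
                    "kind": site.kind,
                    "isoform_label": iso.label,
                    "composition": comp,
                    "abundance": repr(float(iso.abundance)),
                }
            )
    df = pd.DataFrame(rows, columns=_SITE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# backbone_mass = {protein.backbone_mass!r}\n")
        df.to_csv(fh, index=False)


def _read_mzml(path: Path) -> MzSpectrum:
    from pyteomics import mzml

    with mzml.read(str(path)) as reader:
        spec = next(iter(reader), None)
    if spec is None:
        raise FormatError(f"{path}: no spectra in mzML file")
    mz = np.asarray(spec["m/z array"], dtype=float)
    inten = np.asarray(spec["intensity array"], dtype=float)
    mode = "centroid" if spec.get("centroid spectrum") is not None else "profile"
    return _sorted_spectrum(mz, inten, mode, str(path))


def _sorted_spectrum(mz: np.ndarray, inten: np.ndarray, mode: str | None, what: str) -> MzSpectrum:
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size and np.any(np.diff(mz) <= 0):
        # repair duplicates by summing, with a warning
        import warnings

        warnings.warn(f"{what}: duplicate m/z values summed", stacklevel=3)
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, inten)
        mz, inten = uniq, summed
    if mode is None:
        mode = _detect_mode(mz)
    return MzSpectrum(mz, inten, mode)


def _detect_mode(mz: np.ndarray) -> str:
    """Profile if the spectrum is a dense, near-uniform grid."""
    if mz.size > 200:
        d = np.diff(mz)
        if np.std(d) < 0.5 * np.mean(d):
            return "profile"
    return "centroid"


def read_spectrum(path: str | Path, format: str = "auto", mode: str | None = None) -> MzSpectrum:
    """Read a spectrum from two-column text (or mzML, read-only).

    ``format`` is ``auto`` (by extension), ``txt`` or ``mzml``. Text may be
    whitespace- or comma-delimited; ``#`` lines are comments. Unsorted
    input is sorted; duplicate m/z values are summed with a warning. The
    centroid/profile mode is detected from grid density unless given.
    """
    path = Path(path)
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "txt"
    if format == "mzml":
        return _read_mzml(path)
    if format != "txt":
        raise ValueError(f"unknown format {format!r}")
    try:
        arr = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric spectrum data: {exc}") from exc
    arr = np.atleast_2d(arr)
    if arr.size == 0:
        raise FormatError(f"{path}: empty spectrum file")
    if arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (m/z, intensity), got {arr.shape[1]}")
    return _sorted_spectrum(arr[:, 0].copy(), arr[:, 1].copy(), mode, str(path))


def _is_whitespace(path: Path) -> bool:
    for raw in path.read_text().splitlines():
        s = raw.strip()
        if s and not s.startswith("#"):
            return "," not in s
    return True


def write_spectrum(spectrum: MzSpectrum, path: str | Path) -> None:
    """Write a spectrum as tab-separated text with full float precision."""
    with open(path, "w") as fh:
        fh.write(f"# mode = {spectrum.mode}\n")
        for q, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(q)!r}\t{float(i)!r}\n")


def read_zero_charge(path: str | Path) -> ZeroChargeSpectrum:
    """Read a zero-charge (mass, abundance) peak list from text."""
    spec = read_spectrum(path, format="txt", mode="centroid")
    return ZeroChargeSpectrum(spec.mz, spec.intensity, float(spec.intensity.sum()))


def write_zero_charge(spectrum: ZeroChargeSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# retained_probability = {float(spectrum.retained_probability)!r}\n")
        for m, a in zip(spectrum.masses, spectrum.abundances):
            fh.write(f"{float(m)!r}\t{float(a)!r}\n")
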