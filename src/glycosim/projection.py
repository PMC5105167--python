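"""Projection of zero-charge proteoform spectra into m/z space.

Electrosprayed native proteins appear over a narrow charge envelope
[M+mH]^m+ ... [M+nH]^n+. Each neutral mass M observed at charge z gives a
peak at

    Q = (M + z * m_proton) / z

with intensity proportional to the proteoform abundance times the relative
abundance A_k of that charge state. Profile rendering convolves the
resulting sticks with a Gaussian whose width follows an Orbitrap-like
resolution law R(m/z) = R_ref * (mz_ref / mz)**exponent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .proteoforms import ZeroChargeSpectrum

__all__ = [
    "PROTON_MASS",
    "ChargeEnvelope",
    "MzSpectrum",
    "ResolutionModel",
    "to_mz",
    "render_profile",
    "construct_pseudo_native",
    "estimate_envelope",
]

#: Mass of the proton in Da (not the hydrogen atom: the ESI charge carrier).
PROTON_MASS = 1.007276

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ChargeEnvelope:
    """Charge states and their relative abundances, summing to 1."""

    states: tuple[tuple[int, float], ...]

    def __post_init__(self):
        states = tuple((int(z), float(a)) for z, a in self.states)
        if not states:
            raise ValueError("charge envelope must contain at least one state")
        zs = [z for z, _ in states]
        if len(set(zs)) != len(zs):
            raise ValueError("duplicate charge states")
        if any(z <= 0 for z in zs):
            raise ValueError("charges must be positive integers")
        if any(a < 0 for _, a in states):
            raise ValueError("charge-state abundances must be >= 0")
        total = sum(a for _, a in states)
        if abs(total - 1.0) > 1e-9:
            if total <= 0:
                raise ValueError("charge-state abundances sum to zero")
            states = tuple((z, a / total) for z, a in states)
        object.__setattr__(self, "states", states)

    @classmethod
    def uniform(cls, z_min: int, z_max: int) -> "ChargeEnvelope":
        zs = range(z_min, z_max + 1)
        n = len(zs)
        return cls(tuple((z, 1.0 / n) for z in zs))

    @property
    def charges(self) -> tuple[int, ...]:
        return tuple(z for z, _ in self.states)


#: Default native-MS envelope for ~30 kDa glycoproteins (rhEPO-like):
#: charge states 8+, 9+, 10+ with equal weights.
DEFAULT_ENVELOPE = ChargeEnvelope.uniform(8, 10)


@dataclass(frozen=True)
class MzSpectrum:
    """Centroid sticks or a profile trace: sorted (m/z, intensity) points."""

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "centroid"  # "centroid" | "profile"

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")
        if self.mode not in ("centroid", "profile"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return self.mz.size

    @property
    def mz_range(self) -> tuple[float, float]:
        if not len(self):
            raise ValueError("empty spectrum has no m/z range")
        return float(self.mz[0]), float(self.mz[-1])

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def peak_pick(self, rel_threshold: float = 0.01) -> "MzSpectrum":
        """Centroid a profile trace by local-maximum detection.

        Keeps strict local maxima above ``rel_threshold`` x base peak.
        Centroid spectra are returned unchanged (after thresholding).
        """
        if self.mode == "centroid":
            keep = self.intensity >= rel_threshold * self.base_peak_intensity
            return MzSpectrum(self.mz[keep], self.intensity[keep], "centroid")
        y = self.intensity
        if y.size < 3:
            return MzSpectrum(self.mz, y, "centroid")
        is_max = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
        idx = np.flatnonzero(is_max) + 1
        idx = idx[y[idx] >= rel_threshold * self.base_peak_intensity]
        return MzSpectrum(self.mz[idx], y[idx], "centroid")


@dataclass(frozen=True)
class ResolutionModel:
    """Resolving power R(m/z) = R_ref * (mz_ref / mz)**exponent.

    FWHM at m/z Q is Q / R(Q). Defaults follow an Orbitrap operated at
    resolution 17,500 (at m/z 200) with the usual inverse-square-root
    scaling of resolving power with m/z.
    """

    R_ref: float = 17_500.0
    mz_ref: float = 200.0
    exponent: float = 0.5

    def __post_init__(self):
        if not (self.R_ref > 0 and self.mz_ref > 0):
            raise ValueError("R_ref and mz_ref must be > 0")

    def resolving_power(self, mz) -> np.ndarray:
        mz = np.asarray(mz, dtype=float)
        return self.R_ref * (self.mz_ref / mz) ** self.exponent

    def fwhm(self, mz) -> np.ndarray:
        return np.asarray(mz, dtype=float) / self.resolving_power(mz)


def to_mz(
    spectrum: ZeroChargeSpectrum,
    envelope: ChargeEnvelope = DEFAULT_ENVELOPE,
    proton_mass: float = PROTON_MASS,
) -> MzSpectrum:
    """Project a zero-charge spectrum through a charge envelope.

    Each (M, P) peak emits one stick per charge state z at
    Q = (M + z*proton)/z with intensity P * A_z; exactly coincident sticks
    are summed. Total intensity equals the total zero-charge abundance.
    """
    if not proton_mass > 0:
        raise ValueError("proton_mass must be > 0")
    mzs = []
    intens = []
    for z, a in envelope.states:
        mzs.append((spectrum.masses + z * proton_mass) / z)
        intens.append(spectrum.abundances * a)
    mz = np.concatenate(mzs) if mzs else np.array([])
    inten = np.concatenate(intens) if intens else np.array([])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size:
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, inten)
        mz, inten = uniq, summed
    return MzSpectrum(mz, inten, "centroid")


def invert_mz(mz: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """Neutral mass from an m/z value at known charge: M = Q*z - z*proton."""
    return mz * z - z * proton_mass


def render_profile(
    centroid: MzSpectrum,
    res: ResolutionModel = ResolutionModel(),
    grid_step: float | None = None,
    mz_range: tuple[float, float] | None = None,
    truncate_sigmas: float = 6.0,
) -> MzSpectrum:
    """Render centroid sticks into a profile trace of Gaussians.

    Each stick becomes a Gaussian of FWHM m/z / R(m/z) whose *area* equals
    the stick intensity, evaluated on a uniform grid. ``grid_step`` must be
    at most a quarter of the narrowest FWHM in range; a coarser request is
    refined automatically with a warning. Default: narrowest FWHM / 6.
    """
    if not len(centroid):
        return MzSpectrum(np.array([]), np.array([]), "profile")
    fwhms = res.fwhm(centroid.mz)
    min_fwhm = float(fwhms.min())
    if grid_step is None:
        grid_step = min_fwhm / 6.0
    elif grid_step > min_fwhm / 4.0:
        warnings.warn(
            f"grid_step {grid_step:g} too coarse for FWHM {min_fwhm:g}; "
            f"refined to {min_fwhm / 4.0:g}",
            stacklevel=2,
        )
        grid_step = min_fwhm / 4.0
    if not grid_step > 0:
        raise ValueError("grid_step must be > 0")
    sigmas = fwhms * _SIGMA_PER_FWHM
    if mz_range is None:
        lo = centroid.mz[0] - truncate_sigmas * sigmas[0]
        hi = centroid.mz[-1] + truncate_sigmas * sigmas[-1]
    else:
        lo, hi = mz_range
    n = int(np.ceil((hi - lo) / grid_step)) + 1
    grid = lo + np.arange(n) * grid_step
    out = np.zeros(n)
    norm = 1.0 / (np.sqrt(2.0 * np.pi))
    for q, inten, sig in zip(centroid.mz, centroid.intensity, sigmas):
        i0 = max(0, int(np.floor((q - truncate_sigmas * sig - lo) / grid_step)))
        i1 = min(n, int(np.ceil((q + truncate_sigmas * sig - lo) / grid_step)) + 1)
        if i0 >= i1:
            continue
        x = grid[i0:i1]
        # area-normalized Gaussian times the stick intensity, times the grid
        # step so that summing the trace recovers the stick areas
        out[i0:i1] += inten * grid_step * norm / sig * np.exp(-0.5 * ((x - q) / sig) ** 2)
    return MzSpectrum(grid, out, "profile")


def construct_pseudo_native(
    protein,
    envelope: ChargeEnvelope = DEFAULT_ENVELOPE,
    res: ResolutionModel = ResolutionModel(),
    grid_step: float | None = None,
    merge_tol: float = 0.01,
    prune_threshold: float = 1e-8,
    profile: bool = True,
) -> MzSpectrum:
    """Full construction pipeline: model -> zero-charge -> m/z -> profile.

    Deterministic composition of :func:`site_convolution`, :func:`to_mz`
    and :func:`render_profile`. With ``profile=False`` the centroid stick
    spectrum is returned instead.
    """
    from .proteoforms import site_convolution

    zc = site_convolution(protein, merge_tol=merge_tol, prune_threshold=prune_threshold)
    sticks = to_mz(zc, envelope)
    if not profile:
        return sticks
    return render_profile(sticks, res=res, grid_step=grid_step)


def estimate_envelope(
    spectrum: MzSpectrum,
    modal_mass: float,
    charges: tuple[int, ...],
    window_da: float = 4000.0,
    proton_mass: float = PROTON_MASS,
) -> ChargeEnvelope:
    """Estimate charge-state abundances from an experimental m/z spectrum.

    For each candidate charge, intensity is summed over the m/z window that
    the mass range [modal_mass - window, modal_mass + window] maps to at
    that charge; the sums are normalized into envelope abundances.
    """
    weights = []
    for z in charges:
        lo = (modal_mass - window_da + z * proton_mass) / z
        hi = (modal_mass + window_da + z * proton_mass) / z
        sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
        weights.append(float(spectrum.intensity[sel].sum()))
    total = sum(weights)
    if total <= 0:
        raise ValueError("no intensity found in any charge-state window")
    return ChargeEnvelope(tuple((z, w / total) for z, w in zip(charges, weights)))
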