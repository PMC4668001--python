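"""Potentials of mean force by Boltzmann inversion.

The PMF along a distance coordinate is W(r) = -kT ln(rho(r) / rho0), with
rho the sampled probability density and rho0 the modal density, so the
global minimum of W is 0 by construction.  Unsampled bins carry no
information and stay masked rather than being assigned an arbitrary large
value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL_MOL_K

__all__ = [
    "DensityProfile",
    "PMFProfile",
    "histogram_density",
    "boltzmann_invert",
    "align_pmfs",
    "opening_energy",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 0.2


@dataclass
class DensityProfile:
    """Normalised histogram of a distance series."""

    label: str
    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def modal_bin(self) -> int:
        return int(np.argmax(self.density))


@dataclass
class PMFProfile:
    """Boltzmann-inverted free-energy profile (kcal/mol).

    ``values`` is a masked array: masked bins were never sampled.
    ``offset`` is the distance shift applied by :func:`align_pmfs`
    (0 until aligned).
    """

    label: str
    bin_centers: np.ndarray
    values: np.ma.MaskedArray
    temperature: float
    rho0: float
    offset: float = 0.0

    @property
    def positions(self) -> np.ndarray:
        """Bin centres after alignment shift."""
        return self.bin_centers - self.offset

    def minimum_position(self) -> float:
        i = int(np.ma.argmin(self.values))
        return float(self.positions[i])


def histogram_density(values: np.ndarray, label: str = "",
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      value_range: tuple[float, float] | None = None,
                      ) -> DensityProfile:
    """Probability density over uniform bins (sums to 1 when multiplied by
    the bin width).

    The default range pads the sampled extent by one bin on each side so
    edge samples never sit exactly on the outer boundary.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if value_range is None:
        lo, hi = float(v.min()) - bin_width, float(v.max()) + bin_width
    else:
        lo, hi = map(float, value_range)
        if hi <= lo:
            raise ValueError("invalid range")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if v.min() == v.max():
        warnings.warn(f"degenerate sample for {label or 'series'}: all "
                      f"values identical")
    density, edges = np.histogram(v, bins=edges, density=True)
    return DensityProfile(label=label, bin_edges=edges, density=density,
                          n_samples=v.size)


def boltzmann_invert(profile: DensityProfile,
                     temperature: float = DEFAULT_TEMPERATURE) -> PMFProfile:
    """W(r) = -kT ln(rho / rho0), rho0 the modal density (min W = 0)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    kT = KB_KCAL_MOL_K * temperature
    rho0 = float(profile.density.max())
    if rho0 <= 0:
        raise ValueError(f"empty density profile for {profile.label!r}")
    masked = np.ma.masked_where(profile.density <= 0, profile.density)
    values = -kT * np.ma.log(masked / rho0)
    return PMFProfile(label=profile.label,
                      bin_centers=profile.bin_centers.copy(),
                      values=values, temperature=temperature, rho0=rho0)


def align_pmfs(profiles: list[PMFProfile]) -> list[PMFProfile]:
    """Shift each profile along the distance axis so its global minimum
    sits at position 0 (ties resolve to the leftmost minimum, with a
    warning).  Returns new profiles; inputs are untouched."""
    out = []
    for p in profiles:
        vals = p.values
        mn = vals.min()
        where = np.flatnonzero(~np.ma.getmaskarray(vals)
                               & (vals.filled(np.inf) == mn))
        if where.size > 1:
            warnings.warn(f"{p.label}: {where.size} bins tie for the PMF "
                          f"minimum; aligning to the leftmost")
        i = int(where[0])
        out.append(PMFProfile(label=p.label, bin_centers=p.bin_centers,
                              values=vals.copy(), temperature=p.temperature,
                              rho0=p.rho0, offset=float(p.bin_centers[i])))
    return out


def opening_energy(profile: PMFProfile, displacement: float) -> float:
    """PMF value (kcal/mol) at ``displacement`` Angstrom past the minimum,
    by linear interpolation between bin centres.

    Raises when the requested point lies outside the contiguously sampled
    region around the minimum ("insufficient sampling").
    """
    pos = profile.positions
    vals = profile.values
    i_min = int(np.ma.argmin(vals))
    target = pos[i_min] + displacement

    mask = np.ma.getmaskarray(vals)
    # contiguous sampled window around the minimum
    lo = i_min
    while lo > 0 and not mask[lo - 1]:
        lo -= 1
    hi = i_min
    while hi < len(pos) - 1 and not mask[hi + 1]:
        hi += 1
    if not (pos[lo] <= target <= pos[hi]):
        raise ValueError(
            f"insufficient sampling for {profile.label!r}: requested "
            f"displacement {displacement:+.2f} A reaches {target:.2f} A but "
            f"the contiguous sampled window around the minimum is "
            f"[{pos[lo]:.2f}, {pos[hi]:.2f}] A")
    return float(np.interp(target, pos[lo:hi + 1],
                           vals[lo:hi + 1].filled(np.nan)))
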