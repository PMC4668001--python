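"""Geometric descriptors of the BC-CT opening.

Three families of observables, all computed per frame from a
:class:`~bcct.structure.Trajectory`:

* Calpha pair distances between each BC-CT residue and its helix anchor
  (the seven tracked pairs from F24-L15 down to T30-G8);
* aromatic-contact distances: centroid of the six ring carbons of a Phe/Tyr
  to the nearest side-chain carbon of a partner residue;
* hydration: waters inside a 9 A sphere around the L15 C-gamma, with the
  closed-state outside-the-sphere baseline of 9 subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (CORE_SPHERE_RADIUS, DEFAULT_FRAME_INTERVAL_PS,
                        TABLE1_PAIRS, TABLE2_CONTACTS, WATER_BASELINE)
from .structure import (AtomSelector, SelectionError, Structure, Trajectory,
                        select_atoms)

__all__ = [
    "DistanceSeries",
    "WaterCountSeries",
    "pair_selectors",
    "ca_distance_series",
    "ring_center",
    "aromatic_contact_series",
    "water_count_series",
    "rmsd_series",
    "table1_summary",
    "table2_summary",
]


@dataclass
class DistanceSeries:
    """Per-frame scalar distance (Angstrom) with timing metadata."""

    label: str
    values: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n_frames > 1 else 0.0


@dataclass
class WaterCountSeries:
    """Raw and baseline-corrected in-sphere water counts per frame."""

    raw: np.ndarray
    baseline: int = WATER_BASELINE
    radius: float = CORE_SPHERE_RADIUS
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS

    @property
    def corrected(self) -> np.ndarray:
        """Core waters after subtracting the outside-sphere baseline,
        clipped at zero."""
        return np.maximum(self.raw - self.baseline, 0)

    @property
    def n_frames(self) -> int:
        return len(self.raw)


def _single_atom(structure: Structure, selector: AtomSelector) -> int:
    idx = select_atoms(structure, selector)
    if idx.size != 1:
        raise SelectionError(
            f"selector must resolve to exactly one atom, got {idx.size}: "
            f"{selector.describe()}")
    return int(idx[0])


def pair_selectors(label: str, chain: str = "B"):
    """Calpha selectors for one of the tracked Table-1 pair labels."""
    for row in TABLE1_PAIRS:
        if row[0] == label:
            _, bcct_resid, helix_resid, *_ = row
            return (AtomSelector(chain, bcct_resid, "CA"),
                    AtomSelector(chain, helix_resid, "CA"))
    known = ", ".join(r[0] for r in TABLE1_PAIRS)
    raise KeyError(f"unknown pair label {label!r}; tracked pairs: {known}")


def ca_distance_series(trajectory: Trajectory,
                       selector_a: AtomSelector | str,
                       selector_b: AtomSelector | None = None,
                       label: str | None = None) -> DistanceSeries:
    """Per-frame distance between two single atoms.

    Either pass two selectors each resolving to exactly one atom, or a
    tracked pair label such as ``"Y26-V12"`` as the first argument.
    """
    if isinstance(selector_a, str):
        label = label or selector_a
        selector_a, selector_b = pair_selectors(selector_a)
    if selector_b is None:
        raise ValueError("two selectors (or a pair label) are required")
    ia = _single_atom(trajectory.structure, selector_a)
    ib = _single_atom(trajectory.structure, selector_b)
    diff = trajectory.frames[:, ia, :] - trajectory.frames[:, ib, :]
    values = np.linalg.norm(diff, axis=1)
    if label is None:
        label = f"{selector_a.describe()} - {selector_b.describe()}"
    return DistanceSeries(label=label, values=values,
                          frame_interval=trajectory.frame_interval)


def ring_center(structure: Structure, coords: np.ndarray,
                chain_id: str, residue_number: int) -> np.ndarray:
    """Centroid of the six aromatic ring carbons of a Phe/Tyr residue."""
    idx = select_atoms(structure, AtomSelector(chain_id, residue_number,
                                               "ring_carbons"))
    if idx.size != 6:
        raise SelectionError(
            f"aromatic ring of chain {chain_id} resid {residue_number} has "
            f"{idx.size} ring carbons; need all 6")
    return coords[idx].mean(axis=0)


def aromatic_contact_series(trajectory: Trajectory,
                            aromatic: tuple[str, int],
                            partner: tuple[str, int],
                            label: str | None = None) -> DistanceSeries:
    """Ring-centroid to nearest partner side-chain carbon, per frame."""
    st = trajectory.structure
    ring_idx = select_atoms(st, AtomSelector(aromatic[0], aromatic[1],
                                             "ring_carbons"))
    if ring_idx.size != 6:
        raise SelectionError(
            f"aromatic ring of chain {aromatic[0]} resid {aromatic[1]} has "
            f"{ring_idx.size} ring carbons; need all 6")
    part_idx = select_atoms(st, AtomSelector(partner[0], partner[1],
                                             "sidechain_carbons"))
    centers = trajectory.frames[:, ring_idx, :].mean(axis=1)
    d = np.linalg.norm(trajectory.frames[:, part_idx, :]
                       - centers[:, None, :], axis=2)
    values = d.min(axis=1)
    if label is None:
        label = (f"{aromatic[0]}{aromatic[1]}/"
                 f"{partner[0]}{partner[1]}")
    return DistanceSeries(label=label, values=values,
                          frame_interval=trajectory.frame_interval)


def water_count_series(trajectory: Trajectory,
                       center: AtomSelector | None = None,
                       radius: float = CORE_SPHERE_RADIUS,
                       baseline: int = WATER_BASELINE) -> WaterCountSeries:
    """Waters with oxygen within ``radius`` of the core centre, per frame.

    The default centre is the L15 C-gamma of chain B.  The sphere boundary
    is inclusive (distance <= radius counts).  A trajectory without water
    gives an all-zero series and a warning rather than an error.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    st = trajectory.structure
    center = center or AtomSelector("B", 15, "CG")
    ic = _single_atom(st, center)
    try:
        wat_idx = select_atoms(st, AtomSelector(atom_names="water_oxygen"))
    except SelectionError:
        warnings.warn("no water molecules in structure; water counts are 0")
        raw = np.zeros(trajectory.n_frames, dtype=int)
        return WaterCountSeries(raw=raw, baseline=baseline, radius=radius,
                                frame_interval=trajectory.frame_interval)
    d = np.linalg.norm(trajectory.frames[:, wat_idx, :]
                       - trajectory.frames[:, ic, None, :], axis=2)
    raw = (d <= radius).sum(axis=1).astype(int)
    return WaterCountSeries(raw=raw, baseline=baseline, radius=radius,
                            frame_interval=trajectory.frame_interval)


def rmsd_series(trajectory: Trajectory,
                selector: AtomSelector | np.ndarray | None = None,
                reference: int | np.ndarray = 0) -> DistanceSeries:
    """Best-fit (superposed) RMSD of a selection against a reference frame.

    ``reference`` is a frame index or explicit coordinates of the selection.
    At least three atoms are required for a meaningful superposition.
    """
    from MDAnalysis.analysis.rms import rmsd as mda_rmsd

    st = trajectory.structure
    if selector is None:
        selector = AtomSelector(atom_names="CA")
    if isinstance(selector, AtomSelector):
        idx = select_atoms(st, selector)
    else:
        idx = np.asarray(selector, dtype=int)
    if idx.size < 3:
        raise SelectionError(
            f"RMSD superposition needs at least 3 atoms, got {idx.size}")
    if isinstance(reference, (int, np.integer)):
        ref = trajectory.frames[int(reference), idx, :]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (idx.size, 3):
            raise ValueError(
                f"reference coordinates must have shape ({idx.size}, 3)")
    values = np.array([
        mda_rmsd(trajectory.frames[f, idx, :], ref, center=True,
                 superposition=True)
        for f in range(trajectory.n_frames)])
    return DistanceSeries(label="rmsd", values=values,
                          frame_interval=trajectory.frame_interval)


def table1_summary(trajectory: Trajectory, chain: str = "B"):
    """Calpha distances for all tracked pairs: first-frame value plus the
    mean and SD over all frames.  Returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for label, *_ in TABLE1_PAIRS:
        s = ca_distance_series(trajectory, label)
        rows.append({"pair": label,
                     "frame0_A": float(s.values[0]),
                     "mean_A": s.mean(),
                     "sd_A": s.sd()})
    return pd.DataFrame(rows)


def table2_summary(trajectory: Trajectory):
    """Aromatic-contact distances for the four tracked contacts."""
    import pandas as pd

    rows = []
    for label, ar_ch, ar_res, p_ch, p_res, *_ in TABLE2_CONTACTS:
        s = aromatic_contact_series(trajectory, (ar_ch, ar_res),
                                    (p_ch, p_res), label=label)
        rows.append({"contact": label,
                     "frame0_A": float(s.values[0]),
                     "mean_A": s.mean(),
                     "sd_A": s.sd()})
    return pd.DataFrame(rows)
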