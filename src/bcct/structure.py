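"""Structure and trajectory reading with the insulin chain conventions.

PDB parsing (fixed columns, MODEL/ENDMDL multi-frame) is delegated to
MDAnalysis; this module flattens the result into a plain atom table plus a
(n_models, n_atoms, 3) coordinate stack, applies the deterministic altloc
policy (keep blank or 'A'), and resolves the residue/atom selections used by
the descriptor layer: per-chain author numbering, with chain "B" holding the
B1-B30 residues and chain "A" the A1-A21 residues (configurable through a
chain map).
"""

from __future__ import annotations

import io
import os
import tempfile
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Structure",
    "AtomSelector",
    "Trajectory",
    "SelectionError",
    "read_structure",
    "select_atoms",
    "read_trajectory",
    "read_precomputed_series",
    "RING_CARBON_NAMES",
    "WATER_RESNAMES",
]

RING_CARBON_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
AROMATIC_RESNAMES = ("PHE", "TYR")
WATER_RESNAMES = ("HOH", "TIP3", "WAT", "SOL", "SPC", "TIP")
#: backbone carbons excluded by the `sidechain_carbons` category
_BACKBONE_CARBONS = ("CA", "C")

CATEGORIES = ("CA", "CG", "ring_carbons", "sidechain_carbons", "water_oxygen")


class SelectionError(ValueError):
    """An atom selection resolved to no atoms or an invalid residue type."""


@dataclass
class Structure:
    """Flat atom table with one or more coordinate models.

    All models share the same atom list and ordering; coordinates are in
    Angstrom.
    """

    serials: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    icodes: np.ndarray
    elements: np.ndarray
    models: np.ndarray          # (n_models, n_atoms, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def coordinates(self) -> np.ndarray:
        """First-model coordinates (the crystal geometry for single-model
        structures)."""
        return self.models[0]

    def chain_residues(self, chain_id: str) -> np.ndarray:
        return np.unique(self.resids[self.chains == chain_id])


@dataclass(frozen=True)
class AtomSelector:
    """Chain + residue number + atom names or a named category.

    ``atom_names`` is either an explicit tuple of PDB atom names or one of
    the categories: ``CA`` (the alpha-carbon), ``CG`` (the gamma-carbon),
    ``ring_carbons`` (the six Phe/Tyr ring atoms), ``sidechain_carbons``
    (carbons excluding backbone CA/C) and ``water_oxygen`` (oxygen atoms of
    water residues; chain/residue ignored unless given).
    """

    chain_id: str | None = None
    residue_number: int | None = None
    atom_names: tuple[str, ...] | str = "CA"

    def describe(self) -> str:
        names = (self.atom_names if isinstance(self.atom_names, str)
                 else "+".join(self.atom_names))
        return f"chain {self.chain_id} resid {self.residue_number} [{names}]"


def _element_of(name: str, element: str) -> str:
    if element and element.strip():
        return element.strip().upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _universe_from_source(pdb_source):
    import MDAnalysis as mda

    text = None
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
    elif isinstance(pdb_source, str) and "\n" in pdb_source:
        text = pdb_source
    if text is not None:
        tmp = tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False)
        try:
            tmp.write(text)
            tmp.close()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(tmp.name, in_memory=True)
        finally:
            os.unlink(tmp.name)
        return u
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(pdb_source), in_memory=True)


def read_structure(pdb_source) -> Structure:
    """Parse PDB text (path, text string or file-like) into a Structure.

    Multi-model files become multiple coordinate models over the same atom
    list.  Alternate locations other than blank/'A' are dropped; waters are
    retained.
    """
    try:
        u = _universe_from_source(pdb_source)
    except Exception as exc:  # surface parser context
        raise ValueError(f"could not parse PDB input: {exc}") from exc

    atoms = u.atoms
    if hasattr(atoms, "altLocs"):
        keep = np.isin(atoms.altLocs, ("", "A"))
        atoms = atoms[keep]
    if atoms.n_atoms == 0:
        raise ValueError("PDB input contains no atoms")

    frames = []
    for _ in u.trajectory:
        frames.append(atoms.positions.astype(float).copy())
    models = np.stack(frames)
    if not np.isfinite(models).all():
        raise ValueError("non-finite coordinates in PDB input")

    names = atoms.names.astype(str)
    try:
        elements = atoms.elements.astype(str)
    except Exception:
        elements = np.array([""] * atoms.n_atoms)
    elements = np.array([_element_of(n, e) for n, e in zip(names, elements)])
    try:
        icodes = atoms.icodes.astype(str)
    except Exception:
        icodes = np.array([""] * atoms.n_atoms)
    try:
        chains = atoms.chainIDs.astype(str)
    except Exception:
        chains = atoms.segids.astype(str)

    return Structure(
        serials=atoms.ids.astype(int),
        names=names,
        resnames=atoms.resnames.astype(str),
        resids=atoms.resids.astype(int),
        chains=chains,
        icodes=icodes,
        elements=elements,
        models=models,
    )


def select_atoms(structure: Structure, selector: AtomSelector) -> np.ndarray:
    """Resolve a selector to a sorted array of atom indices.

    Raises :class:`SelectionError` when nothing matches or when a category
    is invalid for the residue (e.g. ring carbons of a glycine).
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    if selector.chain_id is not None:
        mask &= structure.chains == selector.chain_id
    if selector.residue_number is not None:
        mask &= structure.resids == selector.residue_number

    names = selector.atom_names
    if isinstance(names, str):
        if names == "CA":
            mask &= structure.names == "CA"
        elif names == "CG":
            mask &= structure.names == "CG"
        elif names == "ring_carbons":
            resnames = set(structure.resnames[mask])
            if resnames and not resnames <= set(AROMATIC_RESNAMES):
                raise SelectionError(
                    f"ring_carbons is only valid for Phe/Tyr; "
                    f"{selector.describe()} matches {sorted(resnames)}")
            mask &= np.isin(structure.names, RING_CARBON_NAMES)
        elif names == "sidechain_carbons":
            mask &= (structure.elements == "C") & ~np.isin(
                structure.names, _BACKBONE_CARBONS)
        elif names == "water_oxygen":
            mask &= np.isin(structure.resnames, WATER_RESNAMES)
            mask &= structure.elements == "O"
        else:
            mask &= structure.names == names
    else:
        mask &= np.isin(structure.names, tuple(names))

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection matched no atoms: "
                             f"{selector.describe()}")
    return idx


@dataclass
class Trajectory:
    """Frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3); ``frame_interval`` is the
    recording interval in ps (metadata only).
    """

    structure: Structure
    frames: np.ndarray
    frame_interval: float = 10.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)


def _parse_xyz_stream(text: str, n_atoms: int) -> np.ndarray:
    """Minimal XYZ frame stream: repeated blocks of `n_atoms` lines with
    ``label x y z`` (an optional count/comment header per block is
    accepted)."""
    frames = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    frame_no = 0
    while i < len(lines):
        # optional "<count>" header followed by a comment line
        if lines[i].split()[0].isdigit() and int(lines[i].split()[0]) == n_atoms:
            i += 2
        block = lines[i:i + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(
                f"frame {frame_no}: expected {n_atoms} atoms, "
                f"got {len(block)}")
        coords = []
        for ln in block:
            parts = ln.split()
            coords.append([float(x) for x in parts[-3:]])
        frames.append(coords)
        i += n_atoms
        frame_no += 1
    if not frames:
        raise ValueError("empty frame source")
    return np.asarray(frames, dtype=float)


def read_trajectory(topology: Structure, frames_source=None,
                    frame_interval: float = 10.0) -> Trajectory:
    """Attach frames to a topology.

    ``frames_source`` may be None (use the topology's own models), an
    ndarray of shape (n_frames, n_atoms, 3), or XYZ-format text (string or
    file-like).  Atom counts are validated per frame.
    """
    if frames_source is None:
        frames = topology.models
    elif isinstance(frames_source, np.ndarray):
        frames = frames_source
    else:
        text = (frames_source.read() if hasattr(frames_source, "read")
                else str(frames_source))
        if "\n" not in text and os.path.exists(text):
            with open(text) as fh:
                text = fh.read()
        frames = _parse_xyz_stream(text, topology.n_atoms)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("empty frame source")
    if frames.shape[1] != topology.n_atoms:
        raise ValueError(
            f"frame atom count {frames.shape[1]} does not match topology "
            f"({topology.n_atoms} atoms)")
    return Trajectory(structure=topology, frames=frames,
                      frame_interval=frame_interval)


def read_precomputed_series(csv_source):
    """Precomputed-series adapter: a CSV with columns
    ``frame, time_ps, <pair label>, ...`` (optionally ``water_count``,
    ``true_state``) is admitted directly, bypassing geometry.

    Returns ``(series: {label: ndarray}, water_counts or None,
    frame_interval)``.
    """
    import pandas as pd

    df = pd.read_csv(csv_source)
    special = {"frame", "time_ps", "water_count", "true_state", "phase"}
    labels = [c for c in df.columns if c not in special]
    if not labels:
        raise ValueError("no series columns found in CSV")
    if "time_ps" in df.columns and len(df) > 1:
        frame_interval = float(df["time_ps"].iloc[1] - df["time_ps"].iloc[0])
    else:
        frame_interval = 10.0
    series = {lab: df[lab].to_numpy(dtype=float) for lab in labels}
    water = (df["water_count"].to_numpy(dtype=int)
             if "water_count" in df.columns else None)
    return series, water, frame_interval
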