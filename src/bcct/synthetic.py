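"""Synthetic trajectories with the statistical structure of BC-CT opening.

The all-atom dynamics of insulin's B-chain C-terminal detachment are emulated
by overdamped Langevin motion on the seven residue-pair distance coordinates
that track the opening (F24-L15 ... T30-G8).  Each coordinate moves on a
multi-well 1-D landscape written as a log-sum of Gaussian wells,

    U_i(x) = -kT ln sum_j exp(D_j/kT) exp(-(x - c_j)^2 / (2 w_j^2)),

so that a well's depth D_j (kcal/mol) and width w_j (A) translate directly
into the Boltzmann weight and spread of its basin.  Adjacent coordinates are
coupled by a barrier-lowering term -C sig_i(x_i) sig_{i+1}(x_{i+1}) (sigmoid
switches centred on the open thresholds), which produces the zipper-like
ordering of openings: an outer coordinate being open lowers the effective
barrier of its inner neighbour.

A gated immigration-death process emulates water entry into the hydrophobic
core: entries occur only while the Y26-V12 gate coordinate is past its open
threshold, and a small residual population (2-3 waters) persists in the
closed state.

The module also writes toy multi-model PDB fixtures, including a synthetic
reference structure whose geometry reproduces the published crystal-structure
distances of the insulin core by construction (see
:func:`write_reference_structure`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import (
    DEFAULT_FRAME_INTERVAL_PS,
    DEFAULT_FRICTION_PS,
    DEFAULT_TEMPERATURE,
    KB_KCAL_MOL_K,
    PAIR_LABELS,
    PRIMARY_PAIR,
    STATE_NAMES,
    TABLE1_PAIRS,
)

__all__ = [
    "Well",
    "CoordinateLandscape",
    "LandscapeModel",
    "WaterProcessParams",
    "SyntheticTrajectory",
    "build_landscape",
    "simulate_langevin",
    "simulate_water_process",
    "simulate_trajectory",
    "stationary_marginals",
    "threshold_occupancies",
    "barrier_heights",
    "write_toy_structure",
    "write_reference_structure",
    "PRESETS",
]


# --------------------------------------------------------------------------
# landscape model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    """One Gaussian well: centre (A), depth (kcal/mol), width (A)."""

    center: float
    depth: float
    width: float


@dataclass(frozen=True)
class CoordinateLandscape:
    """Multi-well landscape of a single distance coordinate."""

    label: str
    wells: tuple[Well, ...]
    theta_open: float
    theta_wide: float
    #: mutant presets may deliberately break the zipper ordering on this
    #: coordinate (e.g. the hinge coordinate with its closed well removed)
    exempt_from_zipper: bool = False


@dataclass(frozen=True)
class LandscapeModel:
    """The full zipper landscape: coordinates in hinge-to-terminus order."""

    coordinates: tuple[CoordinateLandscape, ...]
    coupling_strength: float = 1.2      # kcal/mol
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = DEFAULT_FRICTION_PS
    switch_width: float = 0.3           # A, width of the coupling sigmoids
    primary: str = PRIMARY_PAIR

    @property
    def kT(self) -> float:
        return KB_KCAL_MOL_K * self.temperature

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.coordinates]

    def coordinate(self, label: str) -> CoordinateLandscape:
        for c in self.coordinates:
            if c.label == label:
                return c
        raise KeyError(f"no coordinate labelled {label!r}")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    # -- potential -------------------------------------------------------

    def potential(self, label_or_index, x):
        """Single-coordinate potential U_i(x) in kcal/mol (vectorised)."""
        i = (label_or_index if isinstance(label_or_index, int)
             else self.index(label_or_index))
        coord = self.coordinates[i]
        x = np.asarray(x, dtype=float)
        kT = self.kT
        logs = np.stack([
            w.depth / kT - 0.5 * ((x - w.center) / w.width) ** 2
            for w in coord.wells
        ])
        m = logs.max(axis=0)
        return -kT * (m + np.log(np.exp(logs - m).sum(axis=0)))

    def grid(self, i: int, padding: float = 4.0, n: int = 1201) -> np.ndarray:
        coord = self.coordinates[i]
        lo = min(w.center - padding * w.width for w in coord.wells)
        hi = max(w.center + padding * w.width for w in coord.wells)
        return np.linspace(max(lo, 0.5), hi, n)

    # -- arrays for the jitted kernel ------------------------------------

    def _well_arrays(self):
        n = len(self.coordinates)
        mx = max(len(c.wells) for c in self.coordinates)
        c_arr = np.zeros((n, mx))
        w_arr = np.ones((n, mx))
        lw_arr = np.zeros((n, mx))
        n_wells = np.zeros(n, dtype=np.int64)
        kT = self.kT
        for i, coord in enumerate(self.coordinates):
            n_wells[i] = len(coord.wells)
            for j, w in enumerate(coord.wells):
                c_arr[i, j] = w.center
                w_arr[i, j] = w.width
                lw_arr[i, j] = w.depth / kT
        sw_c = np.array([c.theta_open for c in self.coordinates])
        return c_arr, w_arr, lw_arr, n_wells, sw_c

    def max_curvature(self) -> float:
        """Upper bound on |U''| over all coordinates (kcal/mol/A^2)."""
        worst = 0.0
        for i in range(len(self.coordinates)):
            g = self.grid(i)
            u = self.potential(i, g)
            d2 = np.diff(u, 2) / (g[1] - g[0]) ** 2
            worst = max(worst, float(np.abs(d2).max()))
        # coupling sigmoids contribute at most C * max|sig''| per neighbour
        worst += 2.0 * abs(self.coupling_strength) * 0.0962 / self.switch_width ** 2
        return worst


def barrier_heights(model: LandscapeModel) -> list[float]:
    """Escape barrier out of the first (most closed) well per coordinate.

    Height of the highest point between the first two well centres, measured
    from the basin minimum around the first well.  Coordinates with a single
    well report 0.
    """
    out = []
    for i, coord in enumerate(model.coordinates):
        if len(coord.wells) < 2:
            out.append(0.0)
            continue
        c0, c1 = coord.wells[0].center, coord.wells[1].center
        g = np.linspace(c0 - coord.wells[0].width, c1, 2001)
        u = model.potential(i, g)
        basin = u[g <= c0 + 0.5 * (c1 - c0)].min()
        between = u[(g >= c0) & (g <= c1)].max()
        out.append(float(between - basin))
    return out


def _validate_model(model: LandscapeModel) -> None:
    for coord in model.coordinates:
        centers = [w.center for w in coord.wells]
        if any(w.width <= 0 for w in coord.wells):
            raise ValueError(f"{coord.label}: well widths must be > 0")
        if any(w.depth < 0 for w in coord.wells):
            raise ValueError(f"{coord.label}: well depths must be >= 0")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError(
                f"{coord.label}: well centers must be strictly increasing, "
                f"got {centers}")
        if not (0 < coord.theta_open < coord.theta_wide):
            raise ValueError(
                f"{coord.label}: need 0 < theta_open < theta_wide")
    # zipper ordering: escape barriers non-decreasing from the last
    # coordinate (T30-G8) towards the hinge (F24-L15)
    heights = barrier_heights(model)
    prev = None
    for coord, h in zip(model.coordinates, heights):
        if coord.exempt_from_zipper:
            continue
        if prev is not None and h > prev + 1e-9:
            raise ValueError(
                f"zipper ordering violated at coordinate {coord.label}: "
                f"barrier {h:.3f} kcal/mol exceeds its inner neighbour's "
                f"{prev:.3f} kcal/mol")
        prev = h
    if model.friction <= 0:
        raise ValueError("friction must be > 0")
    if model.temperature < 0:
        raise ValueError("temperature must be >= 0")


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

# Per-coordinate geometry: (label, centers, widths, (theta_open, theta_wide)).
# Closed-well centres sit at the closed-state mean distances of the seven
# pairs; widths grow from the hinge to the terminus so the opening stiffness
# decreases along the zipper.
_GEOMETRY = [
    ("F24-L15", (7.0, 9.4, 11.8), (0.40, 0.65, 0.80), (8.2, 10.4)),
    ("F25-L15", (9.4, 11.1, 13.5), (0.44, 0.75, 0.95), (10.4, 12.5)),
    ("Y26-V12", (8.1, 10.0, 11.7), (0.50, 0.70, 0.95), (8.7, 10.7)),
    ("T27-V12", (10.5, 11.8, 14.3), (0.68, 0.90, 1.10), (11.4, 13.3)),
    ("P28-G8", (8.9, 11.0, 15.6), (1.20, 1.05, 1.30), (9.5, 15.0)),
    ("L29-G8", (12.3, 14.2, 16.6), (0.95, 1.20, 1.40), (13.3, 15.4)),
    ("T30-G8", (13.8, 15.6, 18.0), (1.10, 1.30, 1.50), (14.7, 16.8)),
]

# Well depths (kcal/mol) per preset.  The Y26-V12 depths are calibrated
# against the exact stationary distribution of the coupled chain
# (transfer-operator quadrature, see `stationary_marginals`) so that its
# threshold occupancies equal the target conformational probabilities:
# WT (0.64, 0.31, 0.05), wide-open-dominant mutant (0.07, 0.05, 0.88).
# Outer coordinates open progressively more easily and their escape barriers
# decrease strictly from the hinge to the terminus (the zipper ordering);
# with this table the barriers are approximately
# (3.0, 2.2, 1.9, 0.89, 0.83, 0.66, 0.30) kcal/mol.
_WT_DEPTHS = {
    "F24-L15": (4.94, 2.45, 0.0),
    "F25-L15": (3.69, 1.39, 0.0),
    "Y26-V12": (3.1627, 1.3826, 0.0),
    "T27-V12": (2.30, 0.70, 0.0),
    "P28-G8": (2.20, 0.85, 0.46),
    "L29-G8": (2.95, 2.27, 0.0),
    "T30-G8": (2.31, 1.85, 0.0),
}

_PRESET_NAMES = ("WT", "Y26G", "F24E")


# Per-preset overrides: {label: (centers, widths, depths)}.  The Y26G
# mutant's gate coordinate opens wider than WT (deep wide-open well pushed
# out to 12.3 A, occupancies calibrated to (0.07, 0.05, 0.88)); the F24E
# mutant loses the closed well of the hinge coordinate entirely, so a broken
# hinge cannot reform.  Both modifications deliberately break the WT zipper
# ordering on the mutated coordinate.
_PRESET_OVERRIDES = {
    "WT": {},
    "Y26G": {
        "Y26-V12": ((8.1, 9.8, 12.3), (0.55, 0.60, 0.80), (2.1454, 0.0, 2.6095)),
    },
    "F24E": {
        "F24-L15": ((9.4, 11.8), (0.65, 0.80), (0.0, 4.0)),
    },
}


def _preset_model(name: str, **overrides) -> LandscapeModel:
    key = name.upper().replace("-LIKE", "")
    if key not in _PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {_PRESET_NAMES}")
    special = _PRESET_OVERRIDES[key]
    coords = []
    for label, centers, widths, (t_open, t_wide) in _GEOMETRY:
        if label in special:
            centers, widths, depths = special[label]
        else:
            depths = _WT_DEPTHS[label]
        wells = tuple(Well(c, d, w)
                      for c, d, w in zip(centers, depths, widths))
        coords.append(CoordinateLandscape(
            label, wells, t_open, t_wide,
            exempt_from_zipper=label in special))
    return LandscapeModel(coordinates=tuple(coords), **overrides)


class PRESETS:
    """Names of the bundled landscape presets."""

    names = _PRESET_NAMES


def build_landscape(preset: str | None = None, *,
                    coordinates=None, **params) -> LandscapeModel:
    """Build and validate a :class:`LandscapeModel`.

    Either name a bundled preset (``"WT"``, ``"Y26G"``, ``"F24E"``) or pass
    an explicit ``coordinates`` tuple.  Extra keyword arguments override
    model-level parameters (coupling_strength, temperature, friction, ...).
    """
    if (preset is None) == (coordinates is None):
        raise ValueError("pass exactly one of `preset` or `coordinates`")
    if preset is not None:
        model = _preset_model(preset, **params)
    else:
        model = LandscapeModel(coordinates=tuple(coordinates), **params)
    _validate_model(model)
    return model


# --------------------------------------------------------------------------
# exact stationary distribution (transfer-operator quadrature)
# --------------------------------------------------------------------------

def stationary_marginals(model: LandscapeModel, n_grid: int = 801,
                         padding: float = 4.0):
    """Exact single-coordinate marginals of the coupled chain's Boltzmann
    distribution, by transfer-operator quadrature along the chain.

    Returns ``{label: (grid, density)}`` with each density normalised to
    unit integral on its grid.  Because the coupling is nearest-neighbour,
    the 7-D Boltzmann integral factorises into matrix products and the
    marginals are exact up to grid resolution.
    """
    kT = model.kT
    n = len(model.coordinates)
    grids = [model.grid(i, padding, n_grid) for i in range(n)]
    psis = [np.exp(-(model.potential(i, g) - model.potential(i, g).min()) / kT)
            for i, g in enumerate(grids)]
    sigs = [1.0 / (1.0 + np.exp(-(g - c.theta_open) / model.switch_width))
            for g, c in zip(grids, model.coordinates)]

    def pair_factor(i):
        # exp(+C sig_i sig_{i+1} / kT), shape (len_i, len_{i+1})
        return np.exp(model.coupling_strength / kT
                      * np.outer(sigs[i], sigs[i + 1]))

    # forward messages
    alphas = [psis[0]]
    for i in range(1, n):
        dx = grids[i - 1][1] - grids[i - 1][0]
        a = (alphas[-1] * dx) @ pair_factor(i - 1) * psis[i]
        alphas.append(a / a.max())
    # backward messages
    betas = [np.ones_like(grids[-1])]
    for i in range(n - 2, -1, -1):
        dx = grids[i + 1][1] - grids[i + 1][0]
        b = pair_factor(i) @ (psis[i + 1] * betas[0] * dx)
        betas.insert(0, b / b.max())

    out = {}
    for i, coord in enumerate(model.coordinates):
        p = alphas[i] * betas[i]
        dx = grids[i][1] - grids[i][0]
        p = p / (p.sum() * dx)
        out[coord.label] = (grids[i], p)
    return out


def threshold_occupancies(model: LandscapeModel, label: str | None = None,
                          n_grid: int = 801) -> tuple[float, float, float]:
    """Exact (closed, open, wide_open) probabilities of one coordinate under
    the model's stationary distribution, split at its thresholds."""
    label = label or model.primary
    coord = model.coordinate(label)
    g, p = stationary_marginals(model, n_grid)[label]
    dx = g[1] - g[0]
    closed = p[g < coord.theta_open].sum() * dx
    open_ = p[(g >= coord.theta_open) & (g < coord.theta_wide)].sum() * dx
    wide = p[g >= coord.theta_wide].sum() * dx
    total = closed + open_ + wide
    return closed / total, open_ / total, wide / total


# --------------------------------------------------------------------------
# Langevin simulation
# --------------------------------------------------------------------------

@dataclass
class SyntheticTrajectory:
    """Distance series per coordinate plus ground truth from the generator."""

    frame_interval: float                       # ps
    series: dict[str, np.ndarray]               # label -> A per frame
    true_states: np.ndarray                     # per-frame label strings
    seed: int
    water_counts: np.ndarray | None = None      # core waters per frame
    phase: np.ndarray | None = None             # 'biased'/'free', restraints
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.series.values())))

    def to_frame(self):
        """Ground-truth table as a pandas DataFrame."""
        import pandas as pd

        data = {"frame": np.arange(self.n_frames),
                "time_ps": np.arange(self.n_frames) * self.frame_interval}
        for label, values in self.series.items():
            data[label] = values
        if self.water_counts is not None:
            data["water_count"] = self.water_counts
        data["true_state"] = self.true_states
        if self.phase is not None:
            data["phase"] = self.phase
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_params_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed,
                       "frame_interval_ps": self.frame_interval,
                       **self.params}, fh, indent=2, default=str)


def _classify(values: np.ndarray, theta_open: float,
              theta_wide: float) -> np.ndarray:
    codes = np.ones(len(values), dtype=np.int64)
    codes[values < theta_open] = 0
    codes[values >= theta_wide] = 2
    return codes


def simulate_langevin(model: LandscapeModel, n_frames: int, dt: float = 0.1,
                      seed: int = 0, frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
                      start: np.ndarray | None = None,
                      bias_k: np.ndarray | None = None,
                      bias_r0: np.ndarray | None = None) -> SyntheticTrajectory:
    """Overdamped Euler-Maruyama dynamics on the zipper landscape.

    One frame is recorded every ``frame_interval`` ps (``frame_interval/dt``
    integration steps).  ``bias_k``/``bias_r0`` add a half-harmonic repulsive
    restraint per coordinate (used by the hinge-breaking protocol).
    Identical arguments and seed give bit-identical trajectories.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _validate_model(model)
    n = len(model.coordinates)
    kappa = model.max_curvature()
    if bias_k is not None:
        kappa += float(np.max(bias_k))
    if dt * kappa / model.friction >= 0.5:
        raise ValueError(
            f"unstable time step: dt * max_curvature / friction = "
            f"{dt * kappa / model.friction:.2f} >= 0.5; "
            f"need dt < {0.5 * model.friction / kappa:.4f} ps")
    stride = max(1, int(round(frame_interval / dt)))
    c_arr, w_arr, lw_arr, n_wells, sw_c = model._well_arrays()
    if start is None:
        start = np.array([c.wells[0].center for c in model.coordinates])
    bk = np.zeros(n) if bias_k is None else np.asarray(bias_k, dtype=float)
    br = np.zeros(n) if bias_r0 is None else np.asarray(bias_r0, dtype=float)

    frames, ok, bad = _kernels.langevin_chain(
        np.asarray(start, dtype=float), n_frames, stride, dt,
        model.friction, model.kT, c_arr, w_arr, lw_arr, n_wells,
        model.coupling_strength, sw_c, model.switch_width, bk, br,
        int(seed) % (2 ** 31))
    if not ok:
        raise FloatingPointError(
            f"non-finite coordinate encountered at frame {bad}")

    series = {c.label: frames[:, i].copy()
              for i, c in enumerate(model.coordinates)}
    gate = model.coordinate(model.primary)
    codes = _classify(series[model.primary], gate.theta_open, gate.theta_wide)
    return SyntheticTrajectory(
        frame_interval=frame_interval,
        series=series,
        true_states=np.array(STATE_NAMES, dtype=object)[codes],
        seed=seed,
        params={"preset_dt_ps": dt, "n_frames": n_frames,
                "coupling_strength": model.coupling_strength,
                "temperature": model.temperature,
                "friction": model.friction})


# --------------------------------------------------------------------------
# water process
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterProcessParams:
    """Gated immigration-death process for core waters.

    ``on_rate``/``off_rate`` (per ps) set the entry flux while the gate
    coordinate is past its threshold and the per-water exit rate; the
    stationary mean of the gated component is on_rate/off_rate (about half a
    dozen with the defaults).  ``residual_mean`` waters persist regardless of
    the gate (the core always retains 2-3).  Total counts are capped at
    ``capacity``.
    """

    on_rate: float = 2.4
    off_rate: float = 0.4
    residual_mean: float = 2.5
    capacity: int = 12

    def __post_init__(self):
        if self.on_rate < 0 or self.off_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.residual_mean <= self.capacity):
            raise ValueError("need 0 <= residual_mean <= capacity")

    @property
    def residual_cap(self) -> int:
        return min(self.capacity, int(math.ceil(self.residual_mean)) + 1)


def simulate_water_process(gate_series: np.ndarray,
                           params: WaterProcessParams,
                           dt: float, seed: int = 0,
                           gate_threshold: float = 8.7) -> np.ndarray:
    """Integer core-water counts driven by the gate coordinate.

    ``dt`` is the time between consecutive gate samples (the frame interval,
    ps).  The per-frame transition is the exact immigration-death update:
    survivors are binomial with survival probability exp(-off_rate * dt) and
    arrivals are Poisson with the matching stationary mean, gated on
    ``gate > gate_threshold`` for the entry component.
    """
    gate = np.asarray(gate_series, dtype=float)
    if gate.size == 0:
        raise ValueError("gate_series must be non-empty")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if params.off_rate == 0:
        raise ValueError("off_rate must be > 0 for a stationary water count")
    survive = math.exp(-params.off_rate * dt)
    entry_lam = params.on_rate / params.off_rate
    entry_cap = max(params.capacity - params.residual_cap, 0)
    counts = _kernels.water_process(
        gate, gate_threshold, entry_lam, entry_cap,
        params.residual_mean, params.residual_cap, survive,
        int(seed) % (2 ** 31),
        0, min(int(round(params.residual_mean)), params.residual_cap))
    return counts


def simulate_trajectory(model: LandscapeModel, n_frames: int, seed: int = 0,
                        dt: float = 0.1,
                        frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
                        water_params: WaterProcessParams | None = None,
                        ) -> SyntheticTrajectory:
    """Langevin trajectory plus the coupled water-count process.

    The water process is gated on the primary (Y26-V12) coordinate at its
    open threshold, and is seeded from a fixed offset of ``seed`` so the two
    noise sources are independent but jointly reproducible.
    """
    traj = simulate_langevin(model, n_frames, dt=dt, seed=seed,
                             frame_interval=frame_interval)
    params = water_params or WaterProcessParams()
    gate = model.coordinate(model.primary)
    traj.water_counts = simulate_water_process(
        traj.series[model.primary], params, frame_interval,
        seed=seed + 10007, gate_threshold=gate.theta_open)
    traj.params["water_params"] = params.__dict__.copy()
    return traj


# --------------------------------------------------------------------------
# toy structures
# --------------------------------------------------------------------------

_B_SEQ = {8: "GLY", 9: "SER", 10: "HIS", 11: "LEU", 12: "VAL", 13: "GLU",
          14: "ALA", 15: "LEU", 16: "TYR", 17: "LEU", 18: "VAL", 19: "CYS",
          20: "GLY", 21: "GLU", 22: "ARG", 23: "GLY", 24: "PHE", 25: "PHE",
          26: "TYR", 27: "THR", 28: "PRO", 29: "LEU", 30: "THR"}
_A_SEQ = {1: "GLY", 2: "ILE", 3: "VAL", 4: "GLU", 5: "GLN", 6: "CYS",
          7: "CYS", 8: "THR", 9: "SER", 10: "ILE", 11: "CYS", 12: "SER",
          13: "LEU", 14: "TYR", 15: "GLN", 16: "LEU", 17: "GLU", 18: "ASN",
          19: "TYR", 20: "CYS", 21: "ASN"}

RING_ATOM_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _two_spheres(c1, r1, c2, r2, hint):
    """A point at distance r1 from c1 and r2 from c2, closest to `hint`."""
    c1, c2, hint = map(np.asarray, (c1, c2, hint))
    d = np.linalg.norm(c2 - c1)
    if not (abs(r1 - r2) <= d <= r1 + r2):
        raise ValueError(f"spheres do not intersect: d={d:.2f}, r1={r1}, r2={r2}")
    ex = _unit(c2 - c1)
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = math.sqrt(max(r1 * r1 - a * a, 0.0))
    centre = c1 + a * ex
    # basis of the intersection circle's plane
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ex @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(ex, ref))
    e2 = np.cross(ex, e1)
    best, best_d = None, np.inf
    for t in np.linspace(0, 2 * math.pi, 721):
        p = centre + h * (math.cos(t) * e1 + math.sin(t) * e2)
        dist = np.linalg.norm(p - hint)
        if dist < best_d:
            best, best_d = p, dist
    return best


def _helix(r, base=np.zeros(3), radius=2.3, rise=1.5, turn_deg=100.0,
           start=8):
    ang = math.radians(turn_deg * (r - start))
    return base + np.array([radius * math.cos(ang), radius * math.sin(ang),
                            rise * (r - start)])


def _ring(center, normal, radius=1.39):
    n = _unit(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(n, ref))
    e2 = np.cross(n, e1)
    pts = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        pts.append(center + radius * (math.cos(ang) * e1 + math.sin(ang) * e2))
    return pts


def _build_reference_geometry():
    """Atom list (chain, resid, resname, atom name, xyz) whose Table 1/2
    distances equal the published crystal values by construction."""
    ca_b = {r: _helix(r) for r in range(8, 20)}

    # L15 side chain points radially outward; the F24 ring centre lies on
    # the same ray so the ring-to-nearest-carbon contact is exactly 5.2 A
    # (to L15 CG; all other L15 carbons are farther by construction).
    u15 = _unit([ca_b[15][0], ca_b[15][1], 0.0])
    l15_cb = ca_b[15] + 1.53 * u15
    l15_cg = ca_b[15] + 2.55 * u15
    perp15 = _unit(np.cross(u15, [0, 0, 1]))
    l15_cd1 = l15_cg + 1.53 * perp15
    l15_cd2 = l15_cg - 1.53 * perp15
    ring_f24_c = ca_b[15] + (2.55 + 5.2) * u15

    # Y26 ring centre: 3.8 A from V12's CB and 5.2 A from L11's CB, both of
    # which sit on the ray from their own CA towards the ring centre.
    ring_y26_c = _two_spheres(ca_b[12], 3.8 + 1.54, ca_b[11], 5.2 + 1.54,
                              hint=np.array([8.0, 0.0, 4.0]))
    v12_cb = ca_b[12] + 1.54 * _unit(ring_y26_c - ca_b[12])
    away12 = _unit(ca_b[12] - ring_y26_c)
    v12_cg1 = ca_b[12] + 2.5 * _unit(away12 + np.array([0, 0, 0.5]))
    v12_cg2 = ca_b[12] + 2.5 * _unit(away12 + np.array([0, 0, -0.5]))
    l11_cb = ca_b[11] + 1.54 * _unit(ring_y26_c - ca_b[11])
    away11 = _unit(ca_b[11] - ring_y26_c)
    l11_cg = ca_b[11] + 2.6 * _unit(away11 + np.array([0, 0, 0.4]))
    l11_cd1 = l11_cg + 1.53 * _unit([0, 0, 1.0])
    l11_cd2 = l11_cg + 1.53 * _unit(away11)

    # I2 of chain A: its CB is 5.2 A from the Y26 ring centre
    u_a = _unit(np.array([0.35, -0.85, -0.4]))
    i2_ca = ring_y26_c + (5.2 + 1.54) * u_a
    i2_cb = i2_ca + 1.54 * _unit(ring_y26_c - i2_ca)
    i2_cg1 = i2_ca + 2.5 * _unit(u_a + np.array([0, 0, -0.6]))
    i2_cg2 = i2_ca + 2.5 * _unit(u_a + np.array([0.5, 0, 0]))
    i2_cd1 = i2_ca + 3.3 * _unit(u_a + np.array([0, 0, -0.8]))
    ca_a = {r: i2_ca + (r - 2) * 3.8 * u_a for r in range(1, 22)}

    # BC-CT alpha-carbons: each placed at its published crystal distance
    # from the helix anchor, chained with ~3.8 A virtual bonds
    ca_f24 = _two_spheres(ca_b[15], 6.7, ring_f24_c, 4.2,
                          hint=ring_f24_c + np.array([0, 0, -4.0]))
    ca_f25 = _two_spheres(ca_b[15], 8.5, ca_f24, 3.8,
                          hint=ca_f24 + np.array([2.0, 2.0, -2.0]))
    ca_y26 = _two_spheres(ca_b[12], 7.2, ring_y26_c, 4.2,
                          hint=ca_f25 + np.array([0.0, 0.0, -2.0]))
    ca_t27 = _two_spheres(ca_b[12], 10.2, ca_y26, 3.8,
                          hint=ca_y26 + 3.8 * _unit(ca_y26 - ca_b[12]))
    ca_p28 = _two_spheres(ca_b[8], 9.1, ca_t27, 3.8,
                          hint=ca_t27 + np.array([-2.0, -2.0, -2.0]))
    ca_l29 = _two_spheres(ca_b[8], 12.2, ca_p28, 3.8,
                          hint=ca_p28 + 3.8 * _unit(ca_p28 - ca_b[8]))
    ca_t30 = _two_spheres(ca_b[8], 14.5, ca_l29, 3.8,
                          hint=ca_l29 + 3.8 * _unit(ca_l29 - ca_b[8]))
    ca_bcct = {24: ca_f24, 25: ca_f25, 26: ca_y26, 27: ca_t27,
               28: ca_p28, 29: ca_l29, 30: ca_t30}
    # loop G20-G23 interpolated between the helix end and the hinge
    for k, r in enumerate(range(20, 24), start=1):
        ca_bcct[r] = ca_b[19] + (ca_f24 - ca_b[19]) * k / 5.0

    atoms = []  # (chain, resid, resname, name, xyz)

    def add(chain, resid, resname, name, xyz):
        atoms.append((chain, resid, resname, name, np.asarray(xyz, float)))

    for r in range(1, 22):
        add("A", r, _A_SEQ[r], "CA", ca_a[r])
        if r == 2:
            for nm, xyz in (("CB", i2_cb), ("CG1", i2_cg1),
                            ("CG2", i2_cg2), ("CD1", i2_cd1)):
                add("A", r, "ILE", nm, xyz)
        if r == 3:
            for nm, off in (("CB", [1.2, 0.6, 0.6]), ("CG1", [2.0, 1.0, 1.0]),
                            ("CG2", [1.6, -1.0, 1.2])):
                add("A", r, "VAL", nm, ca_a[r] + np.array(off))

    for r in range(8, 31):
        xyz = ca_b[r] if r < 20 else ca_bcct[r]
        add("B", r, _B_SEQ[r], "CA", xyz)
        if r == 11:
            for nm, p in (("CB", l11_cb), ("CG", l11_cg),
                          ("CD1", l11_cd1), ("CD2", l11_cd2)):
                add("B", r, "LEU", nm, p)
        if r == 12:
            for nm, p in (("CB", v12_cb), ("CG1", v12_cg1), ("CG2", v12_cg2)):
                add("B", r, "VAL", nm, p)
        if r == 15:
            for nm, p in (("CB", l15_cb), ("CG", l15_cg),
                          ("CD1", l15_cd1), ("CD2", l15_cd2)):
                add("B", r, "LEU", nm, p)
        if r in (24, 26):
            centre = ring_f24_c if r == 24 else ring_y26_c
            cb = xyz + 1.53 * _unit(centre - xyz)
            add("B", r, _B_SEQ[r], "CB", cb)
            for nm, p in zip(RING_ATOM_NAMES, _ring(centre, centre - cb)):
                add("B", r, _B_SEQ[r], nm, p)

    truth = {
        "core_center": l15_cg,
        "table1": {label: float(np.linalg.norm(
            (ca_b[h] if h < 20 else ca_bcct[h])
            - (ca_bcct[b] if b >= 20 else ca_b[b])))
            for label, b, h, *_ in TABLE1_PAIRS},
        "table2": {"F24/L15": 5.2, "Y26/I2A": 5.2,
                   "Y26/L11": 5.2, "Y26/V12": 3.8},
    }
    return atoms, truth


def _sphere_points(n, radius, center, rng_phase=0.0):
    """Deterministic golden-angle points on a sphere of given radius."""
    pts = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k in range(n):
        z = 1.0 - 2.0 * (k + 0.5) / n
        r_xy = math.sqrt(max(1.0 - z * z, 0.0))
        th = golden * k + rng_phase
        pts.append(center + radius * np.array(
            [r_xy * math.cos(th), r_xy * math.sin(th), z]))
    return pts


def _pdb_line(record, serial, name, resname, chain, resid, xyz,
              element=" C"):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:>5d} {name_field:<4s}{'':1s}{resname:>3s} "
            f"{chain:1s}{resid:>4d}{'':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def write_toy_structure(n_frames: int = 1, seed: int = 0,
                        core_water_distances=None, n_far_waters: int = 30,
                        jitter: float = 0.0):
    """Multi-model PDB text of a synthetic insulin-like structure.

    The frame-0 geometry reproduces the published crystal-structure
    distances of the hydrophobic core by construction (this is a synthetic
    stand-in for the deposited structure, not the deposited coordinates).
    ``core_water_distances`` places water oxygens at exact distances from
    the L15 C-gamma core centre (default: ten waters between 4 and 8.5 A);
    ``n_far_waters`` more are placed 14-20 A away.  With ``jitter`` > 0,
    models beyond the first add seeded Gaussian noise to protein atoms.

    Returns ``(pdb_text, truth)`` where ``truth`` records the generating
    geometry (exact pair distances, core centre, per-frame in-sphere water
    distances).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    atoms, truth = _build_reference_geometry()
    center = truth["core_center"]
    if core_water_distances is None:
        core_water_distances = [4.0 + 0.5 * k for k in range(10)]
    core_water_distances = list(core_water_distances)
    rng = np.random.default_rng(seed)

    lines = []
    truth["water_distances"] = core_water_distances
    truth["n_core_waters"] = len(core_water_distances)
    truth["n_frames"] = n_frames
    for m in range(1, n_frames + 1):
        lines.append(f"MODEL     {m:>4d}")
        serial = 1
        for chain, resid, resname, name, xyz in atoms:
            pos = xyz
            if jitter > 0 and m > 1:
                pos = xyz + rng.normal(0.0, jitter, 3)
            lines.append(_pdb_line("ATOM", serial, name, resname, chain,
                                   resid, pos))
            serial += 1
        wat = 1
        dirs = _sphere_points(max(len(core_water_distances), 1), 1.0,
                              np.zeros(3), rng_phase=0.37 * m)
        for dist, d in zip(core_water_distances, dirs):
            lines.append(_pdb_line("HETATM", serial, "O", "HOH", "W", wat,
                                   center + dist * _unit(d), element=" O"))
            serial += 1
            wat += 1
        for p in _sphere_points(n_far_waters, 1.0, np.zeros(3),
                                rng_phase=0.11 * m):
            r = 14.0 + 6.0 * ((wat * 2654435761) % 1000) / 1000.0
            lines.append(_pdb_line("HETATM", serial, "O", "HOH", "W", wat,
                                   center + r * _unit(p), element=" O"))
            serial += 1
            wat += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n", truth


def write_reference_structure():
    """Single-model synthetic reference structure emulating the crystal
    geometry of the insulin core (Table 1/2 distances hold exactly)."""
    return write_toy_structure(n_frames=1, seed=0)
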