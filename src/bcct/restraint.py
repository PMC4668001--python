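"""Half-harmonic hinge-breaking restraint and the break/release protocol.

The restraint is repulsive-only:

    U(r) = 1/2 k (r - r0)^2   for r < r0,   0 otherwise,

pushing a pair distance out to the target r0 (the closed-state mean plus
9.8 A).  The protocol applies it to the hinge pair F24-L15 and to P28-G8
for a short bias phase, then releases it and lets the landscape dynamics
relax freely.  In this package the bias acts directly on the distance
coordinates of the synthetic landscape model (the surrogate has no
Cartesian atoms); the surrogate's bias/free durations are configuration,
not physical kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (DEFAULT_FRAME_INTERVAL_PS, RESTRAINT_K,
                        RESTRAINT_R0_OFFSET, TABLE1_PAIRS)
from .synthetic import LandscapeModel, SyntheticTrajectory, simulate_langevin

__all__ = [
    "RestraintSpec",
    "restraint_energy",
    "restraint_force",
    "default_r0",
    "hinge_break_protocol",
]

#: closed-state mean distances used for the default restraint targets
_TABLE1_MEANS = {row[0]: row[4] for row in TABLE1_PAIRS}
DEFAULT_RESTRAINT_PAIRS = ("F24-L15", "P28-G8")


def default_r0(table1_mean: float) -> float:
    """Restraint target: closed-state mean distance plus 9.8 A."""
    if table1_mean <= 0:
        raise ValueError("mean distance must be > 0")
    return float(table1_mean) + RESTRAINT_R0_OFFSET


@dataclass(frozen=True)
class RestraintSpec:
    """Half-harmonic restraint parameters.

    ``r0`` may be a single target or a per-pair mapping; when omitted it
    defaults to the closed-state mean of each pair plus 9.8 A.  The same
    force constant applies to every pair.
    """

    k: float = RESTRAINT_K
    r0: float | dict[str, float] | None = None
    pairs: tuple[str, ...] = DEFAULT_RESTRAINT_PAIRS
    bias_duration_ps: float = 200.0
    free_duration_ps: float = 30000.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant k must be >= 0")
        if self.bias_duration_ps < 0 or self.free_duration_ps < 0:
            raise ValueError("durations must be >= 0")
        for r in (self.r0.values() if isinstance(self.r0, dict)
                  else ([self.r0] if self.r0 is not None else [])):
            if r <= 0:
                raise ValueError("r0 must be > 0")

    def target(self, pair_label: str) -> float:
        if isinstance(self.r0, dict):
            if pair_label in self.r0:
                return float(self.r0[pair_label])
        elif self.r0 is not None:
            return float(self.r0)
        if pair_label not in _TABLE1_MEANS:
            raise KeyError(f"no closed-state mean tabulated for "
                           f"{pair_label!r}; pass r0 explicitly")
        return default_r0(_TABLE1_MEANS[pair_label])


def restraint_energy(r, spec: RestraintSpec, pair_label: str | None = None):
    """U(r) in kcal/mol; repulsive branch only, continuous at r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be > 0")
    r0 = spec.target(pair_label or spec.pairs[0])
    u = np.where(r < r0, 0.5 * spec.k * (r - r0) ** 2, 0.0)
    return float(u) if u.ndim == 0 else u


def restraint_force(r, spec: RestraintSpec, pair_label: str | None = None):
    """F(r) = -dU/dr in kcal/mol/A, signed along increasing r.

    Positive below r0 (pushes the pair apart), zero at and above r0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be > 0")
    r0 = spec.target(pair_label or spec.pairs[0])
    f = np.where(r < r0, -spec.k * (r - r0), 0.0)
    return float(f) if f.ndim == 0 else f


def hinge_break_protocol(model: LandscapeModel,
                         spec: RestraintSpec | None = None,
                         seed: int = 0,
                         dt_bias: float = 0.02,
                         dt_free: float = 0.1,
                         frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
                         ) -> SyntheticTrajectory:
    """Biased opening followed by free relaxation, as one trajectory.

    The restraint force is added to the spec's target coordinates for
    ``bias_duration_ps``, then the simulation continues from the reached
    configuration without any bias for ``free_duration_ps``.  Frames are
    tagged ``biased`` / ``free``.  A warning reports the achieved distance
    if a biased coordinate has not reached its wide-open threshold by the
    end of the bias phase.

    The bias phase uses a smaller integration step (``dt_bias``) because
    the added harmonic curvature k tightens the stability bound.
    """
    spec = spec or RestraintSpec()
    labels = [c.label for c in model.coordinates]
    bias_k = np.zeros(len(labels))
    bias_r0 = np.zeros(len(labels))
    for pair in spec.pairs:
        if pair not in labels:
            raise KeyError(f"model has no coordinate {pair!r}")
        i = labels.index(pair)
        bias_k[i] = spec.k
        bias_r0[i] = spec.target(pair)

    n_bias = max(1, int(round(spec.bias_duration_ps / frame_interval)))
    n_free = max(1, int(round(spec.free_duration_ps / frame_interval)))

    biased = simulate_langevin(model, n_bias, dt=dt_bias, seed=seed,
                               frame_interval=frame_interval,
                               bias_k=bias_k, bias_r0=bias_r0)
    end = np.array([biased.series[lab][-1] for lab in labels])
    for pair in spec.pairs:
        coord = model.coordinate(pair)
        reached = biased.series[pair][-1]
        if reached < coord.theta_wide:
            warnings.warn(
                f"bias phase did not open {pair}: reached {reached:.2f} A, "
                f"wide-open threshold {coord.theta_wide:.2f} A")
    free = simulate_langevin(model, n_free, dt=dt_free, seed=seed + 60013,
                             frame_interval=frame_interval, start=end)

    series = {lab: np.concatenate([biased.series[lab], free.series[lab]])
              for lab in labels}
    phase = np.concatenate([np.full(n_bias, "biased", dtype=object),
                            np.full(n_free, "free", dtype=object)])
    return SyntheticTrajectory(
        frame_interval=frame_interval,
        series=series,
        true_states=np.concatenate([biased.true_states, free.true_states]),
        seed=seed,
        phase=phase,
        params={"restraint_k": spec.k,
                "restraint_pairs": list(spec.pairs),
                "restraint_r0": {p: spec.target(p) for p in spec.pairs},
                "bias_duration_ps": spec.bias_duration_ps,
                "free_duration_ps": spec.free_duration_ps,
                "dt_bias_ps": dt_bias, "dt_free_ps": dt_free})
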