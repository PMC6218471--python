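"""Random kinetic models for a circuit topology.

Each gene ``i`` follows a birth--death equation with shifted-Hill
regulation (see :mod:`circuitnoise.simulate`):

    dx_i/dt = G_i * prod_j H(x_j; X0_ji, n_ji, lam_ji) - k_i * x_i

A *model* is one random draw of all kinetic constants: production rates
``G``, degradation rates ``k``, and per-edge thresholds ``X0``, Hill
coefficients ``n`` and fold-changes ``lam``.  An *ensemble* of thousands
of such models, each simulated once, replaces a single hand-tuned model;
cluster structure across the ensemble is the circuit's phenotype
repertoire.

Parameter ranges follow the RACIPE convention: production uniform on
[1, 100], degradation uniform on [0.1, 1], Hill coefficients uniform on
the integers 1..6, fold-change uniform on [1, 100] (inverted to 1/lam for
inhibitory edges so lam < 1 always weakens the target).  Thresholds use
the half-functional rule: they are drawn around the median unregulated
expression of the regulator, so a regulator sits near its half-effect
point in a typical model.

The parametric-variation index ``P`` (percent) shrinks every range about
its midpoint: ``P = 100`` leaves the defaults untouched, ``P = 0``
collapses each range to its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import ACTIVATION, Circuit

Interval = tuple[float, float]

#: internal seed for the half-functional median estimate; fixed so that
#: parameter ranges are reproducible independently of the sampling seed
_MEDIAN_SEED = 20180
_MEDIAN_DRAWS = 10_000


def scale_interval(interval: Interval, p: float) -> Interval:
    """Rescale ``(x_min, x_max)`` about its midpoint by ``p`` percent.

    y_min = (x_max + x_min)/2 - (x_max - x_min)/2 * p/100
    y_max = (x_max + x_min)/2 + (x_max - x_min)/2 * p/100

    ``p = 100`` is the identity; ``p = 0`` collapses to the midpoint.  The
    arithmetic midpoint is conserved exactly for every ``p``.
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"parametric variation index must lie in [0, 100], got {p}")
    if p == 100.0:  # the identity holds exactly; avoid roundoff in mid +/- half
        return tuple(interval)
    x_min, x_max = interval
    mid = (x_max + x_min) / 2.0
    half = (x_max - x_min) / 2.0 * (p / 100.0)
    return (mid - half, mid + half)


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges for all kinetic constants of a circuit.

    The same range applies to every gene (production, degradation) and
    every edge (Hill coefficient, fold-change, threshold spread); this is
    the RACIPE convention and keeps the ensemble exchangeable across genes.
    ``threshold_spread`` is the multiplicative bracket around the median
    unregulated expression of the regulator from which thresholds are
    drawn; its midpoint 1.0 keeps the threshold median at that level.
    """

    production: Interval = (1.0, 100.0)
    degradation: Interval = (0.1, 1.0)
    fold_change: Interval = (1.0, 100.0)
    hill: Interval = (1.0, 6.0)
    threshold_spread: Interval = (0.02, 1.98)
    #: separate fold-change range for inhibitory edges (sampled, then
    #: inverted to 1/lam); ``None`` reuses ``fold_change``
    inhibition_fold_change: Interval | None = None

    def __post_init__(self) -> None:
        for name in ("production", "degradation", "fold_change", "threshold_spread"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must satisfy 0 < min <= max, got ({lo}, {hi})")
        if self.inhibition_fold_change is not None:
            lo, hi = self.inhibition_fold_change
            if not (0 < lo <= hi):
                raise ValueError(
                    f"inhibition_fold_change range must satisfy 0 < min <= max, got ({lo}, {hi})"
                )
        lo, hi = self.hill
        if not (1.0 <= lo <= hi):
            raise ValueError(f"hill range must satisfy 1 <= min <= max, got ({lo}, {hi})")

    @property
    def inhibition_fold(self) -> Interval:
        return self.inhibition_fold_change or self.fold_change

    def scaled(self, p: float) -> "ParameterRanges":
        """Apply the parametric-variation rescaling to every range."""
        return ParameterRanges(
            production=scale_interval(self.production, p),
            degradation=scale_interval(self.degradation, p),
            fold_change=scale_interval(self.fold_change, p),
            hill=scale_interval(self.hill, p),
            threshold_spread=scale_interval(self.threshold_spread, p),
            inhibition_fold_change=(
                None
                if self.inhibition_fold_change is None
                else scale_interval(self.inhibition_fold_change, p)
            ),
        )

    def unregulated_median(self) -> float:
        """Median unregulated steady-state level (median of G/k over draws).

        Estimated once from 10^4 uniform draws with a fixed internal seed,
        so it is a deterministic function of the production/degradation
        ranges; cached.
        """
        return _unregulated_median(self.production, self.degradation)

    def hill_integers(self) -> np.ndarray:
        """Admissible integer Hill coefficients within the (possibly scaled)
        range; falls back to the rounded midpoint when the scaled range
        contains no integer."""
        lo, hi = self.hill
        ints = np.arange(int(np.ceil(lo - 1e-9)), int(np.floor(hi + 1e-9)) + 1)
        if ints.size == 0:
            ints = np.array([int(round((lo + hi) / 2.0))])
        return ints


#: Calibration for the quadrastable (four-phenotype) self-activating
#: toggle-switch ensemble, emulating an engineered synthetic construct:
#: low leaky basal production and similar reporter stabilities (narrow
#: degradation range), strong cooperative inducible self-activation,
#: comparatively weak mutual repression, and activation thresholds a few
#: fold above basal expression so genes are OFF by default.  Under these
#: ranges a sizeable fraction (~15%) of random models carries all four
#: low/high phenotype combinations as coexisting stable states.
QUADRASTABLE_RANGES = ParameterRanges(
    production=(1.0, 10.0),
    degradation=(0.5, 1.0),
    fold_change=(20.0, 100.0),
    inhibition_fold_change=(1.0, 5.0),
    hill=(4.0, 6.0),
    threshold_spread=(2.0, 6.0),
)


@lru_cache(maxsize=None)
def _unregulated_median(production: Interval, degradation: Interval) -> float:
    rng = np.random.default_rng(_MEDIAN_SEED)
    g = rng.uniform(*production, size=_MEDIAN_DRAWS)
    k = rng.uniform(*degradation, size=_MEDIAN_DRAWS)
    return float(np.median(g / k))


def scale_ranges(ranges: ParameterRanges, p: float) -> ParameterRanges:
    """Functional alias for :meth:`ParameterRanges.scaled`."""
    return ranges.scaled(p)


@dataclass(frozen=True)
class ModelParameters:
    """One random model's kinetic constants, aligned with a circuit.

    ``production``/``degradation`` follow the circuit's gene order;
    ``threshold``/``hill``/``fold_change`` follow the circuit's edge order.
    Fold-changes are already oriented: > 1 on activating edges, in (0, 1)
    on inhibitory edges.
    """

    production: np.ndarray   # (n_genes,)
    degradation: np.ndarray  # (n_genes,)
    threshold: np.ndarray    # (n_edges,)
    hill: np.ndarray         # (n_edges,) integer-valued
    fold_change: np.ndarray  # (n_edges,)

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, ModelParameters):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("production", "degradation", "threshold", "hill", "fold_change")
        )


def sample_model(circuit: Circuit, ranges: ParameterRanges, rng: np.random.Generator) -> ModelParameters:
    """Draw one random model for ``circuit`` from ``ranges``.

    Draw order is fixed (production, degradation, fold-change, Hill,
    threshold) so a given generator state always yields the same model.
    """
    n_g, n_e = circuit.n_genes, circuit.n_edges
    g = rng.uniform(*ranges.production, size=n_g)
    k = rng.uniform(*ranges.degradation, size=n_g)
    lam_act = rng.uniform(*ranges.fold_change, size=n_e)
    lam_inh = rng.uniform(*ranges.inhibition_fold, size=n_e)
    _, _, kind = circuit.edge_arrays()
    inhib = kind != ACTIVATION
    lam = np.where(inhib, 1.0 / lam_inh, lam_act)
    n = rng.choice(ranges.hill_integers(), size=n_e).astype(float)
    med = ranges.unregulated_median()
    x0 = med * rng.uniform(*ranges.threshold_spread, size=n_e)
    return ModelParameters(g, k, x0, n, lam)


def sample_ensemble(
    circuit: Circuit,
    ranges: ParameterRanges,
    n_models: int,
    seed: int,
) -> list[ModelParameters]:
    """Draw ``n_models`` independent models; per-model seeds are spawned
    deterministically from the master seed."""
    if n_models < 1:
        raise ValueError(f"n_models must be >= 1, got {n_models}")
    children = np.random.SeedSequence(seed).spawn(n_models)
    return [sample_model(circuit, ranges, np.random.default_rng(s)) for s in children]


@dataclass
class ParamStack:
    """An ensemble of models stacked into arrays (model axis first).

    This is the layout the vectorized integrator consumes; ``G``/``K`` are
    (n_models, n_genes), ``X0``/``N``/``LAM`` are (n_models, n_edges).
    """

    G: np.ndarray
    K: np.ndarray
    X0: np.ndarray
    N: np.ndarray
    LAM: np.ndarray

    @property
    def n_models(self) -> int:
        return self.G.shape[0]

    @property
    def n_genes(self) -> int:
        return self.G.shape[1]

    @classmethod
    def from_models(cls, models: Sequence[ModelParameters]) -> "ParamStack":
        return cls(
            G=np.stack([m.production for m in models]),
            K=np.stack([m.degradation for m in models]),
            X0=np.stack([m.threshold for m in models]),
            N=np.stack([m.hill for m in models]),
            LAM=np.stack([m.fold_change for m in models]),
        )

    def model(self, i: int) -> ModelParameters:
        return ModelParameters(
            self.G[i].copy(), self.K[i].copy(), self.X0[i].copy(),
            self.N[i].copy(), self.LAM[i].copy(),
        )

    def subset(self, index: np.ndarray) -> "ParamStack":
        return ParamStack(
            self.G[index], self.K[index], self.X0[index], self.N[index], self.LAM[index]
        )

    def tile(self, reps: int) -> "ParamStack":
        """Repeat every model ``reps`` times (model i occupies rows
        i*reps..(i+1)*reps-1); used for multi-initial-condition state
        enumeration."""
        return ParamStack(
            np.repeat(self.G, reps, axis=0),
            np.repeat(self.K, reps, axis=0),
            np.repeat(self.X0, reps, axis=0),
            np.repeat(self.N, reps, axis=0),
            np.repeat(self.LAM, reps, axis=0),
        )

    def copy(self) -> "ParamStack":
        return ParamStack(self.G.copy(), self.K.copy(), self.X0.copy(),
                          self.N.copy(), self.LAM.copy())


# -- tabular import/export ----------------------------------------------

def parameter_columns(circuit: Circuit) -> list[str]:
    cols = [f"G_{g}" for g in circuit.genes] + [f"k_{g}" for g in circuit.genes]
    for e in circuit.edges:
        cols += [f"X0_{e.source}_{e.target}", f"n_{e.source}_{e.target}", f"lam_{e.source}_{e.target}"]
    return cols


def parameters_to_frame(models: Sequence[ModelParameters], circuit: Circuit) -> pd.DataFrame:
    """One row per model, one named column per kinetic constant."""
    stack = ParamStack.from_models(models)
    data: dict[str, np.ndarray] = {}
    for j, g in enumerate(circuit.genes):
        data[f"G_{g}"] = stack.G[:, j]
    for j, g in enumerate(circuit.genes):
        data[f"k_{g}"] = stack.K[:, j]
    for j, e in enumerate(circuit.edges):
        data[f"X0_{e.source}_{e.target}"] = stack.X0[:, j]
        data[f"n_{e.source}_{e.target}"] = stack.N[:, j]
        data[f"lam_{e.source}_{e.target}"] = stack.LAM[:, j]
    frame = pd.DataFrame(data)
    frame.index.name = "model_id"
    return frame[parameter_columns(circuit)]


def frame_to_parameters(frame: pd.DataFrame, circuit: Circuit) -> list[ModelParameters]:
    missing = set(parameter_columns(circuit)) - set(frame.columns)
    if missing:
        raise ValueError(f"parameter table is missing columns: {sorted(missing)}")
    g = frame[[f"G_{x}" for x in circuit.genes]].to_numpy(float)
    k = frame[[f"k_{x}" for x in circuit.genes]].to_numpy(float)
    x0 = frame[[f"X0_{e.source}_{e.target}" for e in circuit.edges]].to_numpy(float)
    n = frame[[f"n_{e.source}_{e.target}" for e in circuit.edges]].to_numpy(float)
    lam = frame[[f"lam_{e.source}_{e.target}" for e in circuit.edges]].to_numpy(float)
    return [ModelParameters(g[i], k[i], x0[i], n[i], lam[i]) for i in range(len(frame))]


def write_parameters(models: Sequence[ModelParameters], circuit: Circuit, path) -> None:
    parameters_to_frame(models, circuit).to_csv(path, sep="\t")


def read_parameters(path, circuit: Circuit) -> list[ModelParameters]:
    return frame_to_parameters(pd.read_csv(path, sep="\t", index_col=0), circuit)
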