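"""Ensemble sampling protocols: SIC, MIC, simulated annealing, and the
randomized-noise and induction experiments.

Three ways to estimate the steady-state probability distribution of a
stochastic system:

* **SIC** (single initial condition): one long trajectory recorded at
  equidistant times.  Cheap but trapped in one basin at low noise.
* **MIC** (multiple initial conditions): many short independent runs at a
  fixed noise level, each recorded once at the end.  At low noise the
  occupancy of each state is proportional to its *basin of attraction*.
* **SA** (simulated annealing): the ensemble starts at a high noise level
  and relaxes down a decreasing noise ladder, carrying terminal states
  between levels.  At low noise the occupancy concentrates in the most
  *stable* state.

For circuit ensembles, each random model contributes exactly one initial
condition; across thousands of models with similar parameters this is
equivalent to (and cheaper than) many initial conditions per model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import Circuit
from .doublewell import DoubleWell, get_variant, particles_simulate, sample_domain
from .parameters import ModelParameters, ParamStack, ParameterRanges, sample_ensemble
from .simulate import ensemble_drift, ensemble_simulate, initial_conditions, relax_deterministic


@dataclass(frozen=True)
class NoiseLadder:
    """Decreasing noise levels ending exactly at 0, with a per-level
    relaxation time ``tau``."""

    levels: tuple[float, ...]
    tau: float = 5.0

    def __post_init__(self) -> None:
        lv = tuple(float(d) for d in self.levels)
        if len(lv) < 1 or lv[-1] != 0.0:
            raise ValueError("noise ladder must end exactly at 0")
        if any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValueError("noise ladder must be strictly decreasing")
        if self.tau <= 0:
            raise ValueError("per-level relaxation time tau must be positive")
        object.__setattr__(self, "levels", lv)

    @classmethod
    def linear(cls, d_max: float = 50.0, n_levels: int = 30, tau: float = 5.0) -> "NoiseLadder":
        """Linearly spaced ladder from ``d_max`` down to 0.

        The defaults span the 0-50 noise range used for circuit ensembles;
        for double wells use :func:`well_annealing_ladder`."""
        return cls(tuple(np.linspace(d_max, 0.0, n_levels)), tau)


def well_annealing_ladder() -> NoiseLadder:
    """Default annealing schedule for the double-well benchmarks: 0.8 down
    to 0 in 30 levels, 50 time units per level — slow enough that the
    shallow well empties before the ladder freezes."""
    return NoiseLadder(tuple(np.linspace(0.8, 0.0, 30)), 50.0)


@dataclass
class CircuitEnsemble:
    """A circuit plus a stacked ensemble of random models — the `system`
    the sampling schemes act on."""

    circuit: Circuit
    params: ParamStack

    @classmethod
    def sample(cls, circuit: Circuit, ranges: ParameterRanges, n_models: int, seed: int) -> "CircuitEnsemble":
        models = sample_ensemble(circuit, ranges, n_models, seed)
        return cls(circuit, ParamStack.from_models(models))

    @property
    def n_models(self) -> int:
        return self.params.n_models


@dataclass
class EnsembleResult:
    """Terminal records of one protocol run.

    ``data`` holds one row per record with columns ``model_id``, ``D``,
    optionally ``time``, then one column per gene (or ``x`` for the
    double-well particle).  ``params`` links back to the generating models
    where applicable.
    """

    scheme: str
    genes: tuple[str, ...]
    data: pd.DataFrame
    params: ParamStack | None = None

    @property
    def expression(self) -> np.ndarray:
        return self.data[list(self.genes)].to_numpy(float)

    @property
    def noise(self) -> np.ndarray:
        return self.data["D"].to_numpy(float)

    def to_tsv(self, path) -> None:
        frame = self.data.copy()
        frame.insert(0, "scheme", self.scheme)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EnsembleResult":
        frame = pd.read_csv(path, sep="\t")
        scheme = str(frame.pop("scheme").iloc[0])
        meta = {"model_id", "D", "time"}
        genes = tuple(c for c in frame.columns if c not in meta)
        return cls(scheme=scheme, genes=genes, data=frame)


def _result_frame(genes, model_id, noise, expr, time=None) -> pd.DataFrame:
    cols = {"model_id": np.asarray(model_id, dtype=int), "D": np.asarray(noise, dtype=float)}
    if time is not None:
        cols["time"] = np.asarray(time, dtype=float)
    frame = pd.DataFrame(cols)
    expr = np.atleast_2d(expr)
    for j, g in enumerate(genes):
        frame[g] = expr[:, j]
    return frame


System = "DoubleWell | CircuitEnsemble"


def run_sic(
    system,
    noise: float,
    t_total: float,
    record_interval: float,
    seed: int,
    *,
    dt: float | None = None,
    burn_in: float = 0.0,
) -> EnsembleResult:
    """Single-initial-condition sampling: one long trajectory per system,
    recorded at equidistant times.  The histogram of the records estimates
    the stationary distribution at this noise level — unless the
    trajectory is trapped in one basin, which is exactly the low-noise
    failure mode this scheme exhibits."""
    rng = np.random.default_rng(seed)
    record_times = np.arange(record_interval, t_total + 1e-9, record_interval)
    record_times = record_times[record_times > burn_in]
    if isinstance(system, (DoubleWell, str)):
        well = get_variant(system)
        dt = 0.02 if dt is None else dt
        x0 = sample_domain(well, 1, rng)
        times, snaps = particles_simulate(
            well, x0, dt=dt, t_max=t_total, noise=noise, rng=rng, record_times=record_times
        )
        expr = snaps.reshape(-1, 1)
        frame = _result_frame(("x",), np.zeros(len(times), int), np.full(len(times), noise),
                              expr, time=times)
        return EnsembleResult("SIC", ("x",), frame)
    ens: CircuitEnsemble = system
    dt = 0.05 if dt is None else dt
    times, snaps = ensemble_simulate(
        ens.circuit, ens.params, dt=dt, t_max=t_total, noise=noise, rng=rng,
        record_times=record_times,
    )
    n_t, n_m = snaps.shape[0], snaps.shape[1]
    frame = _result_frame(
        ens.circuit.genes,
        np.tile(np.arange(n_m), n_t),
        np.full(n_t * n_m, noise),
        snaps.reshape(n_t * n_m, -1),
        time=np.repeat(times, n_m),
    )
    return EnsembleResult("SIC", ens.circuit.genes, frame, ens.params)


def run_mic(
    system,
    noise: float,
    t_max: float,
    seed: int,
    *,
    n_particles: int = 1000,
    dt: float | None = None,
    x0: np.ndarray | None = None,
) -> EnsembleResult:
    """Multiple-initial-condition sampling: independent short runs at a
    fixed noise level, one terminal record each.  For a circuit ensemble
    every model gets one random initial condition; for a double well,
    ``n_particles`` particles start uniformly over the domain."""
    rng = np.random.default_rng(seed)
    if isinstance(system, (DoubleWell, str)):
        well = get_variant(system)
        dt = 0.02 if dt is None else dt
        start = sample_domain(well, n_particles, rng) if x0 is None else np.asarray(x0, float)
        xf = particles_simulate(well, start, dt=dt, t_max=t_max, noise=noise, rng=rng)
        frame = _result_frame(("x",), np.arange(len(xf)), np.full(len(xf), noise), xf[:, None])
        return EnsembleResult("MIC", ("x",), frame)
    ens: CircuitEnsemble = system
    dt = 0.05 if dt is None else dt
    xf = ensemble_simulate(
        ens.circuit, ens.params, dt=dt, t_max=t_max, noise=noise, rng=rng, x0=x0
    )
    frame = _result_frame(
        ens.circuit.genes, np.arange(ens.n_models), np.full(ens.n_models, noise), xf
    )
    return EnsembleResult("MIC", ens.circuit.genes, frame, ens.params)


def run_sa(
    system,
    ladder: NoiseLadder,
    seed: int,
    *,
    n_particles: int = 1000,
    dt: float | None = None,
) -> list[EnsembleResult]:
    """Simulated-annealing sampling down a noise ladder.

    Every model/particle starts from a random initial condition at the
    highest noise level, relaxes for ``ladder.tau`` time units per level,
    and carries its terminal state to the next (lower) level.  Terminal
    records are kept at every level, so the run yields a steady-state
    distribution per noise level; the final (zero-noise) level
    concentrates on the most stable state."""
    rng = np.random.default_rng(seed)
    results: list[EnsembleResult] = []
    if isinstance(system, (DoubleWell, str)):
        well = get_variant(system)
        dt = 0.02 if dt is None else dt
        x = sample_domain(well, n_particles, rng)
        for level in ladder.levels:
            x = particles_simulate(well, x, dt=dt, t_max=ladder.tau, noise=level, rng=rng)
            frame = _result_frame(("x",), np.arange(len(x)), np.full(len(x), level), x[:, None])
            results.append(EnsembleResult("SA", ("x",), frame))
        return results
    ens: CircuitEnsemble = system
    dt = 0.05 if dt is None else dt
    x = initial_conditions(ens.circuit, ens.params, rng)
    for level in ladder.levels:
        x = ensemble_simulate(
            ens.circuit, ens.params, dt=dt, t_max=ladder.tau, noise=level, rng=rng, x0=x
        )
        frame = _result_frame(
            ens.circuit.genes, np.arange(ens.n_models), np.full(ens.n_models, level), x
        )
        results.append(EnsembleResult("SA", ens.circuit.genes, frame, ens.params))
    return results


def run_noise_randomized_mic(
    ensemble: CircuitEnsemble,
    d_max: float,
    t_max: float,
    seed: int,
    *,
    dt: float = 0.05,
) -> EnsembleResult:
    """MIC with the noise level treated as one more random model parameter,
    drawn per model from Uniform(0, d_max).  Binning the terminal records
    by D afterwards gives the global noise-bifurcation picture in a single
    pass."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, d_max, size=ensemble.n_models)
    xf = ensemble_simulate(
        ensemble.circuit, ensemble.params, dt=dt, t_max=t_max, noise=d, rng=rng
    )
    frame = _result_frame(ensemble.circuit.genes, np.arange(ensemble.n_models), d, xf)
    return EnsembleResult("MIC", ensemble.circuit.genes, frame, ensemble.params)


# -- deterministic state enumeration and quadrastable models -------------

def _cluster_states(points: np.ndarray, rel_tol: float, abs_tol: float = 1e-3) -> np.ndarray:
    """Greedy merge of near-identical fixed points (per-gene relative
    tolerance); returns the distinct state centroids, ordered by the first
    gene's expression."""
    centroids: list[np.ndarray] = []
    counts: list[int] = []
    for p in points:
        for i, c in enumerate(centroids):
            if np.all(np.abs(p - c) <= rel_tol * np.maximum(np.abs(p), np.abs(c)) + abs_tol):
                counts[i] += 1
                centroids[i] = c + (p - c) / counts[i]  # running mean
                break
        else:
            centroids.append(p.astype(float).copy())
            counts.append(1)
    out = np.array(centroids)
    return out[np.argsort(out[:, 0])]


def enumerate_states(
    circuit: Circuit,
    params: ParamStack,
    seed: int,
    *,
    n_ic: int = 100,
    dt: float = 0.05,
    t_max: float = 100.0,
    rel_tol: float = 1e-2,
    batch: int = 500,
) -> list[np.ndarray]:
    """Deterministic stable-state enumeration: for each model, relax
    ``n_ic`` random initial conditions at zero noise and cluster the
    converged end points (relative tolerance ``rel_tol``).  Unconverged
    end points (residual rate above tolerance) are discarded rather than
    counted as states.  Returns one (n_states, n_genes) array per model.
    """
    rng = np.random.default_rng(seed)
    src, tgt, _ = circuit.edge_arrays()
    states: list[np.ndarray] = []
    for lo in range(0, params.n_models, batch):
        sub = params.subset(np.arange(lo, min(lo + batch, params.n_models)))
        tiled = sub.tile(n_ic)
        x0 = initial_conditions(circuit, tiled, rng)
        xf = relax_deterministic(circuit, tiled, x0, dt=dt, t_max=t_max, tol=1e-7)
        resid = np.abs(ensemble_drift(xf, tiled, src, tgt)) / (1.0 + np.abs(xf))
        ok = resid.max(axis=1) < 1e-4
        for m in range(sub.n_models):
            rows = xf[m * n_ic:(m + 1) * n_ic][ok[m * n_ic:(m + 1) * n_ic]]
            if len(rows) == 0:
                states.append(np.empty((0, circuit.n_genes)))
            else:
                states.append(_cluster_states(rows, rel_tol))
    return states


def state_thresholds(states: np.ndarray) -> np.ndarray:
    """Per-gene low/high threshold: geometric midpoint of the model's
    fixed-point expression range (midpoint on the log scale)."""
    floor = 1e-12
    lo = np.maximum(states.min(axis=0), floor)
    hi = np.maximum(states.max(axis=0), floor)
    return np.sqrt(lo * hi)


def label_state(x: np.ndarray, thresholds: np.ndarray) -> str:
    """Label an expression vector gene-by-gene: 'H' above threshold, 'L'
    below; e.g. 'LH' = first gene low, second high."""
    return "".join("H" if xi > ti else "L" for xi, ti in zip(np.atleast_1d(x), thresholds))


@dataclass
class QuadrastableEnsemble:
    """Models with exactly four coexisting stable states, plus each
    model's enumerated states and low/high thresholds."""

    circuit: Circuit
    params: ParamStack
    states: list[np.ndarray]       # (4, n_genes) per model
    thresholds: np.ndarray         # (n_models, n_genes)
    state_counts: np.ndarray       # states found per *candidate* model

    @property
    def n_models(self) -> int:
        return self.params.n_models

    def state_by_label(self, model: int, label: str) -> np.ndarray:
        for s in self.states[model]:
            if label_state(s, self.thresholds[model]) == label:
                return s
        raise KeyError(f"model {model} has no state labeled {label!r}")

    def labels(self, model: int) -> list[str]:
        return [label_state(s, self.thresholds[model]) for s in self.states[model]]


def find_quadrastable(
    circuit: Circuit,
    ranges: ParameterRanges,
    n_models: int,
    seed: int,
    *,
    n_ic: int = 100,
    required_labels: tuple[str, ...] = ("LL", "LH", "HL", "HH"),
    **kwargs,
) -> QuadrastableEnsemble:
    """Enumerate states for ``n_models`` random models and keep those with
    exactly four distinct stable states carrying the four low/high label
    combinations."""
    ensemble = CircuitEnsemble.sample(circuit, ranges, n_models, seed)
    states = enumerate_states(circuit, ensemble.params, seed + 1, n_ic=n_ic, **kwargs)
    counts = np.array([len(s) for s in states])
    keep, kept_states, thresholds = [], [], []
    for i, s in enumerate(states):
        if len(s) != 4:
            continue
        thr = state_thresholds(s)
        labels = {label_state(row, thr) for row in s}
        if labels == set(required_labels):
            keep.append(i)
            kept_states.append(s)
            thresholds.append(thr)
    if not keep:
        return QuadrastableEnsemble(circuit, ensemble.params.subset(np.array([], int)),
                                    [], np.empty((0, circuit.n_genes)), counts)
    return QuadrastableEnsemble(
        circuit,
        ensemble.params.subset(np.array(keep)),
        kept_states,
        np.array(thresholds),
        counts,
    )


# -- induction experiment -------------------------------------------------

def _apply_induction(params: ParamStack, circuit: Circuit, factors: dict[str, float]) -> ParamStack:
    """Strengthen the self-activation link of each named gene by its
    induction factor (IF): fold-change multiplied by IF and activation
    threshold divided by IF (each activator molecule becomes IF-fold more
    potent).  IF = 1 leaves the model untouched."""
    out = params.copy()
    for e_idx in circuit.self_activation_edges():
        gene = circuit.edges[e_idx].source
        if gene in factors:
            out.LAM[:, e_idx] = out.LAM[:, e_idx] * factors[gene]
            out.X0[:, e_idx] = out.X0[:, e_idx] / factors[gene]
    unknown = set(factors) - set(circuit.genes)
    if unknown:
        raise ValueError(f"induction factors name genes outside the circuit: {sorted(unknown)}")
    return out


def induction_experiment(
    quad: QuadrastableEnsemble,
    stages: Sequence[dict[str, float]],
    initial_state_label: str,
    *,
    dt: float = 0.05,
    t_max: float = 50.0,
    noise: float = 0.0,
    seed: int = 0,
) -> list[EnsembleResult]:
    """Drive quadrastable models through a schedule of induction stages.

    Each stage is a ``{gene: induction factor}`` map multiplying the
    self-activation fold-changes; the ensemble starts in the fixed point
    carrying ``initial_state_label`` (e.g. ``"LL"``) and each stage relaxes
    the terminal state of the previous one.  Returned results carry a
    ``state`` column with the per-model low/high label after the stage,
    so sequential, simultaneous and removal (back to IF = 1) protocols are
    all expressible as stage lists."""
    if quad.n_models == 0:
        raise ValueError("no quadrastable models supplied")
    allowed = {"".join(p) for p in itertools.product("LH", repeat=quad.circuit.n_genes)}
    if initial_state_label not in allowed:
        raise ValueError(f"unknown state label {initial_state_label!r}")
    rng = np.random.default_rng(seed)
    x = np.stack([quad.state_by_label(i, initial_state_label) for i in range(quad.n_models)])
    results: list[EnsembleResult] = []
    for stage in stages:
        induced = _apply_induction(quad.params, quad.circuit, stage)
        x = ensemble_simulate(
            quad.circuit, induced, dt=dt, t_max=t_max, noise=noise, rng=rng, x0=x
        )
        frame = _result_frame(
            quad.circuit.genes, np.arange(quad.n_models), np.full(quad.n_models, noise), x
        )
        frame["state"] = [label_state(x[i], quad.thresholds[i]) for i in range(quad.n_models)]
        results.append(EnsembleResult("induction", quad.circuit.genes, frame, induced))
    return results
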