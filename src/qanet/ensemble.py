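"""Boltzmann-ensemble MCMC fitting of network models to time courses.

The goodness of fit is a chi-square over observations (gene, platform,
time, value, sigma), with one multiplicative scale factor per
(gene, platform) pair linking model concentrations (arbitrary units) to
measured abundances; each scale is profiled out analytically as the
weighted least-squares solution, floored at zero. Parameters are sampled
by a per-parameter Metropolis random walk in log10 space targeting the
ensemble density exp(-chi^2/2), with proposal widths adapted toward a
25-45% acceptance rate during equilibration only (so accumulation sweeps
leave the target invariant).

The fitting protocol launches independent chains from random in-bounds
starts, equilibrates and briefly accumulates each, then seeds one long
accumulation run from the best chi-square found; the accumulated samples
form the ensemble. Nested variants are compared by an ordinary difference
of their minimum chi-squares against the chi-square distribution whose
degrees of freedom equal the difference in parameter counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from qanet._errors import MappingError, ParameterError, SolverDivergenceError, StructuralError
from qanet.network import NetworkModel, solve_modified_euler

#: log10 sampling bounds: rate constants in [1e-4, 1e3] /hr, initial
#: concentrations in [1e-6, 1e3] a.u.
RATE_LOG10_BOUNDS = (-4.0, 3.0)
CONC_LOG10_BOUNDS = (-6.0, 3.0)

FIT_STEP_H = 0.05  # hr; solver step used inside the chi-square objective


def default_sigma(y: np.ndarray) -> np.ndarray:
    """Per-observation noise scale when the data carry none: 20% of the
    measured value, floored at 0.1."""
    return np.maximum(0.1, 0.2 * np.abs(np.asarray(y, dtype=float)))


@dataclass
class FitDataSet:
    """Observations plus the gene -> mRNA-species mapping."""

    gene: np.ndarray
    platform: np.ndarray
    time_hr: np.ndarray
    value: np.ndarray
    sigma: np.ndarray
    gene_to_species: dict
    _binding: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.gene = np.asarray(self.gene, dtype=object)
        self.platform = np.asarray(self.platform, dtype=object)
        self.time_hr = np.asarray(self.time_hr, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.gene.size
        for arr in (self.platform, self.time_hr, self.value, self.sigma):
            if arr.size != n:
                raise StructuralError("observation columns must align")
        if np.any(self.sigma <= 0):
            raise ParameterError("sigma must be positive")
        for g in np.unique(self.gene):
            if g not in self.gene_to_species:
                raise MappingError(f"gene {g!r} has no mRNA species mapping")

    @classmethod
    def from_profiles(cls, profiles: dict, gene_to_species: dict,
                      time_hr, platform: str = "microarray",
                      sigma=None) -> "FitDataSet":
        """Build from ``{gene: values over time_hr}`` (one platform)."""
        genes, times, values = [], [], []
        t = np.asarray(time_hr, dtype=float)
        for g, vals in profiles.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != t.shape:
                raise StructuralError(f"profile for {g!r} does not match grid")
            genes += [g] * t.size
            times.extend(t)
            values.extend(vals)
        values = np.asarray(values)
        sig = default_sigma(values) if sigma is None else np.broadcast_to(
            np.asarray(sigma, dtype=float), values.shape).copy()
        return cls(np.asarray(genes, dtype=object),
                   np.asarray([platform] * len(genes), dtype=object),
                   np.asarray(times), values, sig, dict(gene_to_species))

    def bind(self, model: NetworkModel) -> dict:
        """Resolve species indices and scale groups against one model."""
        key = id(model)
        if key not in self._binding:
            idx = {s.name: i for i, s in enumerate(model.species)}
            sp = np.empty(self.gene.size, dtype=np.int64)
            for i, g in enumerate(self.gene):
                name = self.gene_to_species[g]
                if name not in idx:
                    raise MappingError(f"species {name!r} not in model")
                sp[i] = idx[name]
            pairs = [(g, p) for g, p in zip(self.gene, self.platform)]
            uniq = list(dict.fromkeys(pairs))
            gid = np.asarray([uniq.index(p) for p in pairs], dtype=np.int64)
            times, t_inv = np.unique(self.time_hr, return_inverse=True)
            self._binding[key] = {
                "species_idx": sp, "group_id": gid, "n_groups": len(uniq),
                "times": times, "time_inv": t_inv,
                "weight": 1.0 / self.sigma**2,
            }
        return self._binding[key]


def chi_square(model: NetworkModel, theta: np.ndarray, data: FitDataSet,
               step_h: float = FIT_STEP_H) -> float:
    """Profiled chi-square of ``theta`` against the data.

    chi^2 = sum_i (y_i - a_{g(i)} x_i)^2 / sigma_i^2 with each group scale
    a profiled in closed form (weighted least squares, floored at 0).
    Returns +inf when the trajectory diverges.
    """
    b = data.bind(model)
    try:
        traj = solve_modified_euler(model, theta, b["times"], step_h=step_h)
    except SolverDivergenceError:
        return np.inf
    x = traj.states[b["time_inv"], b["species_idx"]]
    y = data.value
    w = b["weight"]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        num = np.bincount(b["group_id"], weights=x * y * w,
                          minlength=b["n_groups"])
        den = np.bincount(b["group_id"], weights=x * x * w,
                          minlength=b["n_groups"])
        if not (np.all(np.isfinite(num)) and np.all(np.isfinite(den))):
            return np.inf
        a = np.maximum(np.where(den > 0, num / den, 0.0), 0.0)
        chi2 = float(np.sum(w * (y - a[b["group_id"]] * x) ** 2))
    return chi2 if np.isfinite(chi2) else np.inf


def profiled_scales(model: NetworkModel, theta: np.ndarray, data: FitDataSet,
                    step_h: float = FIT_STEP_H) -> dict:
    """The per-(gene, platform) scale factors at ``theta``."""
    b = data.bind(model)
    traj = solve_modified_euler(model, theta, b["times"], step_h=step_h)
    x = traj.states[b["time_inv"], b["species_idx"]]
    w = b["weight"]
    num = np.bincount(b["group_id"], weights=x * data.value * w,
                      minlength=b["n_groups"])
    den = np.bincount(b["group_id"], weights=x * x * w, minlength=b["n_groups"])
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.maximum(np.where(den > 0, num / den, 0.0), 0.0)
    pairs = list(dict.fromkeys((g, p) for g, p in zip(data.gene, data.platform)))
    return {pair: float(a[i]) for i, pair in enumerate(pairs)}


def default_log10_bounds(model: NetworkModel):
    lo = np.empty(model.n_parameters)
    hi = np.empty(model.n_parameters)
    lo[: model.n_reactions], hi[: model.n_reactions] = RATE_LOG10_BOUNDS
    lo[model.n_reactions:], hi[model.n_reactions:] = CONC_LOG10_BOUNDS
    return lo, hi


@dataclass
class ChainState:
    log10_theta: np.ndarray
    chi2: float
    widths: np.ndarray
    n_proposed: np.ndarray
    n_accepted: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        return 10.0 ** self.log10_theta

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_proposed > 0,
                            self.n_accepted / self.n_proposed, np.nan)


def metropolis_sweep(state: ChainState, objective, lo, hi, rng) -> ChainState:
    """One Metropolis update of every parameter, in random order.

    ``objective`` maps a log10-parameter vector to a chi-square; the target
    density is exp(-chi^2/2). Out-of-bounds proposals are rejected; a
    divergent proposal gets chi^2 = +inf and is rejected too. Mutates and
    returns ``state``.
    """
    x = state.log10_theta
    for p in rng.permutation(x.size):
        old = x[p]
        prop = old + rng.normal(0.0, state.widths[p])
        state.n_proposed[p] += 1
        if prop < lo[p] or prop > hi[p]:
            continue
        x[p] = prop
        new_chi2 = objective(x)
        delta = new_chi2 - state.chi2
        if delta <= 0 or rng.random() < np.exp(-0.5 * delta):
            state.chi2 = new_chi2
            state.n_accepted[p] += 1
        else:
            x[p] = old
    return state


def mcmc_sweep(state: ChainState, model: NetworkModel, data: FitDataSet,
               rng, lo=None, hi=None, step_h: float = FIT_STEP_H) -> ChainState:
    """One full-parameter Metropolis sweep against the ODE chi-square."""
    if lo is None or hi is None:
        lo, hi = default_log10_bounds(model)
    objective = lambda x: chi_square(model, 10.0 ** x, data, step_h=step_h)
    return metropolis_sweep(state, objective, lo, hi, rng)


@dataclass(frozen=True)
class Protocol:
    """Sweep counts of the two-stage fitting protocol."""

    n_chains: int = 20
    equil: int = 35000
    accum1: int = 5000
    final_accum: int = 40000
    adapt_interval: int = 25
    target_acceptance: tuple = (0.25, 0.45)
    init_width: float = 0.1

    def __post_init__(self):
        if self.n_chains < 1 or min(self.equil, self.accum1,
                                    self.final_accum) < 0:
            raise ParameterError("protocol counts must be nonnegative")


@dataclass
class EnsembleResult:
    samples_log10: np.ndarray  # (n_samples, n_parameters), accumulation phase
    chi2_trace: np.ndarray
    min_chi2: float
    best_log10_theta: np.ndarray
    acceptance_rates: np.ndarray
    protocol: Protocol
    seed: int
    chain_best_chi2: np.ndarray

    @property
    def samples(self) -> np.ndarray:
        return 10.0 ** self.samples_log10


def _adapt_widths(state: ChainState, lo_rate: float, hi_rate: float):
    rates = state.acceptance_rates()
    grow = rates > hi_rate
    shrink = rates < lo_rate
    state.widths[grow] *= 1.5
    state.widths[shrink] *= 0.7
    state.n_proposed[:] = 0
    state.n_accepted[:] = 0


def _run_chain(objective, x0, widths, lo, hi, rng, n_equil, n_accum,
               adapt_interval, target_acceptance, record_samples):
    n = x0.size
    state = ChainState(x0.copy(), objective(x0), widths.copy(),
                       np.zeros(n), np.zeros(n))
    best = (state.chi2, state.log10_theta.copy())
    lo_t, hi_t = target_acceptance
    for sweep in range(n_equil):
        metropolis_sweep(state, objective, lo, hi, rng)
        if state.chi2 < best[0]:
            best = (state.chi2, state.log10_theta.copy())
        if adapt_interval and (sweep + 1) % adapt_interval == 0:
            _adapt_widths(state, lo_t, hi_t)
    state.n_proposed[:] = 0
    state.n_accepted[:] = 0
    samples = []
    trace = []
    for _ in range(n_accum):
        metropolis_sweep(state, objective, lo, hi, rng)
        trace.append(state.chi2)
        if state.chi2 < best[0]:
            best = (state.chi2, state.log10_theta.copy())
        if record_samples:
            samples.append(state.log10_theta.copy())
    return state, best, np.asarray(samples), np.asarray(trace)


def run_protocol(model: NetworkModel, data: FitDataSet,
                 protocol: Protocol = Protocol(), seed: int = 0,
                 step_h: float = FIT_STEP_H,
                 init_log10_theta: np.ndarray | None = None) -> EnsembleResult:
    """Run the parallel-chain ensemble protocol.

    ``protocol.n_chains`` chains start from independent log-uniform random
    parameter vectors (or all from ``init_log10_theta`` when given), each
    running ``equil`` adaptation sweeps plus ``accum1`` accumulation sweeps;
    the best chi-square found seeds a final run of ``final_accum``
    accumulation sweeps whose samples form the ensemble. Chains use
    independent seeds derived from ``seed``, so results do not depend on
    scheduling order.
    """
    lo, hi = default_log10_bounds(model)
    objective = lambda x: chi_square(model, 10.0 ** x, data, step_h=step_h)
    chain_best = []
    widths0 = np.full(model.n_parameters, protocol.init_width)
    for c in range(protocol.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        if init_log10_theta is None:
            x0 = rng.uniform(lo, hi)
        else:
            x0 = np.asarray(init_log10_theta, dtype=float).copy()
        state, best, _, _ = _run_chain(
            objective, x0, widths0, lo, hi, rng, protocol.equil,
            protocol.accum1, protocol.adapt_interval,
            protocol.target_acceptance, record_samples=False)
        chain_best.append((best[0], best[1], state.widths.copy()))
    best_chi2s = np.asarray([b[0] for b in chain_best])
    if not np.any(np.isfinite(best_chi2s)):
        raise SolverDivergenceError("all chains diverged; fit failed")
    winner = int(np.argmin(best_chi2s))
    _, x_best, widths_best = chain_best[winner]
    rng = np.random.default_rng(np.random.SeedSequence([seed, protocol.n_chains]))
    state, best, samples, trace = _run_chain(
        objective, x_best, widths_best, lo, hi, rng, 0,
        protocol.final_accum, 0, protocol.target_acceptance,
        record_samples=True)
    if samples.size == 0:
        samples = x_best[None, :].copy()
        trace = np.asarray([best_chi2s[winner]])
    return EnsembleResult(samples, trace, float(min(best[0], best_chi2s[winner])),
                          best[1], state.acceptance_rates(), protocol, seed,
                          best_chi2s)


def ensemble_summary(result: EnsembleResult, model: NetworkModel, t_grid,
                     max_trajectories: int = 100,
                     step_h: float = FIT_STEP_H, floor: float = 1e-12):
    """Pointwise log10 mean and +/-2 SD bands of ensemble trajectories.

    Returns ``(species names, mean, sd)`` with mean/sd of shape
    (n_times, n_species); bands are mean +/- 2*sd.
    """
    n = result.samples_log10.shape[0]
    if n < 1:
        raise StructuralError("empty ensemble")
    take = np.unique(np.linspace(0, n - 1, min(max_trajectories, n)).astype(int))
    logs = []
    for i in take:
        traj = solve_modified_euler(model, 10.0 ** result.samples_log10[i],
                                    np.asarray(t_grid, dtype=float), step_h=step_h)
        logs.append(np.log10(np.maximum(traj.states, floor)))
    logs = np.stack(logs)
    # population SD across the ensemble (n=2 gives the half-difference)
    return ([s.name for s in model.species], logs.mean(axis=0),
            logs.std(axis=0))


def chi2_difference_test(chi2_null: float, chi2_alt: float, df: int):
    """Nested-model comparison by the difference of minimum chi-squares.

    Returns ``(delta, p)`` where delta = chi2_null - chi2_alt and p is the
    upper tail of the chi-square distribution with ``df`` degrees of
    freedom; a nonpositive delta gives p = 1.
    """
    if df < 1:
        raise ParameterError("df must be >= 1")
    delta = chi2_null - chi2_alt
    if delta <= 0:
        return float(delta), 1.0
    return float(delta), float(stats.chi2.sf(delta, df))
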