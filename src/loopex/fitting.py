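"""Global chi-square inference across heterogeneous NMR experiments.

A single two-site exchange model is fit simultaneously to CEST, CPMG, EXSY,
inversion-recovery and 1D-spectrum datasets from multiple sample conditions.
Parameter sharing is expressed through a :class:`ParameterGraph`: each
dataset's ``param_map`` points the roles its forward model needs (p_E, k_ex,
shifts, relaxation rates, PREs, scales) at named global parameters, so e.g.
both complexes can share the probe's chemical shifts while keeping their own
populations and rates.  The target function is

    chi2 = sum_exp sum_i ((O_exp,i - O_calc,i) / sigma_exp,i)^2

minimized with a derivative-free simplex on transformed coordinates
(logit for populations, log for rates/times/scales) so box constraints are
honoured without a constrained optimizer.  Uncertainties come from a
parametric bootstrap: artificial datasets are drawn from the best-fit
prediction plus Gaussian noise at the measurement sigmas, start values are
jittered by 5%, and the model is refit to each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import Dataset, DatasetCollection
from .exchange import (ExchangeModel, simulate_cest, simulate_cpmg,
                       simulate_exsy, simulate_ir_two_state,
                       simulate_lineshape)

__all__ = [
    "Parameter", "ParameterGraph", "GlobalModel", "FitResult",
    "chi2", "assemble_global_model", "fit_global",
    "monte_carlo_uncertainty", "rms_noise",
]


def chi2(observed, calculated, sigmas) -> float:
    """Sum of squared sigma-weighted residuals; additive over datasets."""
    o = np.asarray(observed, dtype=float)
    c = np.asarray(calculated, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    return float(np.sum(((o - c) / s) ** 2))


def rms_noise(values, baseline_fraction: float = 0.2) -> float:
    """Convenience sigma estimator: RMS deviation in the flattest tail.

    Takes the ``baseline_fraction`` of points with the smallest absolute
    deviation from the median (a proxy for signal-free baseline) and
    returns their standard deviation.
    """
    v = np.asarray(values, dtype=float)
    dev = np.abs(v - np.median(v))
    k = max(3, int(baseline_fraction * v.size))
    idx = np.argsort(dev)[:k]
    return float(np.std(v[idx], ddof=1))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class Parameter:
    """One named global parameter with its optimization transform.

    transform: 'linear' (unbounded), 'log' (positive) or 'logit'
    (bounded to (lo, hi), default (0, 1)).
    """

    name: str
    value: float
    vary: bool = True
    transform: str = "linear"
    lo: float = 0.0
    hi: float = 1.0

    def to_internal(self, v: float) -> float:
        if self.transform == "log":
            if v <= 0:
                raise ValueError(f"{self.name}: log transform needs v > 0")
            return np.log(v)
        if self.transform == "logit":
            u = (v - self.lo) / (self.hi - self.lo)
            u = np.clip(u, 1e-12, 1 - 1e-12)
            return np.log(u / (1 - u))
        return v

    def to_external(self, x: float) -> float:
        if self.transform == "log":
            return float(np.exp(x))
        if self.transform == "logit":
            return float(self.lo + (self.hi - self.lo) / (1 + np.exp(-x)))
        return float(x)


class ParameterGraph:
    """Named parameters plus the share structure implied by datasets.

    Sharing is positional: two datasets that map a role to the same
    parameter name share that parameter.  Fixed parameters (vary=False)
    are immutable during optimization.
    """

    def __init__(self, parameters: list[Parameter] | None = None):
        self._params: dict[str, Parameter] = {}
        for p in parameters or []:
            self.add(p)

    def add(self, p: Parameter) -> None:
        if p.name in self._params:
            raise ValueError(f"duplicate parameter {p.name!r}")
        self._params[p.name] = p

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    @property
    def names(self) -> list[str]:
        return list(self._params)

    @property
    def free_names(self) -> list[str]:
        return [n for n, p in self._params.items() if p.vary]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def values(self) -> dict[str, float]:
        return {n: p.value for n, p in self._params.items()}

    def to_internal(self, values: dict[str, float]) -> np.ndarray:
        return np.array([self._params[n].to_internal(values[n])
                         for n in self.free_names])

    def to_external(self, x: np.ndarray) -> dict[str, float]:
        out = {n: p.value for n, p in self._params.items()}
        for n, xi in zip(self.free_names, x):
            out[n] = self._params[n].to_external(xi)
        return out

    def copy(self) -> "ParameterGraph":
        return ParameterGraph([replace(p) for p in self._params.values()])


# ---------------------------------------------------------------------------
# forward-model dispatch
# ---------------------------------------------------------------------------

#: 19F frequency (MHz) at which shift parameters are expressed in Hz
REFERENCE_FREQ_MHZ = 471.0

_ROLES = {
    "CEST": ("p_E", "k_ex", "omega_G", "omega_E", "R1_G", "R1_E",
             "R2_G", "R2_E"),
    "CPMG": ("p_E", "k_ex", "omega_G", "omega_E", "R2_inf"),
    "EXSY": ("p_E", "k_ex", "R1_G", "R1_E", "scale"),
    "IR": ("p_E", "k_ex", "R1_G", "R1_E", "Gamma1_G", "Gamma1_E", "scale"),
    "SPECTRUM": ("p_E", "k_ex", "omega_G", "omega_E", "R2_G", "R2_E",
                 "Gamma2_G", "Gamma2_E", "scale"),
}

_ROLE_DEFAULTS = {"Gamma1_G": 0.0, "Gamma1_E": 0.0, "Gamma2_G": 0.0,
                  "Gamma2_E": 0.0, "scale": 1.0, "omega_G": 0.0,
                  "omega_E": 0.0, "R1_G": 1.0, "R1_E": 1.0}


def _resolve(ds: Dataset, values: dict[str, float]) -> dict[str, float]:
    roles = {}
    for role in _ROLES[ds.kind]:
        if role in ds.param_map:
            roles[role] = values[ds.param_map[role]]
        elif role in _ROLE_DEFAULTS:
            roles[role] = _ROLE_DEFAULTS[role]
        else:
            raise KeyError(f"dataset {ds.name}: role {role!r} unmapped and "
                           "has no default")
    if ds.tags.get("rna") == "plusRNA":
        # RNA-bound complexes are taken to be 100% in the open conformation
        roles["p_E"] = 0.0
    return roles


def _predict(ds: Dataset, roles: dict[str, float]) -> np.ndarray:
    kind = ds.kind
    if kind == "CEST":
        model = ExchangeModel(p_E=roles["p_E"], k_ex=roles["k_ex"],
                              omega_G=roles["omega_G"], omega_E=roles["omega_E"],
                              R1_G=roles["R1_G"], R1_E=roles["R1_E"],
                              R2_G=roles["R2_G"], R2_E=roles["R2_E"])
        return simulate_cest(model, ds.schedule)
    if kind == "CPMG":
        # shift parameters are Hz at the reference 19F field (471 MHz);
        # dispersion at other fields rescales them by the field ratio
        f = ds.schedule.spectrometer_freq / REFERENCE_FREQ_MHZ
        model = ExchangeModel(p_E=roles["p_E"], k_ex=roles["k_ex"],
                              omega_G=f * roles["omega_G"],
                              omega_E=f * roles["omega_E"],
                              R2_G=roles["R2_inf"], R2_E=roles["R2_inf"])
        return simulate_cpmg(model, ds.schedule)
    if kind == "EXSY":
        model = ExchangeModel(p_E=roles["p_E"], k_ex=roles["k_ex"],
                              R1_G=roles["R1_G"], R1_E=roles["R1_E"])
        sched = replace(ds.schedule, scale=roles["scale"])
        return simulate_exsy(model, sched).reshape(-1)
    if kind == "IR":
        model = ExchangeModel(p_E=roles["p_E"], k_ex=roles["k_ex"],
                              R1_G=roles["R1_G"], R1_E=roles["R1_E"],
                              Gamma1_G=roles["Gamma1_G"],
                              Gamma1_E=roles["Gamma1_E"])
        sched = replace(ds.schedule, I_inf=roles["scale"])
        return simulate_ir_two_state(model, sched)
    # SPECTRUM
    model = ExchangeModel(p_E=roles["p_E"], k_ex=roles["k_ex"],
                          omega_G=roles["omega_G"], omega_E=roles["omega_E"],
                          R2_G=roles["R2_G"], R2_E=roles["R2_E"],
                          Gamma2_G=roles["Gamma2_G"], Gamma2_E=roles["Gamma2_E"])
    use_pre = ds.tags.get("pre_state") == "para"
    grid = replace(ds.schedule, scale=roles["scale"])
    return simulate_lineshape(model, grid, use_pre=use_pre)


class GlobalModel:
    """Residual function dispatching each dataset to its forward model."""

    def __init__(self, data: DatasetCollection, graph: ParameterGraph):
        self.data = data
        self.graph = graph
        self._validate()

    def _validate(self) -> None:
        used: set[str] = set()
        for ds in self.data:
            for role, pname in ds.param_map.items():
                if role not in _ROLES[ds.kind]:
                    raise KeyError(f"dataset {ds.name}: role {role!r} not "
                                   f"used by {ds.kind} forward model")
                if pname not in self.graph:
                    raise KeyError(f"dataset {ds.name}: parameter {pname!r} "
                                   "missing from graph")
                used.add(pname)
            _resolve(ds, self.graph.values())   # raises on unmapped roles
        orphans = [n for n in self.graph.free_names if n not in used]
        if orphans:
            raise ValueError(f"free parameters not linked to any dataset: "
                             f"{orphans}")

    def predict(self, values: dict[str, float]) -> dict[str, np.ndarray]:
        return {ds.name: _predict(ds, _resolve(ds, values)) for ds in self.data}

    def chi2_by_dataset(self, values: dict[str, float]) -> dict[str, float]:
        pred = self.predict(values)
        return {ds.name: chi2(ds.y, pred[ds.name], ds.sigma)
                for ds in self.data}

    def chi2(self, values: dict[str, float]) -> float:
        return float(sum(self.chi2_by_dataset(values).values()))


def assemble_global_model(data: DatasetCollection,
                          graph: ParameterGraph) -> GlobalModel:
    """Validate dataset/parameter links and return the residual machinery."""
    return GlobalModel(data, graph)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: dict[str, float]
    chi2: float
    chi2_by_dataset: dict[str, float]
    n_free: int
    n_points: int
    nfev: int
    converged: bool
    start: dict[str, float]
    mc_samples: pd.DataFrame | None = None
    mc_sd: dict[str, float] | None = None
    mc_quantiles: pd.DataFrame | None = None
    mc_n_failed: int = 0

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_points - self.n_free, 1)
        return self.chi2 / dof

    def write(self, directory) -> None:
        """Emit results as JSON (parameters, SDs, chi2) + TSV (MC samples)."""
        import json
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {"params": self.params, "chi2": self.chi2,
                   "chi2_by_dataset": self.chi2_by_dataset,
                   "n_free": self.n_free, "n_points": self.n_points,
                   "converged": self.converged, "mc_sd": self.mc_sd,
                   "mc_n_failed": self.mc_n_failed}
        (directory / "fit.json").write_text(json.dumps(payload, indent=1))
        if self.mc_samples is not None:
            self.mc_samples.to_csv(directory / "mc_samples.tsv", sep="\t",
                                   index=False)

    def summary(self) -> str:
        lines = [f"chi2 = {self.chi2:.6g} over {self.n_points} points, "
                 f"{self.n_free} free parameters"]
        for k, v in self.params.items():
            sd = ""
            if self.mc_sd and k in self.mc_sd:
                sd = f" +/- {self.mc_sd[k]:.3g}"
            lines.append(f"  {k} = {v:.6g}{sd}")
        return "\n".join(lines)


def fit_global(data: DatasetCollection, graph: ParameterGraph,
               start: dict[str, float] | None = None,
               maxfev: int = 20000, restarts: int = 1,
               xatol: float = 1e-6, fatol: float = 1e-8) -> FitResult:
    """Minimize the global chi-square with a Nelder-Mead simplex.

    The simplex runs on transformed coordinates and is restarted
    ``restarts`` times from its own best vertex to escape premature
    collapse.  Deterministic for identical data and start values.
    """
    model = assemble_global_model(data, graph)
    values0 = dict(graph.values())
    if start:
        unknown = set(start) - set(graph.names)
        if unknown:
            raise KeyError(f"start values for unknown parameters: {unknown}")
        values0.update(start)
    x0 = graph.to_internal(values0)

    def objective(x: np.ndarray) -> float:
        try:
            return model.chi2(graph.to_external(x))
        except (FloatingPointError, ZeroDivisionError, np.linalg.LinAlgError):
            return 1e300

    nfev = 0
    converged = False
    best = x0
    fbest = objective(x0)
    # fatol is interpreted relative to the chi2 scale so termination does
    # not depend on the units of sigma; xatol on the transformed parameters
    # remains the binding criterion
    fatol_eff = max(fatol, 1e-9 * (1.0 + abs(fbest)))
    for _ in range(restarts + 1):
        res = minimize(objective, best, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": xatol,
                                "fatol": fatol_eff, "adaptive": True})
        nfev += res.nfev
        if res.fun <= fbest + 1e-300:
            prev, fbest, best = fbest, res.fun, res.x
            converged = res.success or (
                prev > 0 and abs(prev - fbest) / max(prev, 1e-300) < 1e-10)
    if not converged and fbest > 1e-6:
        warnings.warn(f"simplex did not fully converge (chi2={fbest:.4g}, "
                      f"nfev={nfev})")
    params = graph.to_external(best)
    return FitResult(params=params, chi2=float(fbest),
                     chi2_by_dataset=model.chi2_by_dataset(params),
                     n_free=graph.n_free, n_points=data.n_points,
                     nfev=nfev, converged=bool(converged), start=values0)


def monte_carlo_uncertainty(fit: FitResult, data: DatasetCollection,
                            graph: ParameterGraph, n: int = 200,
                            jitter: float = 0.05, seed: int = 0,
                            maxfev: int = 20000) -> FitResult:
    """Parametric-bootstrap uncertainties for a converged fit.

    For each of ``n`` replicates, observations are resampled as the
    best-fit prediction plus Gaussian(0, sigma_i) noise, start values are
    varied uniformly by +/- ``jitter`` (fraction), and the model is refit.
    Per-parameter standard deviations, full sample distributions and
    2.5/16/50/84/97.5% quantiles are attached to the returned FitResult
    (the distributions are not necessarily Gaussian, so quantiles are
    reported alongside the SD).  Replicates that fail to converge are
    excluded and counted.  A single top-level seed fans out
    deterministically to per-replicate seeds.
    """
    model = assemble_global_model(data, graph)
    best_pred = model.predict(fit.params)
    free = graph.free_names
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    rows, n_failed = [], 0
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        rep = DatasetCollection(truth=data.truth)
        for ds in data:
            y_rep = best_pred[ds.name] + rng.normal(0.0, ds.sigma)
            rep.add(Dataset(name=ds.name, kind=ds.kind, schedule=ds.schedule,
                            y=y_rep, sigma=ds.sigma, tags=ds.tags,
                            param_map=ds.param_map))
        start = dict(fit.params)
        for name in free:
            f = 1.0 + rng.uniform(-jitter, jitter)
            start[name] = fit.params[name] * f
        try:
            r = fit_global(rep, graph, start=start, maxfev=maxfev, restarts=0)
        except Exception:
            n_failed += 1
            continue
        rows.append({k: r.params[k] for k in free})
    if not rows:
        raise RuntimeError("all Monte-Carlo replicates failed")
    samples = pd.DataFrame(rows)
    qs = samples.quantile([0.025, 0.16, 0.5, 0.84, 0.975])
    return replace(fit, mc_samples=samples,
                   mc_sd={k: float(samples[k].std(ddof=1)) for k in free},
                   mc_quantiles=qs, mc_n_failed=n_failed)
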