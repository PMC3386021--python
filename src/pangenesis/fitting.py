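"""Least-squares fitting of models A-D to observed gene frequency spectra.

The objective is the mean square difference of the square-root-transformed
spectra,

    Delta = (1/G) * sum_k (sqrt(g_k^obs) - sqrt(g_k^pred))^2,

which balances the heavy tips of the U-shape (k = 1 and k = G) against the
sparse middle (an untransformed objective over-weights the tips, a log
transform over-weights the middle).  The k = G bin is included.

Model A is a 1-D problem in log theta; models C and D add the fluid fraction
lambda1 (optimized on the logit scale) and a second transfer rate; model B's
predicted spectrum is a coalescent Monte Carlo average, made deterministic
per fit by common random numbers (a fixed seed shared by every objective
evaluation, so the optimizer sees a smooth surface).

Each fit runs a log-spaced multi-start grid followed by local refinement
(bounded Brent for model A, Nelder-Mead otherwise) and returns the best
point.  Model D receives the fitted model-A and model-C solutions as extra
candidates (theta2 = theta1 and theta2 = 0 respectively), so the nesting
inequalities Delta_D <= Delta_A, Delta_C hold structurally.  Model D is
symmetric under swapping its two compartments, so the optimizer runs
unconstrained and the convention theta1 >= theta2 is applied afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .coalescent import ModelBParams, spectrum_model_b
from .fluidity import fluidity_expected_from_spectrum
from .spectra import (
    THETA_CAP,
    GeneFrequencySpectrum,
    ModelAParams,
    ModelCParams,
    ModelDParams,
    spectrum_model_a,
    spectrum_model_c,
    spectrum_model_d,
)

__all__ = ["FitResult", "distance", "fit", "fit_all", "fit_report"]

_LOG_THETA_LO, _LOG_THETA_HI = math.log(1e-4), math.log(1e3)


def distance(obs, pred) -> float:
    """Square-root-transform distance Delta between two spectra.

    Accepts GeneFrequencySpectrum objects or plain non-negative vectors of
    equal length.
    """
    go = obs.g if isinstance(obs, GeneFrequencySpectrum) else np.asarray(obs, float)
    gp = pred.g if isinstance(pred, GeneFrequencySpectrum) else np.asarray(pred, float)
    if go.shape != gp.shape:
        raise ValueError(f"spectrum length mismatch: {go.shape} vs {gp.shape}")
    if np.any(go < 0) or np.any(gp < 0):
        raise ValueError("spectra must be non-negative")
    return float(np.mean((np.sqrt(go) - np.sqrt(gp)) ** 2))


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``params`` is the fitted parameter dataclass, ``delta`` the achieved
    distance, ``spectrum`` the predicted spectrum at the observed (G, M).
    ``diagnostics`` holds the optimizer trace: number of objective
    evaluations, grid landscape (model B), warnings, the CRN seed.
    """

    model: str
    params: Any
    delta: float
    spectrum: GeneFrequencySpectrum
    n_eval: int = 0
    converged: bool = True
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def phi_pred(self) -> float:
        """Model-predicted genomic fluidity (exchangeable equal-M formula)."""
        return fluidity_expected_from_spectrum(self.spectrum)


def _infer_M(obs: GeneFrequencySpectrum) -> float:
    """Mean genes per genome, sum_k k*g_k / G, rounded to an integer."""
    return max(1.0, round(obs.total_gene_mass() / obs.G))


class _Counter:
    def __init__(self):
        self.n = 0


def _sigmoid(y: float) -> float:
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    e = math.exp(y)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1.0 - p))


def _fit_model_a(obs: GeneFrequencySpectrum, M: float, options: dict) -> FitResult:
    G = obs.G
    counter = _Counter()

    def objective(logtheta: float) -> float:
        counter.n += 1
        return distance(obs, spectrum_model_a(math.exp(logtheta), M, G))

    grid = np.linspace(_LOG_THETA_LO, _LOG_THETA_HI, options.get("grid_size", 61))
    vals = [objective(x) for x in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    logtheta = float(res.x)
    if res.fun > vals[i]:
        logtheta = float(grid[i])
    theta = math.exp(logtheta)
    diagnostics: dict = {}
    if i == 0 and vals[0] <= min(vals):
        diagnostics["warning"] = (
            "theta at lower search bound; data may be degenerate "
            "(all genes in the core)")
    delta = objective(logtheta)
    return FitResult("A", ModelAParams(theta), delta,
                     spectrum_model_a(theta, M, G),
                     n_eval=counter.n, converged=bool(res.success),
                     diagnostics=diagnostics)


def _nelder_mead(objective, starts: list[np.ndarray], options: dict):
    best = None
    maxiter = options.get("maxiter", 400)
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12,
                                "maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    return best


def _fit_model_c(obs: GeneFrequencySpectrum, M: float, options: dict) -> FitResult:
    G = obs.G
    counter = _Counter()

    def objective(x: np.ndarray) -> float:
        counter.n += 1
        theta1 = math.exp(min(x[0], math.log(THETA_CAP)))
        lam1 = _sigmoid(x[1])
        return distance(obs, spectrum_model_c(ModelCParams(theta1, lam1), M, G))

    thetas = np.linspace(math.log(1e-3), math.log(1e2), options.get("grid_size", 7))
    lams = np.linspace(0.05, 0.95, options.get("grid_size", 7))
    grid = [np.array([t, _logit(l)]) for t in thetas for l in lams]
    vals = [objective(x) for x in grid]
    order = np.argsort(vals)
    starts = [grid[j] for j in order[: options.get("n_starts", 3)]]
    res = _nelder_mead(objective, starts, options)
    theta1 = math.exp(min(res.x[0], math.log(THETA_CAP)))
    lam1 = _sigmoid(res.x[1])
    params = ModelCParams(theta1, lam1)
    pred = spectrum_model_c(params, M, G)
    return FitResult("C", params, distance(obs, pred), pred,
                     n_eval=counter.n, converged=bool(res.success))


def _fit_model_d(obs: GeneFrequencySpectrum, M: float, options: dict,
                 fit_a: FitResult, fit_c: FitResult) -> FitResult:
    G = obs.G
    counter = _Counter()

    def predict(theta1: float, theta2: float, lam1: float) -> GeneFrequencySpectrum:
        t1, t2 = (theta1, theta2) if theta1 >= theta2 else (theta2, theta1)
        l1 = lam1 if theta1 >= theta2 else 1.0 - lam1
        return spectrum_model_d(ModelDParams(t1, t2, l1), M, G)

    def objective(x: np.ndarray) -> float:
        counter.n += 1
        theta1 = math.exp(min(x[0], math.log(THETA_CAP)))
        theta2 = math.exp(min(x[1], math.log(THETA_CAP)))
        lam1 = _sigmoid(x[2])
        return distance(obs, predict(theta1, theta2, lam1))

    n = options.get("grid_size", 5)
    t1s = np.linspace(math.log(1e-2), math.log(1e2), n)
    t2s = np.linspace(math.log(1e-3), math.log(1e1), n)
    lams = np.linspace(0.1, 0.9, n)
    grid = [np.array([a, b, _logit(l)]) for a in t1s for b in t2s for l in lams]
    a = fit_a.params.theta
    grid.append(np.array([math.log(max(a, 1e-12)), math.log(max(a, 1e-12)),
                          _logit(0.5)]))
    vals = [objective(x) for x in grid]
    order = np.argsort(vals)
    starts = [grid[j] for j in order[: options.get("n_starts", 3)]]
    res = _nelder_mead(objective, starts, options)
    theta1 = math.exp(min(res.x[0], math.log(THETA_CAP)))
    theta2 = math.exp(min(res.x[1], math.log(THETA_CAP)))
    lam1 = _sigmoid(res.x[2])
    if theta1 < theta2:  # canonical order: compartment 1 is the fluid one
        theta1, theta2, lam1 = theta2, theta1, 1.0 - lam1
    candidates = [(ModelDParams(theta1, theta2, lam1), float(res.fun))]
    # exact nested candidates: A (theta2 = theta1) and C (theta2 = 0)
    candidates.append((ModelDParams(a, a, 0.5), fit_a.delta))
    cpar = fit_c.params
    candidates.append((ModelDParams(cpar.theta1, 0.0, cpar.lambda1), fit_c.delta))
    best_params, _ = min(candidates, key=lambda pd_: pd_[1])
    pred = spectrum_model_d(best_params, M, G)
    delta = distance(obs, pred)
    notes = {}
    if best_params.theta2 == 0.0:
        notes["note"] = "theta2 = 0: model-C-equivalent fit"
    return FitResult("D", best_params, delta, pred,
                     n_eval=counter.n, converged=bool(res.success),
                     diagnostics=notes)


def _flat_valley(theta0s: np.ndarray, betas: np.ndarray,
                 deltas: np.ndarray) -> bool:
    """Flag near-degenerate objective landscapes.

    True when grid points whose Delta is within 5% of the grid range above
    the minimum span at least a factor 10 in theta0: very different
    parameter combinations then fit almost equally well.
    """
    dmin, dmax = deltas.min(), deltas.max()
    if dmax <= dmin:
        return True
    mask = deltas <= dmin + 0.05 * (dmax - dmin)
    th = np.broadcast_to(theta0s[:, None], deltas.shape)[mask]
    return bool(th.size >= 2 and th.max() / th.min() >= 10.0)


def _fit_model_b(obs: GeneFrequencySpectrum, M: float, options: dict,
                 seed: int | None) -> FitResult:
    G = obs.G
    n_trees = options.get("n_trees", 2000)
    polish_trees = options.get("polish_trees", 2 * n_trees)
    crn_seed = 0 if seed is None else int(seed)
    counter = _Counter()

    def predict(theta0: float, beta: float, nt: int) -> GeneFrequencySpectrum:
        return spectrum_model_b(ModelBParams(theta0, beta), M, G,
                                n_trees=nt, rng=crn_seed)

    def objective(x: np.ndarray) -> float:
        counter.n += 1
        theta0 = math.exp(min(x[0], math.log(THETA_CAP)))
        beta = math.exp(x[1])
        return distance(obs, predict(theta0, beta, n_trees))

    ng = options.get("grid_size", 5)
    theta0s = np.exp(np.linspace(math.log(1e-2), math.log(30.0), ng))
    betas = np.exp(np.linspace(math.log(0.1), math.log(1e3), ng))
    deltas = np.empty((ng, ng))
    for i, t0 in enumerate(theta0s):
        for j, b in enumerate(betas):
            deltas[i, j] = objective(np.array([math.log(t0), math.log(b)]))
    i0, j0 = np.unravel_index(np.argmin(deltas), deltas.shape)
    x0 = np.array([math.log(theta0s[i0]), math.log(betas[j0])])
    res = _nelder_mead(objective, [x0],
                       {**options, "maxiter": options.get("maxiter", 120)})
    theta0 = math.exp(min(res.x[0], math.log(THETA_CAP)))
    beta = math.exp(res.x[1])
    params = ModelBParams(theta0, beta)
    pred = predict(theta0, beta, polish_trees)
    diagnostics = {
        "grid_theta0": theta0s, "grid_beta": betas, "grid_delta": deltas,
        "flat_valley": _flat_valley(theta0s, betas, deltas),
        "crn_seed": crn_seed, "n_trees": n_trees,
    }
    return FitResult("B", params, distance(obs, pred), pred,
                     n_eval=counter.n, converged=bool(res.success),
                     seed=crn_seed, diagnostics=diagnostics)


def fit(obs: GeneFrequencySpectrum, model: str = "A", M: float | None = None,
        seed: int | None = None, options: dict | None = None) -> FitResult:
    """Fit one model to an observed spectrum by minimizing Delta.

    Parameters
    ----------
    obs
        Observed spectrum (counts g_1..g_G).
    model
        One of "A", "B", "C", "D".
    M
        Genes per genome used for predictions; defaults to the data-derived
        mean sum_k k*g_k / G (rounded).  Pass the species value to override.
    seed
        Common-random-numbers seed for the model-B objective (ignored by the
        closed-form models).
    options
        Optimizer knobs: grid_size, n_starts, maxiter, n_trees (model B),
        polish_trees.
    """
    options = dict(options or {})
    if M is None:
        M = _infer_M(obs)
    model = model.upper()
    if model == "A":
        return _fit_model_a(obs, M, options)
    if model == "C":
        return _fit_model_c(obs, M, options)
    if model == "D":
        fa = _fit_model_a(obs, M, options)
        fc = _fit_model_c(obs, M, options)
        return _fit_model_d(obs, M, options, fa, fc)
    if model == "B":
        return _fit_model_b(obs, M, options, seed)
    raise ValueError(f"unknown model {model!r}")


def fit_all(obs: GeneFrequencySpectrum, M: float | None = None,
            seed: int | None = None,
            options: dict | None = None) -> list[FitResult]:
    """Fit models A, B, C and D and return the results in that order."""
    return [fit(obs, m, M=M, seed=seed, options=options) for m in "ABCD"]


def _fmt_theta(theta: float) -> str:
    if math.isinf(theta) or theta >= THETA_CAP:
        return "inf"
    return f"{theta:.3g}"


def fit_report(results: list[FitResult]) -> tuple[pd.DataFrame, list[str]]:
    """Tabulate fits: per-model Delta, parameters and predicted fluidity.

    Parameters are rendered with the compartment fraction lambda in
    parentheses; infinite/capped transfer rates render as "inf".  Returns the
    table (one row per result) and a list of notes (e.g. a model-D fit that
    collapsed onto model C).
    """
    if not results:
        raise ValueError("no fit results to report")
    rows = []
    notes: list[str] = []
    for r in results:
        p = r.params
        if r.model == "A":
            pstr = f"theta={_fmt_theta(p.theta)}"
        elif r.model == "B":
            pstr = f"theta0={_fmt_theta(p.theta0)} beta={p.beta:.3g}"
        elif r.model == "C":
            pstr = (f"theta1={_fmt_theta(p.theta1)} ({p.lambda1:.2f}) "
                    f"theta2=0 ({p.lambda2:.2f})")
        else:
            pstr = (f"theta1={_fmt_theta(p.theta1)} ({p.lambda1:.2f}) "
                    f"theta2={_fmt_theta(p.theta2)} ({p.lambda2:.2f})")
            if p.theta2 == 0.0:
                notes.append("model D fit has theta2 = 0 (model-C-equivalent)")
        rows.append({
            "model": r.model,
            "n_params": {"A": 1, "B": 2, "C": 2, "D": 3}[r.model],
            "delta": r.delta,
            "params": pstr,
            "phi_pred": round(r.phi_pred(), 4),
            "converged": r.converged,
        })
        if r.diagnostics.get("flat_valley"):
            notes.append(
                f"model {r.model}: flat objective valley on the start grid "
                "(distinct parameter combinations fit nearly equally well)")
        if "warning" in r.diagnostics:
            notes.append(f"model {r.model}: {r.diagnostics['warning']}")
        if "note" in r.diagnostics:
            notes.append(f"model {r.model}: {r.diagnostics['note']}")
    return pd.DataFrame(rows), notes
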