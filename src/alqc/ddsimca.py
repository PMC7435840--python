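"""Data-driven SIMCA (DD-SIMCA) one-class classification of NIR spectra.

A target class (one tablet brand) is modelled by PCA of its autoscaled
training spectra.  For each sample, a score distance ``h`` (leverage within
the PC subspace) and an orthogonal distance ``v`` (squared residual norm)
are computed; both are treated as scaled chi-square variables whose degrees
of freedom ``N_h``, ``N_v`` are estimated from the training set by the
method of moments.  The combined statistic

    c = N_h * h / h0 + N_v * v / v0   ~   chi2(N_h + N_v)

defines a data-driven acceptance area at significance level alpha: a sample
is a class member iff ``c <= chi2.ppf(1 - alpha, N_h + N_v)``.  The usual
visualisation plots ``ln(1 + h/h0)`` against ``ln(1 + v/v0)`` together with
the boundary curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import (
    PreprocessConfig,
    PreprocessState,
    apply_preprocess,
    fit_preprocess,
    state_from_dict,
    state_to_dict,
)
from .spectra import SpectraSet

MAX_DOF = 250
DEFAULT_A_GRID = (1, 2, 3, 4, 5)
DEFAULT_ALPHA_GRID = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class DdSimcaModel:
    """Fitted one-class model; all arrays refer to kept variables only."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray                  # indices of variables kept (nonzero SD)
    loadings: np.ndarray              # (n_kept, A)
    eigenvalues: np.ndarray           # (A,)
    A: int
    alpha: float
    h0: float
    v0: float
    N_h: int
    N_v: int
    c_crit: float
    n_variables: int                  # before dropping zero-variance ones
    preprocess_state: PreprocessState | None = None

    def with_alpha(self, alpha: float) -> "DdSimcaModel":
        """Same decomposition, new significance level (and critical value)."""
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        return replace(
            self, alpha=alpha, c_crit=float(stats.chi2.ppf(1 - alpha, self.N_h + self.N_v))
        )


def _moment_dof(x: np.ndarray, what: str) -> tuple[float, int]:
    """Scale and degrees of freedom of a scaled chi-square by moment matching."""
    x0 = float(x.mean())
    var = float(x.var(ddof=1))
    if var <= 0:
        warnings.warn(f"zero variance of {what} distances; clamping dof to {MAX_DOF}")
        return x0, MAX_DOF
    n = int(np.clip(round(2.0 * x0 * x0 / var), 1, MAX_DOF))
    return x0, n


def _autoscaled(model: DdSimcaModel, X: np.ndarray) -> np.ndarray:
    return (X[:, model.kept] - model.mean) / model.sd


def _hv(model: DdSimcaModel, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    T = Z @ model.loadings
    h = np.sum(T**2 / model.eigenvalues, axis=1)
    resid = Z - T @ model.loadings.T
    v = np.sum(resid**2, axis=1)
    return h, v


def fit(
    training: SpectraSet | np.ndarray,
    A: int,
    alpha: float,
    preprocess: PreprocessConfig | None = None,
) -> DdSimcaModel:
    """Fit a DD-SIMCA model on target-class training spectra.

    If a :class:`PreprocessConfig` is given, the preprocessing chain is
    fitted on the training set (class-mean MSC reference) and stored in the
    model, and all later inputs to :func:`distances` are expected raw.
    Zero-variance variables (possible for constant channels) are dropped
    with a warning before autoscaling.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    state = None
    if preprocess is not None:
        if not isinstance(training, SpectraSet):
            raise TypeError("preprocessing requires a SpectraSet input")
        training, state = fit_preprocess(training, preprocess)
    X = training.values if isinstance(training, SpectraSet) else np.atleast_2d(np.asarray(training, float))
    I, J = X.shape
    if A < 1:
        raise ValueError("A must be >= 1")
    if I < A + 2:
        raise ValueError(f"need at least A + 2 = {A + 2} training samples, got {I}")

    sd_full = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd_full > 1e-12)
    if kept.size < J:
        warnings.warn(
            f"dropping {J - kept.size} zero-variance variable(s) before autoscaling: "
            f"{np.setdiff1d(np.arange(J), kept).tolist()}"
        )
    if kept.size <= A:
        raise ValueError("not enough informative variables for the requested A")
    mean = X[:, kept].mean(axis=0)
    sd = sd_full[kept]
    Z = (X[:, kept] - mean) / sd

    _, sv, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:A].T.copy()
    for a in range(A):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] = -loadings[:, a]
    eigenvalues = sv[:A] ** 2 / (I - 1)
    if np.any(eigenvalues <= 0):
        raise ValueError("rank of the training set is below the requested A")

    model = DdSimcaModel(
        mean=mean,
        sd=sd,
        kept=kept,
        loadings=loadings,
        eigenvalues=eigenvalues,
        A=A,
        alpha=alpha,
        h0=1.0,
        v0=1.0,
        N_h=1,
        N_v=1,
        c_crit=1.0,
        n_variables=J,
        preprocess_state=state,
    )
    h, v = _hv(model, Z)
    h0, N_h = _moment_dof(h, "score")
    v0, N_v = _moment_dof(v, "orthogonal")
    model.h0, model.N_h = h0, N_h
    model.v0, model.N_v = v0, N_v
    model.c_crit = float(stats.chi2.ppf(1 - alpha, N_h + N_v))
    return model


def distances(model: DdSimcaModel, spectra: SpectraSet | np.ndarray) -> pd.DataFrame:
    """Score/orthogonal distances and acceptance verdicts for a sample set.

    Raw spectra are pushed through the model's stored preprocessing state
    when one is present.  Returns one row per sample with columns
    ``sample_id, h, v, c, accepted, plot_x, plot_y``.
    """
    if model.preprocess_state is not None:
        if not isinstance(spectra, SpectraSet):
            raise TypeError("this model stores a preprocessing state; pass a SpectraSet")
        spectra = apply_preprocess(spectra, model.preprocess_state)
    X = spectra.values if isinstance(spectra, SpectraSet) else np.atleast_2d(np.asarray(spectra, float))
    if X.shape[1] != model.n_variables:
        raise ValueError(
            f"samples have {X.shape[1]} variables, model expects {model.n_variables}"
        )
    ids = (
        spectra.sample_ids
        if isinstance(spectra, SpectraSet)
        else [f"s{i}" for i in range(X.shape[0])]
    )
    h, v = _hv(model, _autoscaled(model, X))
    c = model.N_h * h / model.h0 + model.N_v * v / model.v0
    return pd.DataFrame(
        {
            "sample_id": ids,
            "h": h,
            "v": v,
            "c": c,
            "accepted": c <= model.c_crit,
            "plot_x": np.log1p(h / model.h0),
            "plot_y": np.log1p(v / model.v0),
        }
    )


def classify_set(model: DdSimcaModel, spectra) -> pd.DataFrame:
    """Acceptance flags for a set (empty set -> empty frame)."""
    n = spectra.n_samples if isinstance(spectra, SpectraSet) else np.atleast_2d(spectra).shape[0]
    if n == 0:
        return pd.DataFrame(columns=["sample_id", "h", "v", "c", "accepted", "plot_x", "plot_y"])
    return distances(model, spectra)


@dataclass
class ClassPerformance:
    """Sensitivity/specificity of a class model, with per-set counts."""

    sensitivity: float | None         # % of target test samples accepted
    specificity: float | None         # % of alien samples rejected (pooled)
    n_target: int = 0
    n_target_accepted: int = 0
    per_alien: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> (rejected, total)


def performance(
    model: DdSimcaModel,
    target_test: SpectraSet | np.ndarray | None,
    aliens: dict[str, SpectraSet] | None = None,
) -> ClassPerformance:
    """Evaluate a model on held-out target samples and alien sets."""
    sens = None
    n_target = n_acc = 0
    if target_test is not None:
        flags = classify_set(model, target_test)["accepted"].to_numpy()
        n_target = flags.size
        if n_target == 0:
            raise ValueError("empty target test set: sensitivity undefined")
        n_acc = int(flags.sum())
        sens = 100.0 * n_acc / n_target
    per_alien: dict[str, tuple[int, int]] = {}
    total = rejected = 0
    for name, alien in (aliens or {}).items():
        flags = classify_set(model, alien)["accepted"].to_numpy()
        per_alien[name] = (int((~flags).sum()), flags.size)
        rejected += int((~flags).sum())
        total += flags.size
    spec = 100.0 * rejected / total if total else None
    return ClassPerformance(
        sensitivity=sens,
        specificity=spec,
        n_target=n_target,
        n_target_accepted=n_acc,
        per_alien=per_alien,
    )


def acceptance_boundary(model: DdSimcaModel, n_points: int = 200) -> np.ndarray:
    """The acceptance-boundary polyline in (plot_x, plot_y) coordinates.

    Solves ``N_h h / h0 + N_v v / v0 = c_crit`` parametrically from the
    ``h = 0`` endpoint to the ``v = 0`` endpoint.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    c_h = np.linspace(0.0, model.c_crit, n_points)
    h = c_h * model.h0 / model.N_h
    v = (model.c_crit - c_h) * model.v0 / model.N_v
    return np.column_stack([np.log1p(h / model.h0), np.log1p(v / model.v0)])


@dataclass
class OptimizeResult:
    model: DdSimcaModel
    trace: pd.DataFrame               # columns A, alpha, sensitivity, specificity
    reached_full_sensitivity: bool


def optimize(
    train: SpectraSet | np.ndarray,
    target_test: SpectraSet | np.ndarray,
    aliens: dict[str, SpectraSet],
    A_grid=DEFAULT_A_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    preprocess: PreprocessConfig | None = None,
) -> OptimizeResult:
    """Two-stage sequential selection of (number of PCs, alpha).

    Acceptance regions are nested in alpha (larger alpha = more stringent),
    so sensitivity is maximal at the smallest alpha of the grid.  Stage 1
    picks the smallest A reaching 100% test sensitivity there; stage 2, at
    that A, keeps the alphas retaining 100% sensitivity and picks the one
    with maximal specificity, ties broken toward larger (more stringent)
    alpha.  If no grid point reaches full sensitivity, the best-sensitivity
    model is returned with ``reached_full_sensitivity=False``.
    """
    A_grid = sorted(set(int(a) for a in A_grid))
    alpha_grid = sorted(set(float(a) for a in alpha_grid))  # ascending
    if not A_grid or not alpha_grid:
        raise ValueError("A_grid and alpha_grid must be non-empty")

    rows = []
    models: dict[int, DdSimcaModel] = {}
    for A in A_grid:
        base = fit(train, A, alpha_grid[0], preprocess=preprocess)
        models[A] = base
        for alpha in alpha_grid:
            m = base.with_alpha(alpha)
            perf = performance(m, target_test, aliens)
            rows.append(
                {
                    "A": A,
                    "alpha": alpha,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                }
            )
    trace = pd.DataFrame(rows)

    alpha_min = alpha_grid[0]
    stage1 = trace[(trace["alpha"] == alpha_min) & (trace["sensitivity"] == 100.0)]
    if stage1.empty:
        # fall back: best sensitivity, ties toward smaller A then larger alpha
        best = trace.sort_values(
            ["sensitivity", "A", "alpha"], ascending=[False, True, False]
        ).iloc[0]
        model = models[int(best["A"])].with_alpha(float(best["alpha"]))
        return OptimizeResult(model=model, trace=trace, reached_full_sensitivity=False)
    A_star = int(stage1["A"].min())
    at_a = trace[(trace["A"] == A_star) & (trace["sensitivity"] == 100.0)]
    best = at_a.sort_values(["specificity", "alpha"], ascending=[False, False]).iloc[0]
    model = models[A_star].with_alpha(float(best["alpha"]))
    return OptimizeResult(model=model, trace=trace, reached_full_sensitivity=True)


# ----------------------------------------------------------- serialization
def model_to_dict(model: DdSimcaModel) -> dict:
    d = {
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "kept": model.kept.tolist(),
        "loadings": model.loadings.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "A": model.A,
        "alpha": model.alpha,
        "h0": model.h0,
        "v0": model.v0,
        "N_h": model.N_h,
        "N_v": model.N_v,
        "c_crit": model.c_crit,
        "n_variables": model.n_variables,
        "preprocess_state": None,
    }
    if model.preprocess_state is not None:
        d["preprocess_state"] = state_to_dict(model.preprocess_state)
    return d


def model_from_dict(d: dict) -> DdSimcaModel:
    state = d.get("preprocess_state")
    return DdSimcaModel(
        mean=np.asarray(d["mean"], float),
        sd=np.asarray(d["sd"], float),
        kept=np.asarray(d["kept"], int),
        loadings=np.asarray(d["loadings"], float),
        eigenvalues=np.asarray(d["eigenvalues"], float),
        A=int(d["A"]),
        alpha=float(d["alpha"]),
        h0=float(d["h0"]),
        v0=float(d["v0"]),
        N_h=int(d["N_h"]),
        N_v=int(d["N_v"]),
        c_crit=float(d["c_crit"]),
        n_variables=int(d["n_variables"]),
        preprocess_state=state_from_dict(state) if state else None,
    )


def save_model(model: DdSimcaModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path) -> DdSimcaModel:
    return model_from_dict(json.loads(Path(path).read_text()))
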