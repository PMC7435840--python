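"""Spectral preprocessing: Savitzky-Golay second derivative, multiplicative
scatter correction and restriction to the informative 1085-1601 nm window.

The default chain is SG (second-degree polynomial, second derivative, valid
interior only) -> MSC against the mean of the fitted set -> truncation.  The
fitted MSC reference and the final grid are recorded in a
:class:`PreprocessState` so test samples are always corrected against the
training reference rather than being silently re-fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

DEFAULT_RANGE_NM = (1085.0, 1601.0)


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings of the preprocessing chain.

    ``sg_window`` is the odd point count of the Savitzky-Golay filter (the
    polynomial degree and derivative order are both 2); ``range_nm`` the
    closed retained wavelength interval.  ``truncate_first`` switches to
    truncating before filtering instead of after.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 2
    range_nm: tuple[float, float] = DEFAULT_RANGE_NM
    msc_reference: str = "mean"
    truncate_first: bool = False

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if self.sg_polyorder < self.sg_deriv:
            raise ValueError("sg_polyorder must be >= sg_deriv")
        if self.range_nm[0] >= self.range_nm[1]:
            raise ValueError("range_nm must satisfy low < high")


@dataclass
class PreprocessState:
    """Fitted preprocessing artefacts reused on new samples."""

    config: PreprocessConfig
    msc_reference: np.ndarray  # on the post-SG grid of the fitting stage
    grid: np.ndarray           # final output grid


def savgol_derivative(spectra: SpectraSet, config: PreprocessConfig | None = None) -> SpectraSet:
    """Apply the SG least-squares smoothing/differentiation kernel.

    The derivative is taken per grid index (unit step); the output keeps only
    the valid interior, dropping ``(window - 1) / 2`` points per edge so no
    padded boundary values propagate into MSC.
    """
    config = config or PreprocessConfig()
    w = config.sg_window
    if w >= spectra.n_points:
        raise ValueError(f"sg_window {w} does not fit a grid of {spectra.n_points} points")
    filtered = savgol_filter(
        spectra.values, w, config.sg_polyorder, deriv=config.sg_deriv, delta=1.0, axis=1
    )
    half = w // 2
    return spectra.replace_values(spectra.wavelengths[half:-half], filtered[:, half:-half])


def msc(
    spectra: SpectraSet, reference: str | np.ndarray = "mean"
) -> tuple[SpectraSet, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed as ``x ~ a + b * ref`` by ordinary least
    squares and corrected to ``(x - a) / b``.  Returns the corrected set and
    the reference actually used (the mean of the input set by default), so
    callers can store it for correcting future samples.
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown MSC reference {reference!r}")
        ref = spectra.values.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (spectra.n_points,):
            raise ValueError("MSC reference length does not match the spectra")

    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-300:
        raise ValueError("degenerate (constant) MSC reference")
    x = spectra.values
    xm = x.mean(axis=1, keepdims=True)
    b = (x - xm) @ ref_c / denom
    tiny = np.abs(b) < 1e-12
    if np.any(tiny):
        bad = [spectra.sample_ids[i] for i in np.flatnonzero(tiny)]
        raise ValueError(f"MSC slope below 1e-12 for sample(s): {bad}")
    a = xm[:, 0] - b * ref.mean()
    corrected = (x - a[:, None]) / b[:, None]
    return spectra.replace_values(spectra.wavelengths.copy(), corrected), ref.copy()


def truncate_range(spectra: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep wavelengths in the closed interval [low, high]."""
    if low >= high:
        raise ValueError("low must be < high")
    mask = (spectra.wavelengths >= low) & (spectra.wavelengths <= high)
    if not mask.any():
        raise ValueError(f"no grid points inside [{low}, {high}] nm")
    return spectra.replace_values(spectra.wavelengths[mask], spectra.values[:, mask])


def fit_preprocess(
    spectra: SpectraSet, config: PreprocessConfig | None = None
) -> tuple[SpectraSet, PreprocessState]:
    """Run the full chain on a training set and record the fitted state."""
    config = config or PreprocessConfig()
    work = spectra
    if config.truncate_first:
        work = truncate_range(work, *config.range_nm)
    work = savgol_derivative(work, config)
    work, ref = msc(work, config.msc_reference)
    if not config.truncate_first:
        work = truncate_range(work, *config.range_nm)
    return work, PreprocessState(config=config, msc_reference=ref, grid=work.wavelengths.copy())


def apply_preprocess(spectra: SpectraSet, state: PreprocessState) -> SpectraSet:
    """Preprocess new samples with a previously fitted state (stored MSC ref)."""
    config = state.config
    work = spectra
    if config.truncate_first:
        work = truncate_range(work, *config.range_nm)
    work = savgol_derivative(work, config)
    work, _ = msc(work, state.msc_reference)
    if not config.truncate_first:
        work = truncate_range(work, *config.range_nm)
    if work.n_points != state.grid.size or not np.allclose(work.wavelengths, state.grid):
        raise ValueError("input grid incompatible with the fitted preprocessing state")
    return work


def preprocess_pipeline(
    spectra: SpectraSet,
    config: PreprocessConfig | None = None,
    state: PreprocessState | None = None,
) -> tuple[SpectraSet, PreprocessState]:
    """Fit on ``spectra`` (state=None) or apply an existing fitted state."""
    if state is None:
        return fit_preprocess(spectra, config)
    return apply_preprocess(spectra, state), state


def state_to_dict(state: PreprocessState) -> dict:
    cfg = state.config
    return {
        "config": {
            "sg_window": cfg.sg_window,
            "sg_polyorder": cfg.sg_polyorder,
            "sg_deriv": cfg.sg_deriv,
            "range_nm": list(cfg.range_nm),
            "msc_reference": "mean",
            "truncate_first": cfg.truncate_first,
        },
        "msc_reference": state.msc_reference.tolist(),
        "grid": state.grid.tolist(),
    }


def state_from_dict(d: dict) -> PreprocessState:
    cfg = d["config"]
    config = PreprocessConfig(
        sg_window=int(cfg["sg_window"]),
        sg_polyorder=int(cfg["sg_polyorder"]),
        sg_deriv=int(cfg["sg_deriv"]),
        range_nm=tuple(float(v) for v in cfg["range_nm"]),
        msc_reference=cfg.get("msc_reference", "mean"),
        truncate_first=bool(cfg.get("truncate_first", False)),
    )
    return PreprocessState(
        config=config,
        msc_reference=np.asarray(d["msc_reference"], dtype=float),
        grid=np.asarray(d["grid"], dtype=float),
    )
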