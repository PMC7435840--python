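"""End-to-end brand screening: batch-wise splits and per-brand DD-SIMCA.

A class model is only built for products with at least five collected
batches; its training set is the first three batches (splitting is by batch,
never by tablet), the remaining batches are the sensitivity test set, and
every other product — including the illicit-channel samples — forms the
specificity (alien) sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import ddsimca
from .preprocess import PreprocessConfig
from .spectra import SpectraSet

MIN_BATCHES_FOR_MODEL = 5
N_TRAINING_BATCHES = 3


def split_batches(
    spectra: SpectraSet, brand: str, channel: str = "licit", n_train: int = N_TRAINING_BATCHES
) -> tuple[SpectraSet, SpectraSet]:
    """Batch-wise train/test split of one product's spectra.

    The first ``n_train`` batch indices train the model; the remaining
    batches are held out.  Tablets of one batch never straddle the split.
    """
    product = spectra.select_product(brand, channel)
    batches = sorted(product.meta["batch"].unique())
    if len(batches) <= n_train:
        raise ValueError(
            f"{brand} ({channel}) has {len(batches)} batches; need more than "
            f"{n_train} for a batch-wise split"
        )
    train = product.select_batches(batches[:n_train])
    test = product.select_batches(batches[n_train:])
    return train, test


def eligible_targets(spectra: SpectraSet, min_batches: int = MIN_BATCHES_FOR_MODEL):
    """(brand, channel) pairs with enough batches for a class model (licit only)."""
    out = []
    for (brand, channel), subset in spectra.iter_products():
        if channel != "licit":
            continue
        if subset.meta["batch"].nunique() >= min_batches:
            out.append((brand, channel))
    return out


@dataclass
class BrandScreenResult:
    brand: str
    channel: str
    model: ddsimca.DdSimcaModel
    performance: ddsimca.ClassPerformance
    trace: pd.DataFrame
    reached_full_sensitivity: bool


def screen_brand(
    spectra: SpectraSet,
    brand: str,
    channel: str = "licit",
    preprocess: PreprocessConfig | None = None,
    A_grid=ddsimca.DEFAULT_A_GRID,
    alpha_grid=ddsimca.DEFAULT_ALPHA_GRID,
    min_batches: int = MIN_BATCHES_FOR_MODEL,
) -> BrandScreenResult:
    """Build, optimise and evaluate the one-class model of a single brand."""
    product = spectra.select_product(brand, channel)
    n_batches = product.meta["batch"].nunique()
    if n_batches < min_batches:
        raise ValueError(
            f"{brand} ({channel}) has only {n_batches} batches; class models are "
            f"built only for products with at least {min_batches} collected batches"
        )
    preprocess = preprocess or PreprocessConfig()
    train, target_test = split_batches(spectra, brand, channel)
    aliens = {
        f"{b} ({c})": subset
        for (b, c), subset in spectra.iter_products()
        if (b, c) != (brand, channel)
    }
    result = ddsimca.optimize(
        train, target_test, aliens, A_grid=A_grid, alpha_grid=alpha_grid, preprocess=preprocess
    )
    perf = ddsimca.performance(result.model, target_test, aliens)
    return BrandScreenResult(
        brand=brand,
        channel=channel,
        model=result.model,
        performance=perf,
        trace=result.trace,
        reached_full_sensitivity=result.reached_full_sensitivity,
    )


def screen_study(
    spectra: SpectraSet,
    preprocess: PreprocessConfig | None = None,
    A_grid=ddsimca.DEFAULT_A_GRID,
    alpha_grid=ddsimca.DEFAULT_ALPHA_GRID,
    min_batches: int = MIN_BATCHES_FOR_MODEL,
) -> dict[str, BrandScreenResult]:
    """Screen every eligible brand of a study; returns brand -> result."""
    results = {}
    for brand, channel in eligible_targets(spectra, min_batches):
        results[brand] = screen_brand(
            spectra, brand, channel, preprocess=preprocess,
            A_grid=A_grid, alpha_grid=alpha_grid, min_batches=min_batches,
        )
    return results


def performance_table(results: dict[str, BrandScreenResult]) -> pd.DataFrame:
    rows = []
    for brand, res in results.items():
        rows.append(
            {
                "brand": brand,
                "A": res.model.A,
                "alpha": res.model.alpha,
                "sensitivity": res.performance.sensitivity,
                "specificity": res.performance.specificity,
                "n_target_test": res.performance.n_target,
                "n_target_accepted": res.performance.n_target_accepted,
            }
        )
    return pd.DataFrame(rows)
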