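"""In-memory container and CSV I/O for sets of NIR tablet spectra.

A :class:`SpectraSet` bundles a strictly increasing wavelength grid (nm), an
``(n_samples, n_points)`` intensity matrix and a per-sample metadata table
(sample id, brand, sales channel, batch, tablet).  It is the unit that flows
through preprocessing, PCA and DD-SIMCA classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "brand", "channel", "batch", "tablet"]


@dataclass
class SpectraSet:
    """A wavelength grid, an intensity matrix and per-sample metadata.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_points,)
        Strictly increasing wavelength grid in nm.
    values : ndarray, shape (n_samples, n_points)
        One spectrum per row, pseudo-absorbance units.
    meta : DataFrame
        One row per spectrum with columns ``sample_id``, ``brand``,
        ``channel``, ``batch``, ``tablet``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelength grid must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"values have {self.values.shape[1]} points but the grid has "
                f"{self.wavelengths.size}"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata rows and spectra rows differ")
        self.meta = self.meta.reset_index(drop=True)

    # ------------------------------------------------------------------ basic
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavelengths.size

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.wavelengths.copy(), self.values.copy(), self.meta.copy())

    def replace_values(self, wavelengths: np.ndarray, values: np.ndarray) -> "SpectraSet":
        """Same samples, new grid/matrix (used by preprocessing stages)."""
        return SpectraSet(wavelengths, values, self.meta.copy())

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(
            self.wavelengths.copy(),
            self.values[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def select_product(self, brand: str, channel: str | None = None) -> "SpectraSet":
        mask = self.meta["brand"] == brand
        if channel is not None:
            mask &= self.meta["channel"] == channel
        if not mask.any():
            raise KeyError(f"no spectra for brand={brand!r} channel={channel!r}")
        return self.select(mask.to_numpy())

    def select_batches(self, batches) -> "SpectraSet":
        return self.select(self.meta["batch"].isin(list(batches)).to_numpy())

    def iter_products(self) -> Iterator[tuple[tuple[str, str], "SpectraSet"]]:
        """Yield ((brand, channel), subset) in first-appearance order."""
        seen: list[tuple[str, str]] = []
        for brand, channel in zip(self.meta["brand"], self.meta["channel"]):
            key = (brand, channel)
            if key not in seen:
                seen.append(key)
        for brand, channel in seen:
            yield (brand, channel), self.select(
                ((self.meta["brand"] == brand) & (self.meta["channel"] == channel)).to_numpy()
            )

    # --------------------------------------------------------------------- IO
    @classmethod
    def from_matrix(
        cls,
        values: np.ndarray,
        wavelengths: np.ndarray | None = None,
        sample_ids: list[str] | None = None,
    ) -> "SpectraSet":
        """Wrap a bare matrix with a unit grid and placeholder metadata."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if wavelengths is None:
            wavelengths = np.arange(values.shape[1], dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(values.shape[0])]
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "brand": "unknown",
                "channel": "unknown",
                "batch": 0,
                "tablet": np.arange(values.shape[0]),
            }
        )
        return cls(np.asarray(wavelengths, dtype=float), values, meta)

    def to_csv(self, spectra_path, meta_path) -> None:
        """Write the wide spectra table and the companion metadata table.

        The spectra CSV has a first column ``wavelength_nm`` and one column
        per spectrum named by its sample id.
        """
        columns = {"wavelength_nm": self.wavelengths}
        columns.update({sid: row for sid, row in zip(self.sample_ids, self.values)})
        pd.DataFrame(columns).to_csv(spectra_path, index=False)
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path, meta_path) -> "SpectraSet":
        wide = pd.read_csv(spectra_path)
        meta = pd.read_csv(meta_path)
        grid = wide["wavelength_nm"].to_numpy(dtype=float)
        ids = meta["sample_id"].astype(str).tolist()
        values = np.column_stack([wide[s].to_numpy(dtype=float) for s in ids]).T
        meta["sample_id"] = meta["sample_id"].astype(str)
        return cls(grid, values, meta)


def write_run_info(out_dir, seed: int | None, config: dict, command: str) -> Path:
    """Record the reproducibility sidecar (seed + config hash) for an output dir."""
    import hashlib
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    info = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    path = out_dir / "run_info.json"
    path.write_text(json.dumps(info, indent=2))
    return path
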