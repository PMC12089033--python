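"""Cross-layer summary statistics.

These are the figure-level quantities the simulator is judged on: the
progressive contraction of the rate range across layers, conservation of
the mean at each sampling step, regulation of the active-cell density at
field and file level, and the linearity of every layer mean in the input
mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .granular import FieldActivity, FileCode
from .pipeline import NetworkRun

__all__ = [
    "IncompleteRunError",
    "InsufficientDataError",
    "layer_values",
    "layer_summaries",
    "mean_conservation",
    "linearity_check",
    "density_regulation_table",
]

LAYER_ORDER = ["mossy", "pf", "stellate", "compartment", "soma", "nuclear"]


class IncompleteRunError(ValueError):
    """A layer required for a summary is missing from the run."""


class InsufficientDataError(ValueError):
    """Not enough runs (or variation) for a regression."""


def layer_values(run: NetworkRun, layer: str) -> np.ndarray:
    """The flat vector of unit values for one named layer of a run."""
    try:
        if layer == "mossy":
            return run.layer.all_rates()
        if layer == "pf":
            return np.concatenate([fc.pf_rates for fc in run.files])
        if layer == "stellate":
            return run.stellate.outputs
        if layer == "compartment":
            return run.pcs.compartments.ravel()
        if layer == "soma":
            return run.pcs.soma
        if layer == "nuclear":
            return run.nuclear.outputs
    except (AttributeError, TypeError) as exc:
        raise IncompleteRunError(f"run is missing layer {layer!r}") from exc
    raise IncompleteRunError(f"unknown layer {layer!r}")


def _expected_n(run: NetworkRun, layer: str) -> int | None:
    g = run.geom
    return {
        "stellate": g.stellate_total,
        "compartment": g.compartment_total,
        "soma": g.pcs_total,
        "nuclear": g.nuclear_cells,
    }.get(layer)


def layer_summaries(run: NetworkRun) -> pd.DataFrame:
    """One row per layer: n, mean, sd, min, max, range."""
    rows = []
    for layer in LAYER_ORDER:
        v = layer_values(run, layer)
        expected = _expected_n(run, layer)
        if expected is not None and len(v) != expected:
            raise IncompleteRunError(
                f"layer {layer!r} has {len(v)} values, expected {expected}"
            )
        rows.append(
            {
                "layer": layer,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "min": float(v.min()),
                "max": float(v.max()),
                "range": float(v.max() - v.min()),
            }
        )
    return pd.DataFrame(rows)


def _boot_se(values: np.ndarray, rng: np.random.Generator, n_boot: int = 50) -> float:
    means = np.array(
        [values[rng.integers(0, len(values), len(values))].mean() for _ in range(n_boot)]
    )
    return float(means.std(ddof=1))


def mean_conservation(
    run: NetworkRun, n_boot: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Mean conservation at each adjacent sampling step from pf onward.

    The standard error of each layer mean is estimated by ``n_boot``
    bootstrap resamples; the difference SE combines the two layers'
    (conservatively, as if independent).
    """
    rng = substream(seed, "bootstrap")
    chain = ["pf", "stellate", "compartment", "soma", "nuclear"]
    vals = {layer: layer_values(run, layer) for layer in chain}
    ses = {layer: _boot_se(vals[layer], rng, n_boot) for layer in chain}
    rows = []
    for up, down in zip(chain[:-1], chain[1:]):
        diff = float(vals[down].mean() - vals[up].mean())
        se = float(np.hypot(ses[up], ses[down]))
        rows.append(
            {
                "upstream": up,
                "downstream": down,
                "diff": diff,
                "se": se,
                "within_3se": abs(diff) <= 3 * se,
            }
        )
    return pd.DataFrame(rows)


def linearity_check(
    runs: list[NetworkRun], layers: tuple[str, ...] = ("pf", "stellate", "compartment", "soma", "nuclear")
) -> pd.DataFrame:
    """Least-squares fit of each layer's mean against the input (mossy) mean.

    Requires at least three runs differing by a uniform shift of the mossy
    rates; returns slope, intercept and R^2 per layer.
    """
    if len(runs) < 3:
        raise InsufficientDataError(f"need >= 3 runs, got {len(runs)}")
    x = np.array([layer_values(r, "mossy").mean() for r in runs])
    if np.ptp(x) == 0:
        raise InsufficientDataError("mossy means show no variation across runs")
    rows = []
    for layer in layers:
        y = np.array([layer_values(r, layer).mean() for r in runs])
        fit = stats.linregress(x, y)
        rows.append(
            {
                "layer": layer,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r2": float(fit.rvalue**2),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DensityTable:
    field_pct: np.ndarray
    file_pct: np.ndarray

    @property
    def sd_field(self) -> float:
        return float(self.field_pct.std(ddof=1))

    @property
    def sd_file(self) -> float:
        return float(self.file_pct.std(ddof=1))

    def to_frame(self) -> pd.DataFrame:
        n = max(len(self.field_pct), len(self.file_pct))
        return pd.DataFrame(
            {
                "field_pct": pd.Series(self.field_pct),
                "file_pct": pd.Series(self.file_pct),
            },
            index=range(n),
        )


def density_regulation_table(
    activities: list[list[FieldActivity]], files: list[FileCode]
) -> DensityTable:
    """Active-cell percentages per field and per file."""
    field_pct = np.array(
        [100.0 * a.fraction_active for row in activities for a in row]
    )
    file_pct = np.array([100.0 * fc.density for fc in files])
    return DensityTable(field_pct=field_pct, file_pct=file_pct)
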