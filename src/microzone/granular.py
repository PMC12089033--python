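"""Granular-layer recoding: Golgi inhibition, granule firing, file codes.

Per field, a small population of Golgi units each averages a random sample
of the field's mossy terminal rates; each glomerulus then averages a random
sample of Golgi rates, giving the inhibition a granule cell dendrite meets
at that glomerulus.  Inhibition is adjusted by a calibrated constant so
that a target fraction of granule cells fires (the sparse code, 0.5% by
default).  Each granule cell draws four dendritic (terminal rate,
glomerular inhibition) pairs; a dendrite wins when excitation exceeds
inhibition, the cell fires when at least ``min_wins`` dendrites win, and a
firing cell's rate is the mean of its dendritic excitation rates.

The calibrated constant is, by default, an *additive* offset on the
glomerular inhibition (in Hz).  An additive constant leaves the firing
fraction invariant under a uniform shift of all mossy rates, which is what
makes every downstream layer mean a linear, slope-one function of the
input mean.  A multiplicative mode (``mode="scale"``) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .geometry import NetworkGeometry
from .mossy import FieldRates, InputLayer

__all__ = [
    "GranularError",
    "CalibrationError",
    "GolgiParams",
    "FiringRule",
    "InhibitionField",
    "FieldActivity",
    "FileCode",
    "CalibrationResult",
    "compute_field_inhibition",
    "evaluate_granule_firing",
    "calibrate_inhibition_scale",
    "assemble_file_codes",
    "run_granular_layer",
]


class GranularError(ValueError):
    """Invalid granular-layer input or parameter."""


class CalibrationError(RuntimeError):
    """The target active fraction is unreachable within the search bracket."""


@dataclass(frozen=True)
class GolgiParams:
    """Sizes of the two-stage mean-of-means inhibition chain."""

    n_golgi: int = 10
    golgi_sample: int = 4
    glomerulus_sample: int = 4

    def validate(self) -> None:
        if min(self.n_golgi, self.golgi_sample, self.glomerulus_sample) < 1:
            raise GranularError("Golgi chain sizes must be >= 1")


@dataclass(frozen=True)
class FiringRule:
    """Granule cell dendritic competition rule."""

    n_dendrites: int = 4
    min_wins: int = 3
    rate_mode: str = "all"  # "all": mean of all dendritic rates; "winners": winners only

    def validate(self) -> None:
        if self.n_dendrites < 1:
            raise GranularError("n_dendrites must be >= 1")
        if not 1 <= self.min_wins <= self.n_dendrites:
            raise GranularError(
                f"min_wins must lie in 1..{self.n_dendrites}, got {self.min_wins}"
            )
        if self.rate_mode not in ("all", "winners"):
            raise GranularError(f"unknown rate_mode: {self.rate_mode!r}")


@dataclass
class InhibitionField:
    rank_index: int
    field_index: int
    values: np.ndarray
    scale: float
    offset: float


@dataclass
class FieldActivity:
    rank_index: int
    field_index: int
    n_granule: int
    active_ids: np.ndarray
    active_rates: np.ndarray

    @property
    def fraction_active(self) -> float:
        return len(self.active_ids) / self.n_granule


@dataclass
class FileCode:
    """Active parallel-fibre rates converging on one microzone sector."""

    file_index: int
    pf_rates: np.ndarray
    n_granule_total: int

    @property
    def density(self) -> float:
        return len(self.pf_rates) / self.n_granule_total


@dataclass
class CalibrationResult:
    scale: float
    offset: float
    achieved_fraction: float
    iterations: int
    target: float
    mode: str
    converged: bool = True

    @property
    def constant(self) -> float:
        return self.offset if self.mode == "offset" else self.scale


def compute_field_inhibition(
    field: FieldRates,
    golgi: GolgiParams,
    scale: float,
    rng: np.random.Generator,
    n_glomeruli: int = 700,
    offset: float = 0.0,
) -> InhibitionField:
    """Glomerular inhibition levels for one field.

    Each Golgi unit's rate is the mean of ``golgi_sample`` randomly chosen
    terminal rates; each glomerulus receives
    ``scale * mean(glomerulus_sample Golgi rates) + offset``, floored at 0.
    """
    if field.n_terminals == 0:
        raise GranularError(
            f"field ({field.rank_index}, {field.field_index}) has no terminals"
        )
    if scale < 0:
        raise GranularError(f"scale must be >= 0, got {scale}")
    golgi.validate()
    base = _glomerular_base(field.rates, golgi, n_glomeruli, rng)
    values = np.clip(scale * base + offset, 0.0, None)
    return InhibitionField(field.rank_index, field.field_index, values, scale, offset)


def _glomerular_base(
    rates: np.ndarray, golgi: GolgiParams, n_glomeruli: int, rng: np.random.Generator
) -> np.ndarray:
    """Unscaled mean-of-means inhibition base, one value per glomerulus."""
    golgi_rates = rates[
        rng.integers(0, rates.size, (golgi.n_golgi, golgi.golgi_sample))
    ].mean(axis=1)
    return golgi_rates[
        rng.integers(0, golgi.n_golgi, (n_glomeruli, golgi.glomerulus_sample))
    ].mean(axis=1)


def evaluate_granule_firing(
    field: FieldRates,
    inh: InhibitionField,
    rule: FiringRule,
    n_granule: int,
    rng: np.random.Generator,
) -> FieldActivity:
    """Which granule cells of one field fire, and at what rate."""
    rule.validate()
    if field.n_terminals == 0:
        raise GranularError(
            f"field ({field.rank_index}, {field.field_index}) has no terminals"
        )
    exc = field.rates[rng.integers(0, field.n_terminals, (n_granule, rule.n_dendrites))]
    inh_draw = inh.values[rng.integers(0, inh.values.size, (n_granule, rule.n_dendrites))]
    win = exc > inh_draw
    fires = win.sum(axis=1) >= rule.min_wins
    if rule.rate_mode == "all":
        rates = exc[fires].mean(axis=1)
    else:
        w = win[fires]
        rates = (exc[fires] * w).sum(axis=1) / w.sum(axis=1)
    return FieldActivity(
        rank_index=field.rank_index,
        field_index=field.field_index,
        n_granule=n_granule,
        active_ids=np.flatnonzero(fires),
        active_rates=rates,
    )


def _field_fraction(
    field: FieldRates,
    scale: float,
    offset: float,
    golgi: GolgiParams,
    rule: FiringRule,
    n_granule: int,
    n_glomeruli: int,
    seed: int,
) -> float:
    """Active fraction of one field under common random numbers.

    The substream is keyed by the field alone, so repeated calls with
    different constants reuse identical draws: the fraction is then a
    deterministic, monotone non-increasing function of ``scale`` and
    ``offset``, which bisection exploits.
    """
    rng = substream(seed, "calibrate", field.rank_index, field.field_index)
    base = _glomerular_base(field.rates, golgi, n_glomeruli, rng)
    inh = InhibitionField(
        field.rank_index,
        field.field_index,
        np.clip(scale * base + offset, 0.0, None),
        scale,
        offset,
    )
    return evaluate_granule_firing(field, inh, rule, n_granule, rng).fraction_active


def calibrate_inhibition_scale(
    layer: InputLayer,
    target: float,
    tol: float = 0.1,
    seed: int = 0,
    golgi: GolgiParams | None = None,
    rule: FiringRule | None = None,
    mode: str = "offset",
    scale: float = 1.0,
    bounds: tuple[float, float] | None = None,
    subsample_fraction: float = 0.25,
    calibration_granule: int = 2000,
    max_iter: int = 60,
) -> CalibrationResult:
    """Bisect the inhibition constant to reach a target active fraction.

    ``mode="offset"`` (default) bisects the additive constant with the
    multiplicative ``scale`` held fixed; ``mode="scale"`` bisects the
    multiplier with offset 0.  The mean active fraction is measured over a
    random subsample of fields with ``calibration_granule`` granule cells
    per field, under common random numbers so the objective is a
    deterministic monotone function of the constant.
    """
    if not 0.0 < target < 1.0:
        raise GranularError(f"target fraction must lie in (0, 1), got {target}")
    if mode not in ("offset", "scale"):
        raise GranularError(f"unknown calibration mode: {mode!r}")
    golgi = golgi or GolgiParams()
    rule = rule or FiringRule()
    geom = layer.geom
    n_granule = min(calibration_granule, geom.granule_per_field)
    n_glom = geom.glomeruli_per_field

    all_fields = list(layer.iter_fields())
    n_sub = max(20, int(round(subsample_fraction * len(all_fields))))
    n_sub = min(n_sub, len(all_fields))
    pick = substream(seed, "calibrate", "fields").choice(
        len(all_fields), size=n_sub, replace=False
    )
    sample_fields = [all_fields[i] for i in np.sort(pick)]

    rate_max = max(float(f.rates.max()) for f in sample_fields)
    if bounds is None:
        bounds = (0.0, 4.0) if mode == "scale" else (-2.0 * rate_max, 2.0 * rate_max)
    lo, hi = bounds

    def fraction(c: float) -> float:
        s, o = (c, 0.0) if mode == "scale" else (scale, c)
        return float(
            np.mean(
                [
                    _field_fraction(f, s, o, golgi, rule, n_granule, n_glom, seed)
                    for f in sample_fields
                ]
            )
        )

    f_lo = fraction(lo)
    if f_lo < target:
        warnings.warn(
            f"target fraction {target} is above the maximum reachable "
            f"({f_lo:.4g}) at the lower bound {lo}; returning the boundary",
            UserWarning,
            stacklevel=2,
        )
        s, o = (lo, 0.0) if mode == "scale" else (scale, lo)
        return CalibrationResult(s, o, f_lo, 1, target, mode, converged=False)
    f_hi = fraction(hi)
    if f_hi > target:
        raise CalibrationError(
            f"target {target} unreachable: fraction at bracket "
            f"[{lo}, {hi}] is [{f_lo:.4g}, {f_hi:.4g}]"
        )

    achieved, mid, iterations = f_lo, lo, 0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        achieved = fraction(mid)
        if abs(achieved - target) <= tol * target:
            break
        if achieved > target:
            lo = mid
        else:
            hi = mid
    converged = abs(achieved - target) <= tol * target
    if not converged:
        warnings.warn(
            f"calibration stopped after {iterations} iterations at fraction "
            f"{achieved:.4g} (target {target})",
            UserWarning,
            stacklevel=2,
        )
    s, o = (mid, 0.0) if mode == "scale" else (scale, mid)
    return CalibrationResult(s, o, achieved, iterations, target, mode, converged)


def run_granular_layer(
    layer: InputLayer,
    scale: float,
    offset: float,
    seed: int = 0,
    golgi: GolgiParams | None = None,
    rule: FiringRule | None = None,
) -> list[list[FieldActivity]]:
    """Evaluate inhibition and granule firing for every field of the grid."""
    golgi = golgi or GolgiParams()
    rule = rule or FiringRule()
    geom = layer.geom
    activities: list[list[FieldActivity]] = []
    for r, row in enumerate(layer.fields):
        acts = []
        for f, fr in enumerate(row):
            rng = substream(seed, "granular", r, f)
            inh = compute_field_inhibition(
                fr, golgi, scale, rng, n_glomeruli=geom.glomeruli_per_field, offset=offset
            )
            acts.append(
                evaluate_granule_firing(fr, inh, rule, geom.granule_per_field, rng)
            )
        activities.append(acts)
    return activities


def assemble_file_codes(
    activities: list[list[FieldActivity]], geom: NetworkGeometry
) -> list[FileCode]:
    """Pool each file's 41 fields into one parallel-fibre code."""
    if len(activities) != geom.n_ranks or any(
        len(row) != geom.fields_per_rank for row in activities
    ):
        raise GranularError(
            "incomplete activity grid: expected "
            f"{geom.n_ranks} x {geom.fields_per_rank}"
        )
    codes = []
    n_total = geom.n_ranks * geom.granule_per_field
    for j in range(geom.fields_per_rank):
        rates = np.concatenate([activities[r][j].active_rates for r in range(geom.n_ranks)])
        codes.append(FileCode(file_index=j, pf_rates=rates, n_granule_total=n_total))
    return codes
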