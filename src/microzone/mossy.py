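"""Mossy fibre input synthesis and distribution to fields.

Each rank of the input layer receives firing rates drawn independently from
a configurable distribution (uniform, normal, discontinuous, or a
sinusoidal rank-mean drive used by the swimming experiment).  Terminal
*branching* (a fibre ends in several spaced-out terminal clusters) and
terminal *clustering* (each cluster holds several terminals, intermingled
with terminals of other fibres) are emulated so that the rates received by
each field behave like an independent random sample, with replacement, of
the rates received by the whole rank — the anatomical replacement
facsimile that underpins every downstream sampling stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .geometry import GeometryError, NetworkGeometry

__all__ = [
    "InputSpecError",
    "CalibrationWarning",
    "SineDriveSpec",
    "RankInputSpec",
    "BranchingParams",
    "FieldRates",
    "InputLayer",
    "draw_rank_rates",
    "distribute_to_fields",
    "build_input_layer",
    "export_field_rates",
]


class InputSpecError(ValueError):
    """An input-rate specification is invalid."""


class CalibrationWarning(UserWarning):
    """Branching parameters miss the per-field terminal target."""


@dataclass(frozen=True)
class SineDriveSpec:
    """Sinusoidal rank-mean drive for the locomotor (swimming) experiment.

    The row of ranks spans ``wavelength_fraction`` of one body wavelength:
    rank ``r`` of ``n`` receives rates drawn from a narrow normal
    distribution whose mean is
    ``baseline + amplitude * sin(2*pi*(r/n)*wavelength_fraction + phase)``.
    ``rank_sd`` is the within-rank spread (Hz).
    """

    wavelength_fraction: float = 1.0
    phase_deg: float = 0.0
    amplitude: float = 100.0
    baseline: float = 125.0
    rank_sd: float = 12.5

    def validate(self) -> None:
        if self.wavelength_fraction <= 0:
            raise InputSpecError("wavelength_fraction must be positive")
        if self.rank_sd < 0:
            raise InputSpecError("rank_sd must be non-negative")
        if self.baseline - self.amplitude < 0:
            raise InputSpecError(
                "baseline - amplitude must be >= 0 so rates stay non-negative"
            )

    def rank_mean(self, rank_index: int, n_ranks: int) -> float:
        theta = (
            2.0 * math.pi * (rank_index / n_ranks) * self.wavelength_fraction
            + math.radians(self.phase_deg)
        )
        return self.baseline + self.amplitude * math.sin(theta)

    def with_phase(self, phase_deg: float) -> "SineDriveSpec":
        return dataclasses.replace(self, phase_deg=phase_deg)


@dataclass(frozen=True)
class RankInputSpec:
    """Distribution of mossy fibre firing rates received by one rank."""

    kind: str = "uniform"
    lo: float = 0.0
    hi: float = 250.0
    mean: float = 125.0
    sd: float = 40.0
    bands: tuple[tuple[float, float], ...] | None = None
    sine: SineDriveSpec | None = None

    @classmethod
    def uniform(cls, lo: float = 0.0, hi: float = 250.0) -> "RankInputSpec":
        return cls(kind="uniform", lo=lo, hi=hi)

    @classmethod
    def normal(cls, mean: float = 125.0, sd: float = 40.0) -> "RankInputSpec":
        return cls(kind="normal", mean=mean, sd=sd)

    @classmethod
    def discontinuous(
        cls, bands: Sequence[tuple[float, float]] = ((50.0, 110.0), (180.0, 300.0))
    ) -> "RankInputSpec":
        return cls(kind="discontinuous", bands=tuple(tuple(b) for b in bands))

    @classmethod
    def sine_driven(cls, sine: SineDriveSpec) -> "RankInputSpec":
        return cls(kind="sine_driven", sine=sine)

    def validate(self) -> None:
        if self.kind == "uniform":
            if not (0 <= self.lo < self.hi):
                raise InputSpecError(f"uniform bounds invalid: ({self.lo}, {self.hi})")
        elif self.kind == "normal":
            if self.sd < 0 or self.mean < 0:
                raise InputSpecError("normal spec needs mean >= 0 and sd >= 0")
        elif self.kind == "discontinuous":
            if not self.bands:
                raise InputSpecError("discontinuous spec needs at least one band")
            prev_hi = -math.inf
            for lo, hi in self.bands:
                if not (0 <= lo < hi):
                    raise InputSpecError(f"band invalid: ({lo}, {hi})")
                if lo < prev_hi:
                    raise InputSpecError("bands must be disjoint and ordered")
                prev_hi = hi
        elif self.kind == "sine_driven":
            if self.sine is None:
                raise InputSpecError("sine_driven spec needs a SineDriveSpec")
            self.sine.validate()
        else:
            raise InputSpecError(f"unknown input kind: {self.kind!r}")


def draw_rank_rates(
    spec: RankInputSpec,
    n_mossy: int,
    rng: np.random.Generator,
    rank_index: int = 0,
    n_ranks: int = 1,
) -> np.ndarray:
    """Draw ``n_mossy`` i.i.d. firing rates for one rank, truncated at zero."""
    if n_mossy <= 0:
        raise InputSpecError(f"n_mossy must be positive, got {n_mossy}")
    spec.validate()
    if spec.kind == "uniform":
        rates = rng.uniform(spec.lo, spec.hi, n_mossy)
    elif spec.kind == "normal":
        rates = rng.normal(spec.mean, spec.sd, n_mossy)
    elif spec.kind == "discontinuous":
        bands = np.asarray(spec.bands, dtype=float)
        widths = bands[:, 1] - bands[:, 0]
        which = rng.choice(len(bands), size=n_mossy, p=widths / widths.sum())
        rates = rng.uniform(bands[which, 0], bands[which, 1])
    else:  # sine_driven
        mean = spec.sine.rank_mean(rank_index, n_ranks)
        rates = rng.normal(mean, spec.sine.rank_sd, n_mossy)
    return np.clip(rates, 0.0, None)


@dataclass(frozen=True)
class BranchingParams:
    """Terminal branching/clustering model.

    A fibre terminates in ``clusters_min``..``clusters_max`` clusters whose
    centres are placed along the rank with at least
    ``min_cluster_separation_fields`` field-widths between them (edge-to-edge
    cluster separation of >= 200 um plus the ~200 um cluster extent).  Each
    cluster holds ``terminals_min``..``terminals_max`` terminals, split
    binomially between the two fields its footprint straddles.  No fibre may
    contribute more than ``max_share_per_fibre`` of a field's terminal
    target; excess terminals of a straddling cluster are pushed to the
    cluster's other field.
    """

    clusters_min: int = 2
    clusters_max: int = 8
    terminals_min: int = 4
    terminals_max: int = 12
    min_cluster_separation_fields: int = 2
    max_share_per_fibre: float = 0.01

    def validate(self) -> None:
        if not (1 <= self.clusters_min <= self.clusters_max):
            raise InputSpecError("cluster count bounds invalid")
        if not (1 <= self.terminals_min <= self.terminals_max):
            raise InputSpecError("terminal count bounds invalid")
        if self.min_cluster_separation_fields < 1:
            raise InputSpecError("min_cluster_separation_fields must be >= 1")
        if not 0 < self.max_share_per_fibre <= 1:
            raise InputSpecError("max_share_per_fibre must lie in (0, 1]")


@dataclass
class FieldRates:
    """Terminal-level firing rates received by one field."""

    rank_index: int
    field_index: int
    rates: np.ndarray
    source_ids: np.ndarray

    @property
    def n_terminals(self) -> int:
        return len(self.rates)

    def max_source_share(self) -> float:
        """Largest share of the field's terminals contributed by one fibre."""
        if self.n_terminals == 0:
            return 0.0
        _, counts = np.unique(self.source_ids, return_counts=True)
        return counts.max() / self.n_terminals


def _cluster_positions(
    k_per_fibre: np.ndarray,
    n_fields: int,
    sep: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster centres per fibre, pairwise separated by >= ``sep`` fields.

    Centres live on a continuous axis in [-1, n_fields - 1]; a cluster with
    centre c occupies [c, c + 1) in field widths, so parts falling outside
    the rank strip are later discarded.  Returns (fibre_index, centre).
    """
    total = int(k_per_fibre.sum())
    fibre_of_cluster = np.repeat(np.arange(len(k_per_fibre)), k_per_fibre)
    centres = np.empty(total)
    starts = np.cumsum(k_per_fibre) - k_per_fibre
    pos_in_fibre = np.arange(total) - np.repeat(starts, k_per_fibre)
    # vectorise by cluster-count group: sorted uniforms plus fixed offsets
    for kv in np.unique(k_per_fibre):
        span = n_fields - sep * (kv - 1)
        if span <= 0:
            raise GeometryError(
                f"cannot place {kv} clusters separated by {sep} fields in a "
                f"rank of {n_fields} fields"
            )
        rows = np.where(k_per_fibre == kv)[0]
        u = np.sort(rng.uniform(0.0, span, size=(len(rows), kv)), axis=1)
        pos = u + sep * np.arange(kv) - 1.0
        mask = np.isin(fibre_of_cluster, rows)
        centres[mask] = pos[np.searchsorted(rows, fibre_of_cluster[mask]), pos_in_fibre[mask]]
    return fibre_of_cluster, centres


def distribute_to_fields(
    rank_rates: np.ndarray,
    geom: NetworkGeometry,
    params: BranchingParams | None,
    rng: np.random.Generator,
    rank_index: int = 0,
    source_offset: int = 0,
) -> list[FieldRates]:
    """Distribute one rank's mossy fibre rates to its fields.

    Each fibre carries a single rate (all its terminals are copies of that
    signal).  Returns one :class:`FieldRates` per field of the rank.
    """
    rank_rates = np.asarray(rank_rates, dtype=float)
    if rank_rates.size == 0:
        raise InputSpecError("rank_rates must be non-empty")
    params = params or BranchingParams()
    params.validate()
    n_fields = geom.fields_per_rank
    sep = params.min_cluster_separation_fields

    k = rng.integers(params.clusters_min, params.clusters_max + 1, rank_rates.size)
    fibre_of_cluster, centres = _cluster_positions(k, n_fields, sep, rng)
    t = rng.integers(
        params.terminals_min, params.terminals_max + 1, centres.size
    )

    left_field = np.floor(centres).astype(int)
    frac_left = left_field + 1 - centres
    n_left = rng.binomial(t, frac_left)
    n_right = t - n_left

    # single-fibre share cap: a cluster straddles two fields, so pushing the
    # excess to the other side keeps both parts within the cap when
    # terminals_max <= 2 * cap
    cap = max(1, int(math.floor(params.max_share_per_fibre * geom.terminals_per_field_target)))
    if params.terminals_max > 2 * cap:
        warnings.warn(
            f"terminals_max={params.terminals_max} exceeds twice the per-fibre "
            f"cap ({cap}); single-fibre share may exceed {params.max_share_per_fibre:.1%}",
            CalibrationWarning,
            stacklevel=2,
        )
        cap = int(math.ceil(params.terminals_max / 2))
    n_left = np.clip(n_left, np.maximum(0, t - cap), cap)
    n_right = t - n_left

    fields = np.concatenate([left_field, left_field + 1])
    counts = np.concatenate([n_left, n_right])
    fibres = np.concatenate([fibre_of_cluster, fibre_of_cluster])
    keep = (fields >= 0) & (fields < n_fields) & (counts > 0)
    fields, counts, fibres = fields[keep], counts[keep], fibres[keep]

    term_field = np.repeat(fields, counts)
    term_fibre = np.repeat(fibres, counts)
    order = np.argsort(term_field, kind="stable")
    term_field, term_fibre = term_field[order], term_fibre[order]
    bounds = np.searchsorted(term_field, np.arange(n_fields + 1))

    out: list[FieldRates] = []
    for f in range(n_fields):
        sl = slice(bounds[f], bounds[f + 1])
        src = term_fibre[sl]
        out.append(
            FieldRates(
                rank_index=rank_index,
                field_index=f,
                rates=rank_rates[src],
                source_ids=src + source_offset,
            )
        )

    mean_terminals = np.mean([fr.n_terminals for fr in out])
    target = geom.terminals_per_field_target
    if not 0.5 * target <= mean_terminals <= 1.5 * target:
        warnings.warn(
            f"mean terminals per field {mean_terminals:.0f} misses the target "
            f"~{target}; adjust mossy fibre count or branching parameters",
            CalibrationWarning,
            stacklevel=2,
        )
    return out


@dataclass
class InputLayer:
    """The full grid of per-field mossy terminal rates (ranks x files)."""

    geom: NetworkGeometry
    specs: tuple[RankInputSpec, ...]
    seed: int
    fields: list[list[FieldRates]] = dfield(repr=False, default_factory=list)
    rank_rates: list[np.ndarray] = dfield(repr=False, default_factory=list)

    def field(self, rank: int, file: int) -> FieldRates:
        return self.fields[rank][file]

    def iter_fields(self):
        for row in self.fields:
            yield from row

    def file_fields(self, file_index: int) -> list[FieldRates]:
        return [row[file_index] for row in self.fields]

    def all_rates(self) -> np.ndarray:
        return np.concatenate([fr.rates for fr in self.iter_fields()])

    def shifted(self, delta: float) -> "InputLayer":
        """A copy with every terminal (and rank) rate shifted by ``delta``.

        Used for linearity checks: the selection draws downstream are
        rate-independent, so under a common seed every layer mean shifts by
        exactly ``delta``.
        """
        out = InputLayer(geom=self.geom, specs=self.specs, seed=self.seed)
        out.rank_rates = [r + delta for r in self.rank_rates]
        out.fields = [
            [
                FieldRates(fr.rank_index, fr.field_index, fr.rates + delta, fr.source_ids)
                for fr in row
            ]
            for row in self.fields
        ]
        return out


def build_input_layer(
    specs: Sequence[RankInputSpec],
    geom: NetworkGeometry,
    branching: BranchingParams | None = None,
    seed: int = 0,
) -> InputLayer:
    """Build the full input grid, one independent RNG substream per rank."""
    if len(specs) != geom.n_ranks:
        raise GeometryError(
            f"need one input spec per rank: got {len(specs)} specs for "
            f"{geom.n_ranks} ranks"
        )
    layer = InputLayer(geom=geom, specs=tuple(specs), seed=seed)
    n_mossy = geom.mossy_per_rank
    for r, spec in enumerate(specs):
        rng = substream(seed, "mossy", r)
        rates = draw_rank_rates(spec, n_mossy, rng, rank_index=r, n_ranks=geom.n_ranks)
        layer.rank_rates.append(rates)
        layer.fields.append(
            distribute_to_fields(
                rates, geom, branching, rng, rank_index=r, source_offset=r * n_mossy
            )
        )
    return layer


def export_field_rates(layer: InputLayer, csv_path: str | Path) -> Path:
    """Write the grid to tidy CSV plus a JSON sidecar recording seed + specs."""
    csv_path = Path(csv_path)
    frames = []
    for fr in layer.iter_fields():
        frames.append(
            pd.DataFrame(
                {
                    "rank": fr.rank_index,
                    "field": fr.field_index,
                    "terminal": np.arange(fr.n_terminals),
                    "source_id": fr.source_ids,
                    "rate_hz": fr.rates,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "seed": layer.seed,
        "specs": [dataclasses.asdict(s) for s in layer.specs],
    }
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    return csv_path
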