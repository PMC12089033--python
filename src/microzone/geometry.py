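"""Network geometry: anatomical counts, dimensions and derived arithmetic.

The simulated network is a stack of three layers.  The input layer (a region
of the granular layer) is divided into ``n_ranks`` sagittal strips (ranks),
each a row of ``fields_per_rank`` fields of roughly 200 x 150 um.  A
mediolateral row of fields crossing all ranks is a *file*; the parallel
fibres of a file converge on one *sector* of the middle layer (the
microzone), so there is one sector per file.  Each sector holds 4 Purkinje
cells and 80 stellate cells (five depth layers of 16).  The output layer is
a nuclear group of ~50 cells.

All derived counts are pure functions of the configuration, so a validated
geometry can be serialised and re-validated with identical results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "GeometryError",
    "NetworkGeometry",
    "pf_through_stellate_territory",
    "active_pf_count",
    "validate_geometry",
]


class GeometryError(ValueError):
    """A geometry parameter or invariant is violated."""


def pf_through_stellate_territory(a: int, b: float, c: float, t: float) -> int:
    """Number of parallel fibres passing through a stellate territory.

    Parallel fibres are assumed uniformly distributed in the sagittal plane,
    so the count through a ``t x t`` um territory is the count ``a`` through
    a reference plane of ``b x c`` um, scaled by the area ratio:
    ``a / ((b * c) / t**2)``, rounded to the nearest integer.

    With the default anatomy (350 000 fibres through a 200 x 300 um Purkinje
    cell plane, 120 um inner stellate territory) this gives ~84 000.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("t", t)):
        if v <= 0:
            raise GeometryError(f"{name} must be positive, got {v}")
    return int(round(a / ((b * c) / t**2)))


def active_pf_count(passing: int, active_fraction: float) -> int:
    """Number of active fibres among ``passing``, at the given active fraction."""
    if passing <= 0:
        raise GeometryError(f"passing must be positive, got {passing}")
    if not 0.0 <= active_fraction <= 1.0:
        raise GeometryError(
            f"active_fraction must lie in [0, 1], got {active_fraction}"
        )
    return int(round(passing * active_fraction))


@dataclass(frozen=True)
class NetworkGeometry:
    """Anatomical constants of one microzone network.

    Lengths are in micrometres, counts are cells or structures.  Defaults
    are the mid-range estimates used throughout: a 41-rank input layer of
    100 fields per rank, ~80 000 mossy fibres, 9000 granule cells and 700
    glomeruli per field, 80 stellate and 4 Purkinje cells per sector, and a
    50-cell nuclear group sampling 30-50 Purkinje cells each.
    """

    n_ranks: int = 41
    fields_per_rank: int = 100
    field_sagittal_um: float = 200.0
    field_mediolateral_um: float = 150.0
    glomeruli_per_field: int = 700
    granule_per_field: int = 9000
    mossy_fibres_total: int = 80_000
    terminals_per_field_target: int = 700
    pcs_per_sector: int = 4
    stellate_per_sector: int = 80
    stellate_per_flank: int = 16
    neighbour_stellate_max: int = 8
    compartments_per_pc: int = 16
    compartment_sample_size: int = 6
    nuclear_cells: int = 50
    nuclear_sample_min: int = 30
    nuclear_sample_max: int = 50
    pf_through_pc: int = 350_000
    pc_territory_sagittal_um: float = 200.0
    pc_territory_depth_um: float = 300.0
    stellate_inner_territory_um: float = 120.0
    pf_contacting_stellate: int = 1000
    active_fraction_target: float = 0.005

    # ------------------------------------------------------------------ #
    # derived counts                                                     #
    # ------------------------------------------------------------------ #

    @property
    def n_fields(self) -> int:
        return self.n_ranks * self.fields_per_rank

    @property
    def n_sectors(self) -> int:
        # one sector per file, one file per mediolateral row of fields
        return self.fields_per_rank

    @property
    def pcs_total(self) -> int:
        return self.pcs_per_sector * self.n_sectors

    @property
    def stellate_total(self) -> int:
        return self.stellate_per_sector * self.n_sectors

    @property
    def compartment_total(self) -> int:
        return self.pcs_total * self.compartments_per_pc

    @property
    def stellate_depth_layers(self) -> int:
        return self.stellate_per_sector // self.stellate_per_flank

    @property
    def mossy_per_rank(self) -> int:
        return int(round(self.mossy_fibres_total / self.n_ranks))

    @property
    def pf_through_stellate(self) -> int:
        return pf_through_stellate_territory(
            self.pf_through_pc,
            self.pc_territory_sagittal_um,
            self.pc_territory_depth_um,
            self.stellate_inner_territory_um,
        )

    @property
    def contact_probability(self) -> float:
        """Exact probability that an active parallel fibre contacts a stellate cell."""
        return self.pf_contacting_stellate / self.pf_through_stellate

    @property
    def active_pf_through_stellate(self) -> int:
        return active_pf_count(self.pf_through_stellate, self.active_fraction_target)

    # ------------------------------------------------------------------ #
    # validation and (de)serialisation                                   #
    # ------------------------------------------------------------------ #

    def validate(self) -> dict[str, int]:
        """Check every invariant; return the derived-count report.

        Raises :class:`GeometryError` naming the failing relation.
        """
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not f.name.startswith("active"):
                if v <= 0:
                    raise GeometryError(f"{f.name} must be strictly positive, got {v}")
        if not 0.0 < self.active_fraction_target < 1.0:
            raise GeometryError(
                "active_fraction_target must lie in (0, 1), got "
                f"{self.active_fraction_target}"
            )
        if self.stellate_per_sector != self.stellate_per_flank * 5:
            raise GeometryError(
                "stellate_per_sector != stellate_per_flank * 5 "
                f"({self.stellate_per_sector} != {self.stellate_per_flank} * 5); "
                "five depth layers of stellate cells are required"
            )
        if not (self.nuclear_sample_min <= self.nuclear_sample_max <= self.pcs_total):
            raise GeometryError(
                "nuclear_sample_min <= nuclear_sample_max <= pcs_total violated: "
                f"{self.nuclear_sample_min} <= {self.nuclear_sample_max} <= "
                f"{self.pcs_total}"
            )
        if self.compartment_sample_size > self.stellate_per_flank:
            raise GeometryError(
                "compartment_sample_size exceeds stellate_per_flank: "
                f"{self.compartment_sample_size} > {self.stellate_per_flank}"
            )
        return {
            "n_fields": self.n_fields,
            "n_sectors": self.n_sectors,
            "stellate_total": self.stellate_total,
            "pcs_total": self.pcs_total,
            "compartment_total": self.compartment_total,
        }

    def scaled(self, factor: float) -> "NetworkGeometry":
        """A geometry with per-field cell counts scaled by ``factor``.

        Scales granule cells, glomeruli, mossy fibres and the terminal
        target together, leaving the rank/field/sector grid and the
        molecular- and nuclear-layer counts unchanged.  Intended for quick,
        statistically faithful runs at reduced cost.
        """
        if factor <= 0:
            raise GeometryError(f"scale factor must be positive, got {factor}")
        return dataclasses.replace(
            self,
            glomeruli_per_field=max(1, int(round(self.glomeruli_per_field * factor))),
            granule_per_field=max(1, int(round(self.granule_per_field * factor))),
            mossy_fibres_total=max(
                self.n_ranks, int(round(self.mossy_fibres_total * factor))
            ),
            terminals_per_field_target=max(
                1, int(round(self.terminals_per_field_target * factor))
            ),
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "NetworkGeometry":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkGeometry":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_mapping(data or {})


def validate_geometry(geom: NetworkGeometry) -> dict[str, int]:
    """Validate ``geom`` and return its derived-count report."""
    return geom.validate()
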