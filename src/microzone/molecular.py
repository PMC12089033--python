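"""The microzone (molecular-layer) computation.

Stellate cells are linear units: each averages a binomially sized random
sample of the active parallel-fibre rates in its sector's file.  The sample
size law is Binomial(420, 0.0119): ~84 000 parallel fibres pass through an
inner stellate territory, ~420 are active at the 0.5% sparse code, and each
has contact probability 1000/84 000 ~ 0.0119.  Purkinje cells integrate two
flanking stellate networks through 16 dendritic compartments, each
averaging a small random sample of network afferents; the soma averages the
compartments.  Every stage is a mean of an independent random sample, so
the rate distribution narrows while its mean is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import stats

from .geometry import NetworkGeometry
from .granular import FileCode

__all__ = [
    "MolecularError",
    "DegenerateInputError",
    "StellateSampleLaw",
    "StellateLayerResult",
    "PCNetwork",
    "PurkinjeLayerResult",
    "stellate_sample_size_pmf",
    "simulate_stellate_layer",
    "build_pc_afferent_networks",
    "integrate_pc",
]

# depth layers 0 and 1 (of five) are "outer level": their limited axonal
# range excludes them from contacting Purkinje cells in neighbouring sectors
OUTER_DEPTH_LAYERS = 2


class MolecularError(ValueError):
    """Invalid molecular-layer input or parameter."""


class DegenerateInputError(MolecularError):
    """A sector's parallel-fibre pool is empty."""


@dataclass(frozen=True)
class StellateSampleLaw:
    """Binomial law for the number of active parallel fibres contacting a
    stellate cell.

    The default ``p_contact`` is the rounded constant 0.0119 used in the
    printed probability table; :meth:`from_geometry` derives the exact
    ratio (1000/84000 = 1/84) from the anatomy instead.  ``truncate_zero``
    resamples zero draws, since the mean-of-inputs unit function is
    undefined for a cell with no active input.
    """

    n_active: int = 420
    p_contact: float = 0.0119
    truncate_zero: bool = True

    @classmethod
    def from_geometry(cls, geom: NetworkGeometry, truncate_zero: bool = True) -> "StellateSampleLaw":
        return cls(
            n_active=geom.active_pf_through_stellate,
            p_contact=geom.contact_probability,
            truncate_zero=truncate_zero,
        )

    def pmf(self, x: int | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x)
        if np.any((x < 0) | (x > self.n_active)):
            raise MolecularError(
                f"x must lie in 0..{self.n_active}, got {x}"
            )
        out = stats.binom.pmf(x, self.n_active, self.p_contact)
        return float(out) if out.ndim == 0 else out

    @property
    def mean(self) -> float:
        return self.n_active * self.p_contact

    def pmf_table(self, x_max: int = 12) -> np.ndarray:
        return stats.binom.pmf(np.arange(x_max + 1), self.n_active, self.p_contact)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw sample sizes; zero draws are resampled if ``truncate_zero``."""
        x = rng.binomial(self.n_active, self.p_contact, size)
        if self.truncate_zero:
            while True:
                zeros = np.flatnonzero(x == 0)
                if zeros.size == 0:
                    break
                x[zeros] = rng.binomial(self.n_active, self.p_contact, zeros.size)
        return x


def stellate_sample_size_pmf(x: int, law: StellateSampleLaw | None = None) -> float:
    """Probability that a stellate cell is contacted by exactly ``x`` active
    parallel fibres."""
    law = law or StellateSampleLaw()
    return float(law.pmf(x))


@dataclass
class StellateLayerResult:
    """Outputs of every stellate unit, tidy arrays indexed by unit."""

    sector: np.ndarray
    depth_layer: np.ndarray
    cell_index: np.ndarray
    n_inputs: np.ndarray
    outputs: np.ndarray
    input_rates: list[np.ndarray] = dfield(repr=False, default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.outputs)

    def sector_outputs(self, sector: int) -> np.ndarray:
        return self.outputs[self.sector == sector]


def simulate_stellate_layer(
    files: list[FileCode],
    law: StellateSampleLaw,
    geom: NetworkGeometry,
    rng: np.random.Generator,
    store_inputs: bool = True,
) -> StellateLayerResult:
    """Stellate unit outputs for every sector.

    Each of the ``stellate_per_sector`` units of a sector draws its input
    count from ``law`` and averages that many rates sampled (without
    replacement where possible) from its own file's parallel-fibre pool;
    units never sample outside their file.
    """
    if len(files) != geom.n_sectors:
        raise MolecularError(
            f"expected {geom.n_sectors} file codes, got {len(files)}"
        )
    per = geom.stellate_per_sector
    n_units = geom.stellate_total
    sectors = np.repeat(np.arange(geom.n_sectors), per)
    local = np.tile(np.arange(per), geom.n_sectors)
    depth = local // geom.stellate_per_flank
    x = law.sample(rng, n_units)
    outputs = np.empty(n_units)
    inputs: list[np.ndarray] = []
    for s, code in enumerate(files):
        pool = code.pf_rates
        if pool.size == 0:
            raise DegenerateInputError(f"file/sector {s} has no active parallel fibres")
        for u in range(per):
            i = s * per + u
            k = int(x[i])
            picked = rng.choice(pool, size=k, replace=pool.size < k)
            outputs[i] = picked.mean()
            if store_inputs:
                inputs.append(picked)
    return StellateLayerResult(
        sector=sectors,
        depth_layer=depth,
        cell_index=np.arange(n_units),
        n_inputs=x,
        outputs=outputs,
        input_rates=inputs,
    )


@dataclass
class PCNetwork:
    """The two flanking stellate networks afferent to one Purkinje cell."""

    sector: int
    pc_index: int
    flanks: tuple[np.ndarray, np.ndarray]  # global stellate unit ids


def build_pc_afferent_networks(
    geom: NetworkGeometry, rng: np.random.Generator
) -> list[PCNetwork]:
    """Assign each Purkinje cell its two flanking stellate networks.

    Each flank holds ``stellate_per_flank`` units drawn from the cell's own
    sector (the two flanks are disjoint there) plus up to
    ``neighbour_stellate_max`` inner-level units from each sagittally
    neighbouring sector; edge sectors have a single neighbour (no wrap).
    """
    geom.validate()
    per = geom.stellate_per_sector
    flank_n = geom.stellate_per_flank
    inner_local = np.flatnonzero(
        np.arange(per) // flank_n >= OUTER_DEPTH_LAYERS
    )
    networks: list[PCNetwork] = []
    for s in range(geom.n_sectors):
        neighbours = [n for n in (s - 1, s + 1) if 0 <= n < geom.n_sectors]
        for pc in range(geom.pcs_per_sector):
            perm = rng.permutation(per)
            flanks = []
            for side in range(2):
                own = s * per + perm[side * flank_n : (side + 1) * flank_n]
                parts = [own]
                for n in neighbours:
                    k = int(rng.integers(0, geom.neighbour_stellate_max + 1))
                    if k:
                        chosen = rng.choice(inner_local, size=k, replace=False)
                        parts.append(n * per + chosen)
                flanks.append(np.concatenate(parts))
            networks.append(PCNetwork(sector=s, pc_index=pc, flanks=tuple(flanks)))
    return networks


@dataclass
class PurkinjeLayerResult:
    """Compartment and somatic values for every Purkinje cell."""

    sector: np.ndarray
    pc_index: np.ndarray
    compartments_by_flank: np.ndarray  # (n_pc, 2, n_compartments)
    compartments: np.ndarray  # (n_pc, n_compartments), mean of the two flanks
    soma: np.ndarray  # (n_pc,)

    @property
    def n_cells(self) -> int:
        return len(self.soma)


def integrate_pc(
    stellate: StellateLayerResult,
    networks: list[PCNetwork],
    geom: NetworkGeometry,
    rng: np.random.Generator,
) -> PurkinjeLayerResult:
    """Compartment sampling and somatic integration for every Purkinje cell.

    Per flank and compartment, the compartment averages
    ``compartment_sample_size`` distinct units of that flank's network
    (sampling is independent across compartments, so a unit may serve
    several).  A compartment's value is the mean of its two flank values;
    the soma is the mean of its compartments.
    """
    n_pc = len(networks)
    n_comp = geom.compartments_per_pc
    m = geom.compartment_sample_size
    by_flank = np.empty((n_pc, 2, n_comp))
    for i, net in enumerate(networks):
        for side, ids in enumerate(net.flanks):
            if ids.size < m:
                raise MolecularError(
                    f"flank network of PC {i} has {ids.size} units, "
                    f"fewer than the compartment sample size {m}"
                )
            vals = stellate.outputs[ids]
            # one vectorised without-replacement draw per compartment
            picks = np.argpartition(
                rng.random((n_comp, ids.size)), m - 1, axis=1
            )[:, :m]
            by_flank[i, side] = vals[picks].mean(axis=1)
    compartments = by_flank.mean(axis=1)
    soma = compartments.mean(axis=1)
    return PurkinjeLayerResult(
        sector=np.array([n.sector for n in networks]),
        pc_index=np.array([n.pc_index for n in networks]),
        compartments_by_flank=by_flank,
        compartments=compartments,
        soma=soma,
    )
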