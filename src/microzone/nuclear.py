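"""Nuclear convergence: the microzone's output layer.

Each of the ~50 cells of the nuclear group averages the somatic values of a
random sample of 30-50 of the microzone's 400 Purkinje cells.  This is the
final averaging step of the cascade: the output distribution is again
narrower than, and centred on the mean of, the Purkinje distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .geometry import GeometryError, NetworkGeometry
from .molecular import PurkinjeLayerResult

__all__ = ["NuclearOutputs", "project_to_nucleus"]


@dataclass
class NuclearOutputs:
    cell_index: np.ndarray
    sample_size: np.ndarray
    outputs: np.ndarray
    sampled_pc_ids: list[np.ndarray] = dfield(repr=False, default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.outputs)


def project_to_nucleus(
    pcs: PurkinjeLayerResult | np.ndarray,
    geom: NetworkGeometry,
    rng: np.random.Generator,
) -> NuclearOutputs:
    """Project Purkinje somatic values onto the nuclear group.

    Each output cell draws a sample size uniformly in
    ``[nuclear_sample_min, nuclear_sample_max]``, samples that many Purkinje
    cells without replacement, and outputs the mean of their somatic values.
    """
    soma = pcs.soma if isinstance(pcs, PurkinjeLayerResult) else np.asarray(pcs, float)
    if soma.size < geom.nuclear_sample_max:
        raise GeometryError(
            f"need at least nuclear_sample_max={geom.nuclear_sample_max} Purkinje "
            f"values, got {soma.size}"
        )
    n = geom.nuclear_cells
    sizes = rng.integers(geom.nuclear_sample_min, geom.nuclear_sample_max + 1, n)
    outputs = np.empty(n)
    picked_ids: list[np.ndarray] = []
    for i, m in enumerate(sizes):
        ids = rng.choice(soma.size, size=int(m), replace=False)
        picked_ids.append(ids)
        outputs[i] = soma[ids].mean()
    return NuclearOutputs(
        cell_index=np.arange(n),
        sample_size=sizes,
        outputs=outputs,
        sampled_pc_ids=picked_ids,
    )
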