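"""Result container for a converged (or capped) optimization run."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from vertopt.geometry import DensityField


@dataclass
class DesignResult:
    """Outcome of one topology-optimization run.

    ``density`` is always the full-model (mirrored) field so that designs
    from reduced-symmetry runs can be visualized and classified directly.
    ``density_reduced`` keeps the raw field on the run's reduced grid.
    """

    density: DensityField                 # full-model field
    density_reduced: DensityField         # field on the run's (reduced) grid
    group_name: str
    objective_history: np.ndarray         # f(rho) per iteration, J
    volume_history: np.ndarray            # volume ratio per iteration
    lambda_history: np.ndarray            # volume multiplier per iteration
    converged: bool
    iterations: int
    config: Any = None                    # OptimizerConfig
    provenance: dict = field(default_factory=dict)

    @property
    def final_objective(self) -> float:
        return float(self.objective_history[-1])

    @property
    def final_volume_ratio(self) -> float:
        return float(self.volume_history[-1])

    def summary(self) -> dict:
        return {
            "case": self.group_name,
            "compliance_J": self.final_objective,
            "volume_ratio": self.final_volume_ratio,
            "iterations": self.iterations,
            "converged": self.converged,
        }
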