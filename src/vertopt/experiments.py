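"""High-level runners: single optimizations and parameter sweeps.

``run_case`` wires together the domain build (with the symmetry reduction
each load case prescribes), the load group, the optimizer and the feature
classifier.  ``run_sweep`` replicates the published parameter studies:
volume-fraction series per load case, the bending-ratio sweep ``w``, the
arch-gap sweep ``eta``, the cone-angle sweep ``theta`` (with the slant
length rescaled as ``L(theta) = L sin(45 deg) / sin(theta)`` so the
dorsoventral height stays fixed), and the initial-density sensitivity
study.
"""

from __future__ import annotations

import dataclasses
import math
import traceback
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from vertopt import features as feat
from vertopt import io as vio
from vertopt import optimizer as opt
from vertopt.fem import MaterialModel
from vertopt.geometry import GeometryParams, build_domain
from vertopt.loads import CASE_NAMES, CASE_SYMMETRY, make_load_group
from vertopt.results import DesignResult

DEFAULT_ELEMENT_SIZE = 2.0e-4  # m; the coarsest grid resolving the shell

SWEEP_PARAMS = ("w", "eta", "theta", "init_value")


def domain_for_case(params: GeometryParams, case: str,
                    element_size: float = DEFAULT_ELEMENT_SIZE):
    """Build the analysis domain with the case's prescribed symmetry."""
    if case not in CASE_NAMES:
        raise ValueError(f"unknown load case {case!r}")
    return build_domain(params, element_size, symmetry=CASE_SYMMETRY[case])


def run_case(case: str,
             V_f: float = 0.3,
             params: Optional[GeometryParams] = None,
             element_size: float = DEFAULT_ELEMENT_SIZE,
             F: float = 1.0e6,
             w: Optional[float] = None,
             init_value: Optional[float] = None,
             material: Optional[MaterialModel] = None,
             optimizer: Optional[opt.OptimizerConfig] = None,
             classify: bool = True,
             callback=None):
    """Optimize one load case end to end.

    Returns ``(DesignResult, FeatureReport | None)``.
    """
    params = params or GeometryParams()
    material = material or MaterialModel()
    config = optimizer or opt.OptimizerConfig(V_f=V_f)
    if config.V_f != V_f:
        config = replace(config, V_f=V_f)
    domain = domain_for_case(params, case, element_size)
    group = make_load_group(case, domain, F=F, w=w)
    result = opt.run(domain, group, material, config,
                     init_value=init_value, callback=callback)
    result.provenance.update({"V_f": V_f, "F": F, "w": w,
                              "init_value": init_value})
    report = feat.classify_design(result.density) if classify else None
    return result, report


@dataclass
class SweepSpec:
    """Declarative description of a parameter sweep."""

    case: str
    V_f: Sequence[float] = (0.3,)
    grid_param: Optional[str] = None       # one of SWEEP_PARAMS, or None
    grid_values: Sequence[float] = ()
    geometry: GeometryParams = field(default_factory=GeometryParams)
    element_size: float = DEFAULT_ELEMENT_SIZE
    F: float = 1.0e6
    w: Optional[float] = None
    optimizer: opt.OptimizerConfig = field(default_factory=opt.OptimizerConfig)
    outdir: Optional[str] = None
    save_artifacts: bool = False

    def __post_init__(self) -> None:
        if self.case not in CASE_NAMES:
            raise ValueError(f"unknown load case {self.case!r}")
        if len(self.V_f) == 0:
            raise ValueError("V_f grid must be non-empty")
        if self.grid_param is not None:
            if self.grid_param not in SWEEP_PARAMS:
                raise ValueError(f"grid_param must be one of {SWEEP_PARAMS}")
            if len(self.grid_values) == 0:
                raise ValueError("grid_values must be non-empty")

    def points(self):
        """Yield (V_f, grid value or None) for every sweep point."""
        for vf in self.V_f:
            if self.grid_param is None:
                yield vf, None
            else:
                for g in self.grid_values:
                    yield vf, g

    @classmethod
    def from_yaml(cls, path) -> "SweepSpec":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SweepSpec":
        raw = dict(raw)
        if "geometry" in raw and isinstance(raw["geometry"], dict):
            raw["geometry"] = GeometryParams(**raw["geometry"])
        if "optimizer" in raw and isinstance(raw["optimizer"], dict):
            raw["optimizer"] = opt.OptimizerConfig(**raw["optimizer"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown sweep config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        import json
        # JSON round-trip turns tuples into YAML-safe lists.
        return json.loads(json.dumps(dataclasses.asdict(self), default=float))


def _sweep_geometry(spec: SweepSpec, g: Optional[float]) -> GeometryParams:
    base = spec.geometry
    if spec.grid_param == "eta":
        return replace(base, eta=float(g))
    if spec.grid_param == "theta":
        # Keep the dorsoventral height fixed while changing the cone angle.
        L = base.L * math.sin(math.radians(45.0)) / math.sin(math.radians(g))
        return replace(base, theta=float(g), L=L)
    return base


def run_sweep(spec: SweepSpec, progress=None) -> pd.DataFrame:
    """Run every sweep point; failures are recorded and the sweep continues.

    Returns a summary table (one row per point) and, when ``outdir`` is
    set, writes ``summary.csv``, the resolved config, and per-run
    artifacts.
    """
    rows = []
    outdir = Path(spec.outdir) if spec.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "sweep_config.yaml").write_text(
            yaml.safe_dump(spec.to_dict(), sort_keys=True))
    for i, (vf, g) in enumerate(spec.points()):
        row = {"index": i, "case": spec.case, "V_f": vf,
               "grid_param": spec.grid_param, "grid_value": g}
        try:
            geo_params = _sweep_geometry(spec, g)
            w = spec.w
            init_value = None
            if spec.grid_param == "w":
                w = float(g)
            elif spec.grid_param == "init_value":
                init_value = float(g)
            result, report = run_case(
                spec.case, V_f=vf, params=geo_params,
                element_size=spec.element_size, F=spec.F, w=w,
                init_value=init_value, optimizer=spec.optimizer)
            row.update(result.summary())
            counts = report.counts()
            for cls_name, n in counts.items():
                row[f"n_{cls_name.lower()}"] = n
            row["error"] = ""
            if outdir and spec.save_artifacts:
                vio.save_result(outdir / f"run_{i:03d}", result, report)
        except Exception as err:  # noqa: BLE001 - sweep must continue
            row["error"] = f"{type(err).__name__}: {err}"
            if progress:
                progress(traceback.format_exc())
        rows.append(row)
        if progress:
            progress(f"[{i + 1}] {row}")
    df = pd.DataFrame(rows)
    if outdir:
        df.to_csv(outdir / "summary.csv", index=False)
    return df
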