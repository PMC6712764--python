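"""YAML/JSON configuration for simulations.

A single document supplies the lattice geometry, every model parameter, the
tumor seeding and the run controls.  Unspecified keys fall back to the
reference defaults of :class:`~tumorvox.metabolism.ModelParams`.  Example::

    n: 21
    delta_s_mm: 2.0
    delta_tau_s: 10.0
    M: 8.0e6
    M_max_factor: 1.02
    lambda: 10
    beta1: 0.1
    beta2: 0.2
    regression_halftime_days: 5     # or v_r directly
    expansion_doubling_days: 1      # or v_e directly
    seeding:
      - voxel: [11, 11, 11]
        cells: 5.0e5
    horizon_days: 90
    replicates: 20
    seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lattice import LatticeSpec
from .metabolism import ModelParams, rate_from_doubling_days, rate_from_halftime_days

__all__ = ["SimulationConfig", "load_config"]

_PARAM_KEYS = {
    "M", "M_max", "K_o", "K_gl", "cc", "a_max", "beta1", "beta2", "h_o", "h_gl",
    "o0_bar", "gl0_bar", "o_b_max0", "gl_b_max0", "v_r", "v_e", "kappa",
    "perturb_period", "perturb_magnitude", "angiogenesis_enabled",
    "extinction_threshold", "D_o", "D_gl",
}

_ALIASES = {
    "n": None,  # handled separately
    "lambda": "lambda_",
    "o0": "o0_bar",
    "gl0": "gl0_bar",
    "o_b_max": "o_b_max0",
    "gl_b_max": "gl_b_max0",
}


@dataclass
class SimulationConfig:
    params: ModelParams
    spec: LatticeSpec
    seeding: list = field(default_factory=list)
    horizon_days: float = 90.0
    replicates: int = 20
    seed: int = 0
    D_c_principal: float = 1.5e-6
    D_c_transverse: float = 1.5e-8

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_days * 86400.0 / self.spec.delta_tau))


def load_config(path: str | Path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    N = int(doc.pop("n", doc.pop("N", 21)))
    delta_s = float(doc.pop("delta_s_mm", doc.pop("delta_s", 2.0)))
    delta_tau = float(doc.pop("delta_tau_s", doc.pop("delta_tau", 10.0)))
    spec = LatticeSpec(N=N, delta_s=delta_s, delta_tau=delta_tau)

    kwargs: dict = {}
    for key, val in list(doc.items()):
        target = _ALIASES.get(key, key)
        if target in _PARAM_KEYS or target == "lambda_":
            kwargs[target] = val
            doc.pop(key)
    if "M" in kwargs and "M_max" not in kwargs:
        kwargs["M_max"] = float(doc.pop("M_max_factor", 1.02)) * float(kwargs["M"])
    elif "M_max_factor" in doc:
        kwargs["M_max"] = float(doc.pop("M_max_factor")) * ModelParams().M
    if "regression_halftime_days" in doc:
        kwargs["v_r"] = rate_from_halftime_days(
            float(doc.pop("regression_halftime_days")), delta_tau
        )
    if "expansion_doubling_days" in doc:
        kwargs["v_e"] = rate_from_doubling_days(
            float(doc.pop("expansion_doubling_days")), delta_tau
        )
    params = ModelParams(**{k: v for k, v in kwargs.items()})

    seeding = []
    for item in doc.pop("seeding", []) or []:
        seeding.append((tuple(item["voxel"]), float(item["cells"])))
    return SimulationConfig(
        params=params,
        spec=spec,
        seeding=seeding,
        horizon_days=float(doc.pop("horizon_days", 90.0)),
        replicates=int(doc.pop("replicates", 20)),
        seed=int(doc.pop("seed", 0)),
        D_c_principal=float(doc.pop("D_c_principal", 1.5e-6)),
        D_c_transverse=float(doc.pop("D_c_transverse", 1.5e-8)),
    )
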