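"""Run configuration, unit-aware parameter files and experiment presets.

Parameter files are flat YAML. Physical quantities are strings with explicit
units (``"10 um"``, ``"40 kBT"``, ``"-2 mC/m2"``); silent unit mistakes are
the main practical hazard in this problem, so bare numbers are accepted only
for dimensionless entries. A file contains either a ``physical`` block or a
``dimensionless`` block (never both), an optional ``preset`` name the
physical block overrides, and an optional ``run`` block with solver options.

The presets mirror the experimental regimes: POPC vesicles in 1 M
sucrose/glucose on plain glass, with the ionic strength set by residual
ions (``no-salt``, Debye length about 300 nm), by the calcein contrast dye
(``calcein``, 214 nm), or by added salt (``salt-3mM``, 5.5 nm);
``uncharged`` switches the membrane charge (and with it the wall repulsion)
off.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

import numpy as np
import yaml
from scipy.constants import Avogadro, epsilon_0

from .physics import (K_B, DimensionlessParams, PhysicalParams,
                      nondimensionalize)

__all__ = ["RunConfig", "load_config", "save_dimensionless", "PRESETS",
           "parse_quantity", "preset_params"]


# unit token -> (SI factor, kind). 'kBT' and 'eps0' are resolved contextually.
_UNITS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    "kg/m3": 1.0, "g/m3": 1e-3,
    "Pa.s": 1.0, "Pa*s": 1.0, "mPa.s": 1e-3, "mPa*s": 1e-3, "cP": 1e-3,
    "J": 1.0, "kBT": None,
    "N/m": 1.0, "mN/m": 1e-3,
    "K": 1.0,
    "F/m": 1.0, "eps0": None,
    "C/m2": 1.0, "mC/m2": 1e-3, "uC/m2": 1e-6,
    "M": 1e3 * Avogadro, "mol/L": 1e3 * Avogadro,
    "mM": Avogadro, "mol/m3": Avogadro, "uM": 1e-3 * Avogadro,
    "1/m3": 1.0, "m-3": 1.0,
    "m/s2": 1.0,
}


def parse_quantity(text, temperature: float | None = None) -> float:
    """Parse ``"<value> <unit>"`` to SI.

    Thermal units need the temperature: ``"40 kBT"`` is ``40 k_B T`` joules;
    ``"78.5 eps0"`` multiples of the vacuum permittivity. Plain numbers pass
    through unchanged (dimensionless or already-SI values).
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([^\s]*)\s*", str(text))
    if not m:
        raise ValueError(f"cannot parse quantity {text!r}")
    value, unit = float(m.group(1)), m.group(2)
    if not unit:
        return value
    if unit == "kBT":
        if temperature is None:
            raise ValueError("'kBT' units need the temperature")
        return value * K_B * temperature
    if unit == "eps0":
        return value * epsilon_0
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r} in {text!r}")
    return value * _UNITS[unit]


# experimental defaults: POPC GUV in 1 M sucrose/glucose over plain glass
_BASE = {
    "a": "10 um",
    "mu": "2.0 mPa.s",
    "delta_rho": "35 kg/m3",
    "kappa_b": "40 kBT",
    "K_A": "0.2 N/m",
    "T": "296 K",
    "epsilon": "78.5 eps0",
    "sigma_glass": "-2 mC/m2",
    "sigma_vesicle": "-2 mC/m2",
    "g": "9.81 m/s2",
}

PRESETS = {
    # residual hydronium/salt only: Debye length about 300 nm
    "no-salt": {**_BASE, "n_ion": "1.02 uM"},
    # 1 uM calcein adds counterions at about 2 uM: 214 nm
    "calcein": {**_BASE, "n_ion": "2 uM"},
    # 3 mM NaCl screens the repulsion down to 5.5 nm
    "salt-3mM": {**_BASE, "n_ion": "3 mM"},
    # unlabelled membrane: no surface charge, no wall repulsion
    "uncharged": {**_BASE, "n_ion": "2 uM", "sigma_vesicle": "0 C/m2"},
}


@dataclass
class RunConfig:
    """Solver and output options for one simulation."""

    refinement: int = 3
    initial_height: float = 6.0
    max_time: float = np.inf
    electrostatics: bool = True
    stabilization: bool = True
    resample_15s: bool = False
    equil_tol: float = 1e-6
    equil_consecutive: int = 10
    sample_every: int = 5
    gap_floor: float = 1e-3
    safety: float = 1.0
    snapshot_every: int | None = None
    output_dir: str = "."

    def __post_init__(self):
        if not (1 <= self.refinement <= 5):
            raise ValueError("refinement must be in [1, 5]")
        if self.initial_height <= 1:
            raise ValueError("initial_height must be > 1 (vesicle radii)")


def preset_params(name: str, overrides: dict | None = None) -> PhysicalParams:
    """PhysicalParams for a named preset, with optional key overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; "
                         f"available: {sorted(PRESETS)}")
    raw = dict(PRESETS[name])
    if overrides:
        raw.update(overrides)
    return _physical_from_mapping(raw)


def _physical_from_mapping(raw: dict) -> PhysicalParams:
    T = parse_quantity(raw.get("T", _BASE["T"]))
    known = {f.name for f in fields(PhysicalParams)}
    errors = [f"unknown physical key {k!r}" for k in raw if k not in known]
    missing = [k for k in known
               if k not in raw and k not in ("g", "lambda_visc")]
    errors += [f"missing physical key {k!r}" for k in missing]
    if errors:
        raise ValueError("invalid physical block: " + "; ".join(errors))
    kwargs = {}
    for k, v in raw.items():
        kwargs[k] = parse_quantity(v, temperature=T)
    return PhysicalParams(**kwargs)


def _dimensionless_from_mapping(raw: dict) -> DimensionlessParams:
    known = {f.name for f in fields(DimensionlessParams)}
    errors = [f"unknown dimensionless key {k!r}" for k in raw
              if k not in known]
    missing = [k for k in ("Bg", "B_el", "lambda_bar", "c_tilde")
               if k not in raw]
    errors += [f"missing dimensionless key {k!r}" for k in missing]
    if errors:
        raise ValueError("invalid dimensionless block: " + "; ".join(errors))
    return DimensionlessParams(**{k: float(v) for k, v in raw.items()})


def load_config(path):
    """Read a YAML parameter file.

    Returns ``(params, run_config)`` where ``params`` is a
    :class:`PhysicalParams` (physical block, possibly on top of a preset) or
    a :class:`DimensionlessParams` (dimensionless block). Supplying both
    blocks is an error, as is any unknown or missing key.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    if "physical" in doc and "dimensionless" in doc:
        raise ValueError("config has both 'physical' and 'dimensionless' "
                         "blocks; give exactly one")
    run = RunConfig(**(doc.get("run") or {}))
    if "dimensionless" in doc:
        if "preset" in doc:
            raise ValueError("a preset implies physical parameters and "
                             "cannot be combined with a dimensionless block")
        return _dimensionless_from_mapping(doc["dimensionless"]), run
    overrides = doc.get("physical") or {}
    if "preset" in doc:
        return preset_params(doc["preset"], overrides), run
    if not overrides:
        raise ValueError("config needs a 'preset', 'physical' or "
                         "'dimensionless' section")
    return _physical_from_mapping(overrides), run


def save_dimensionless(params: DimensionlessParams, path,
                       run: RunConfig | None = None):
    """Write a dimensionless parameter block (round-trips bit-identically)."""
    doc = {"dimensionless": {
        "Bg": float(params.Bg), "B_el": float(params.B_el),
        "lambda_bar": float(params.lambda_bar),
        "c_tilde": float(params.c_tilde),
        "kappa_kT": float(params.kappa_kT),
        "lambda_visc": float(params.lambda_visc),
        "sigma_red": float(params.sigma_red),
        "topology_coeff": float(params.topology_coeff),
    }}
    if run is not None:
        doc["run"] = {k: float(v) if isinstance(v, float) else v
                      for k, v in run.__dict__.items()
                      if not (isinstance(v, float) and not np.isfinite(v))}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def describe_groups(params) -> str:
    """Human-readable echo of the dimensionless groups of a run."""
    d = params if isinstance(params, DimensionlessParams) \
        else nondimensionalize(params)
    lines = [
        f"Bg          = {d.Bg:.6g}   (gravitational number)",
        f"B_el        = {d.B_el:.6g}   (electrostatic traction scale)",
        f"lambda_bar  = {d.lambda_bar:.6g}   (Debye length / radius)",
        f"c_tilde     = {d.c_tilde:.6g}   (direct-dilation modulus)",
        f"kappa_b/kT  = {d.kappa_kT:.6g}",
        f"lambda_visc = {d.lambda_visc:.6g}",
    ]
    return "\n".join(lines)
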