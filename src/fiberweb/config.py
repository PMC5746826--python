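"""Run configuration: YAML/JSON loading and validation against model preconditions."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import model
from .exceptions import FiberwebError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for CLI runs.

    Porosity may be given directly (``P``) or as a gravimetric mass record
    (``M2_g`` + ``rho_g_cm3``), in which case it is derived at load time.
    """

    L_mm: float = 40.0
    W_mm: float = 5.0
    T_mm: float = 0.11
    P: float | None = 0.75
    M2_g: float | None = None
    rho_g_cm3: float | None = None
    radius_nm: float = 136.0
    exact_pi_r2: bool = False
    calibration: float = 1.0
    n_seeds: int = 10
    Nf_cap: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P is None:
            if self.M2_g is None or self.rho_g_cm3 is None:
                raise FiberwebError(
                    "either porosity P or a mass record (M2_g, rho_g_cm3) is required"
                )
            self.P = model.porosity_from_mass(
                self.M2_g, self.L_mm, self.W_mm, self.T_mm, self.rho_g_cm3
            )
        if not (0 <= self.P < 1):
            raise FiberwebError(f"porosity P = {self.P} outside [0, 1)")
        if not (self.L_mm > 0 and self.W_mm > 0 and self.T_mm > 0):
            raise FiberwebError("geometry dimensions must be > 0")
        if not self.radius_nm > 0:
            raise FiberwebError("radius_nm must be > 0")
        if self.calibration <= 0:
            raise FiberwebError("calibration must be > 0")
        if self.n_seeds < 1:
            raise FiberwebError("n_seeds must be >= 1")

    @property
    def k(self) -> float:
        return self.W_mm / self.L_mm

    @property
    def r_mm(self) -> float:
        return float(model.nm_to_mm(self.radius_nm))

    @property
    def geometry(self) -> model.MembraneGeometry:
        return model.MembraneGeometry(L=self.L_mm, W=self.W_mm, T=self.T_mm)

    def metadata(self) -> dict:
        """Full serializable record embedded in every output artifact."""
        from . import __version__

        d = asdict(self)
        d["fiberweb_version"] = __version__
        return d


def _flatten(doc: dict) -> dict:
    """Accept either flat keys or the nested layout
    {geometry: {...}, porosity: {...}, fiber: {...}, model: {...}, simulation: {...}}."""
    flat: dict = {}
    nested_maps = {
        "geometry": {"L_mm": "L_mm", "W_mm": "W_mm", "T_mm": "T_mm"},
        "porosity": {"P": "P", "M2_g": "M2_g", "rho_g_cm3": "rho_g_cm3"},
        "fiber": {"radius_nm": "radius_nm"},
        "model": {"exact_pi_r2": "exact_pi_r2", "calibration": "calibration"},
        "simulation": {"n_seeds": "n_seeds", "Nf_cap": "Nf_cap"},
    }
    for key, val in doc.items():
        if key in nested_maps and isinstance(val, dict):
            for sub, target in nested_maps[key].items():
                if sub in val:
                    flat[target] = val[sub]
            unknown = set(val) - set(nested_maps[key])
            if unknown:
                raise FiberwebError(f"unknown keys {sorted(unknown)} in '{key}'")
        else:
            flat[key] = val
    if "porosity" in flat and not isinstance(flat["porosity"], dict):
        flat["P"] = flat.pop("porosity")
    return flat


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config file into a validated :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FiberwebError(f"config root must be a mapping in {path}")
    flat = _flatten(doc)
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(flat) - valid
    if unknown:
        raise FiberwebError(f"unknown config keys: {sorted(unknown)}")
    if "P" in flat and ("M2_g" in flat or "rho_g_cm3" in flat):
        raise FiberwebError("give porosity either as P or as a mass record, not both")
    if "M2_g" in flat:
        flat.setdefault("P", None)
    return RunConfig(**flat)
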