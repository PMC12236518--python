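"""Packaged fixture presets for the synthetic generators.

Parameters live in ``data/presets.yaml`` and mirror a realistic
fragment-stabilization study of a PAS-HTH receptor: a DMSO control
melting at 53.4 °C, three stabilizing fragments (KG-96, KG-408,
KG-484) with their melting temperatures and micromolar dissociation
constants, a 760-compound duplicate screen, and apo/ligand-bound
amide-I thermal ramps in which the ligand shifts the native β-sheet
melting midpoint by +14 °C and helix classes by 4–5 °C.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import yaml

from .synthdata import (
    AggregateBand,
    BindingTruth,
    DSFGenParams,
    IRBandTruth,
    IRGenParams,
    ScreenSpec,
)

__all__ = [
    "available",
    "dsf_params",
    "binding_truth",
    "std_noise_cv",
    "screen_spec",
    "ir_params",
    "native_beta_shift",
]


@functools.lru_cache(maxsize=1)
def _presets() -> dict:
    text = resources.files("stabscreen").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def _grid(spec: dict) -> np.ndarray:
    return np.arange(spec["start"], spec["stop"] + 1e-9, spec["step"])


def available() -> dict[str, list[str]]:
    """Names of the packaged presets by stage."""
    p = _presets()
    return {"dsf": sorted(p["dsf"]), "std": sorted(p["std"]), "ir": sorted(p["ir"])}


def dsf_params(name: str, **overrides) -> DSFGenParams:
    """DSF generator preset (``control``, ``KG-96``, ``KG-408``, ``KG-484``)."""
    cfg = dict(_presets()["dsf"][name])
    cfg["temp_grid"] = _grid(cfg["temp_grid"])
    cfg.update(overrides)
    return DSFGenParams(**cfg)


def binding_truth(name: str, **overrides) -> BindingTruth:
    """STD binding-truth preset for one ligand (``KG-96``, ``KG-408``, ``KG-484``)."""
    cfg = dict(_presets()["std"][name])
    epi = cfg.pop("epitopes")
    cfg.pop("noise_cv", None)
    cfg["alpha_std"] = {k: v["alpha_std"] for k, v in epi.items()}
    cfg["ksat_ref"] = {k: v["ksat_ref"] for k, v in epi.items()}
    cfg["ligand_concs"] = tuple(cfg["ligand_concs"])
    cfg["sat_times"] = tuple(cfg["sat_times"])
    cfg.update(overrides)
    return BindingTruth(**cfg)


def std_noise_cv(name: str) -> float:
    """Default multiplicative noise CV for an STD preset."""
    return float(_presets()["std"][name]["noise_cv"])


def screen_spec(seed: int = 0, **overrides) -> ScreenSpec:
    """The 760-compound duplicate-screen preset."""
    cfg = dict(_presets()["screen"])
    cfg["hit_delta_range"] = tuple(cfg["hit_delta_range"])
    cfg["seed"] = seed
    cfg.update(overrides)
    return ScreenSpec(**cfg)


def ir_params(name: str, **overrides) -> IRGenParams:
    """Amide-I ramp preset (``apo`` or ``KG-408`` ligand-bound)."""
    cfg = dict(_presets()["ir"][name])
    bands = tuple(IRBandTruth(**b) for b in cfg.pop("bands"))
    agg = AggregateBand(**cfg.pop("aggregate_band"))
    cfg["wavenumber_grid"] = _grid(cfg["wavenumber_grid"])
    cfg["temp_grid"] = _grid(cfg["temp_grid"])
    cfg.update(overrides)
    return IRGenParams(band_truth=bands, aggregate_band=agg, **cfg)


def native_beta_shift(apo: str = "apo", bound: str = "KG-408") -> float:
    """Generating native β-sheet melt-midpoint shift between two IR presets."""
    def tm(name: str) -> float:
        tms = {b.melt_tm for b in ir_params(name).band_truth
               if b.structure_class == "native_beta"}
        if len(tms) != 1:
            raise ValueError(f"preset {name!r} has inconsistent native-beta midpoints")
        return tms.pop()
    return tm(bound) - tm(apo)
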