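"""CSV/YAML/JSON interchange, run configuration and the end-to-end pipeline.

CSV is the lone interchange format; units are embedded in the column
names (``temperature_C``, ``ligand_conc_uM``, ``sat_time_s``,
``wavenumber_cm1``) to prevent silent unit mistakes.  Every output file
carries the run-configuration hash so each reported number is traceable
to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .dsf import HitTable, MeltCurve, call_hits, fit_replicates
from .mms import IRSpectrumSeries, default_band_model, run_thermal_ramp
from .stdnmr import RECORD_COLUMNS, STDDataset, run_std_pipeline
from .synthdata import generate_dsf_curve, generate_ir_series, generate_screen, generate_std_dataset

__all__ = [
    "load_tables",
    "load_std_dataset",
    "write_melt_csv",
    "write_std_csv",
    "write_ir_csv",
    "RunConfig",
    "RunReport",
    "run_end_to_end",
]

logger = logging.getLogger("stabscreen")

MELT_COLUMNS = ("well", "compound", "replicate", "temperature_C", "fluorescence")
SCHEMAS = {
    "melt": MELT_COLUMNS,
    "std_integrals": RECORD_COLUMNS,
    "spectrum": ("ppm", "intensity"),
    "ir_matrix": ("wavenumber_cm1",),
}


def _check_columns(df: pd.DataFrame, schema: str) -> None:
    required = SCHEMAS[schema]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{schema} table is missing required column {col!r}")


def load_tables(path, schema: str):
    """Load and validate a typed dataset from CSV.

    ``schema`` is one of ``melt`` (long-format well traces →
    list[MeltCurve]), ``std_integrals`` (record DataFrame), ``spectrum``
    ((ppm, intensity) arrays) or ``ir_matrix`` (IRSpectrumSeries with
    one column per ramp temperature).  Lines starting with ``#`` are
    treated as comments.  Non-monotone axes are rejected.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path, comment="#")
    _check_columns(df, schema)
    if schema == "melt":
        curves = []
        for (well, compound, rep), g in df.groupby(["well", "compound", "replicate"],
                                                   sort=False):
            t = g["temperature_C"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise ValueError(
                    f"temperature_C not strictly increasing for well {well!r}")
            curves.append(MeltCurve(str(well), str(compound), t,
                                    g["fluorescence"].to_numpy(float), int(rep)))
        return curves
    if schema == "std_integrals":
        return df.loc[:, list(RECORD_COLUMNS)]
    if schema == "spectrum":
        ppm = df["ppm"].to_numpy(float)
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be monotone")
        return ppm, df["intensity"].to_numpy(float)
    # ir_matrix
    wn = df["wavenumber_cm1"].to_numpy(float)
    if not np.all(np.diff(wn) > 0):
        raise ValueError("wavenumber_cm1 must be strictly increasing")
    temp_cols = [c for c in df.columns if c != "wavenumber_cm1"]
    try:
        temps = np.array([float(c) for c in temp_cols])
    except ValueError as err:
        raise ValueError(f"ir_matrix temperature headers must be numeric °C: {err}") from err
    order = np.argsort(temps)
    absorb = df[temp_cols].to_numpy(float).T[order]
    return IRSpectrumSeries(wn, temps[order], absorb)


def load_std_dataset(path, protein_conc_uM: float) -> STDDataset:
    """Load an STD integral table; the protein concentration is a required input."""
    return STDDataset(load_tables(path, "std_integrals"), protein_conc_uM)


def _write_csv(df: pd.DataFrame, path, config_hash: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def write_melt_csv(curves: list[MeltCurve], path, config_hash: str | None = None) -> None:
    frames = [
        pd.DataFrame({
            "well": c.well_id, "compound": c.compound_id, "replicate": c.replicate_index,
            "temperature_C": c.temperature, "fluorescence": c.fluorescence,
        })
        for c in curves
    ]
    _write_csv(pd.concat(frames, ignore_index=True), path, config_hash)


def write_std_csv(dataset: STDDataset, path, config_hash: str | None = None) -> None:
    _write_csv(dataset.records.loc[:, list(RECORD_COLUMNS)], path, config_hash)


def write_ir_csv(series: IRSpectrumSeries, path, config_hash: str | None = None) -> None:
    wide = pd.DataFrame({"wavenumber_cm1": series.wavenumbers})
    for t, row in zip(series.temperatures, series.absorbance):
        wide[f"{t:g}"] = row
    _write_csv(wide, path, config_hash)


# ---------------------------------------------------------------------------
# Run configuration and end-to-end pipeline


@dataclass
class RunConfig:
    """Reproducible-run configuration; all randomness flows from ``seed``."""

    seed: int = 0
    fixture: str = "demo"
    out_dir: str = "stabscreen_out"
    stages: tuple[str, ...] = ("dsf", "std", "mms")
    log_level: str = "INFO"
    screen_compounds: int = 120
    std_noise_cv: float = 0.03
    std_ligands: tuple[str, ...] = ("KG-96", "KG-408", "KG-484")
    ir_temp_step: float = 1.0

    def validate(self) -> None:
        unknown = set(self.stages) - {"dsf", "std", "mms"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["std_ligands"] = list(self.std_ligands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("stages", "std_ligands"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summaries with provenance."""

    config: dict
    config_hash: str
    package_version: str
    stages: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        body = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=float)
        if path is not None:
            Path(path).write_text(body)
        return body

    @property
    def ok(self) -> bool:
        return not self.errors


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def run_end_to_end(config: RunConfig, out_dir=None) -> RunReport:
    """Run the requested stages on packaged fixtures and write all artifacts.

    Identical config + seed reproduces byte-identical report bodies.  A
    stage failure is recorded in the report's ``errors`` and the
    remaining stages still run.
    """
    from . import __version__

    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    report = RunReport(config.to_dict(), chash, __version__)
    seeds = _stage_seeds(config.seed)

    if "dsf" in config.stages:
        try:
            spec = fixtures.screen_spec(seed=seeds[0],
                                        n_compounds=config.screen_compounds)
            base = fixtures.dsf_params("control")
            curves, truth = generate_screen(spec, base_params=base)
            hits = call_hits(fit_replicates(curves), control_id="DMSO")
            hits.to_csv(out / "hits.csv")
            _write_csv(truth, out / "screen_truth.csv", chash)
            report.stages["dsf"] = {
                "n_compounds": int(spec.n_compounds),
                "control_mean_tm_C": hits.control_mean_tm,
                "compound_tm_sd_C": hits.compound_tm_sd,
                "threshold_C": hits.threshold,
                "n_hits": int(hits.table["hit"].sum()),
                "n_discarded": int(hits.table["discard_reason"].notna().sum()),
            }
        except Exception as err:  # noqa: BLE001 - partial reports are the contract
            logger.exception("dsf stage failed")
            report.errors["dsf"] = str(err)

    if "std" in config.stages:
        try:
            summary = {}
            for i, ligand in enumerate(config.std_ligands):
                truth = fixtures.binding_truth(ligand)
                ds = generate_std_dataset(truth, config.std_noise_cv, seeds[1] + i)
                est = run_std_pipeline(ds)
                (out / f"kd_{ligand}.json").write_text(
                    json.dumps({"config_hash": chash, **est.to_dict()}, indent=2))
                summary[ligand] = {
                    "kd_uM": est.kd_combined,
                    "kd_se_uM": est.kd_combined_se,
                    "kd_true_uM": truth.kd_true,
                }
            report.stages["std"] = summary
        except Exception as err:  # noqa: BLE001
            logger.exception("std stage failed")
            report.errors["std"] = str(err)

    if "mms" in config.stages:
        try:
            model = default_band_model()
            results = {}
            for i, name in enumerate(("apo", "KG-408")):
                params = fixtures.ir_params(name)
                if config.ir_temp_step != 1.0:
                    tg = params.temp_grid
                    params = dataclasses.replace(
                        params, temp_grid=np.arange(tg[0], tg[-1] + 1e-9,
                                                    config.ir_temp_step))
                series = generate_ir_series(params, seeds[2] + i, meta={"sample": name})
                comps, analysis, _ = run_thermal_ramp(series, model)
                frac = pd.DataFrame([c.fractions for c in comps])
                frac.insert(0, "temperature_C", series.temperatures)
                _write_csv(frac, out / f"hos_fractions_{name}.csv", chash)
                (out / f"thermal_{name}.json").write_text(
                    json.dumps({"config_hash": chash, **analysis.to_dict()}, indent=2))
                results[name] = analysis
            d_native = (results["KG-408"].per_class["native_beta"].tm
                        - results["apo"].per_class["native_beta"].tm)
            report.stages["mms"] = {
                "global_tm_apo_C": results["apo"].global_tm,
                "global_tm_bound_C": results["KG-408"].global_tm,
                "delta_tm_native_beta_C": d_native,
                "per_class_tm_apo_C": {k: v.tm for k, v in results["apo"].per_class.items()},
                "per_class_tm_bound_C": {k: v.tm for k, v in
                                         results["KG-408"].per_class.items()},
            }
        except Exception as err:  # noqa: BLE001
            logger.exception("mms stage failed")
            report.errors["mms"] = str(err)

    report.to_json(out / "report.json")
    return report
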