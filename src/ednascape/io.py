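"""Readers and writers for the pipeline's file formats.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimals; reach ids are strings.  Writers and readers round-trip
bit-exactly on valid data (floats are written with shortest-roundtrip
repr).  Formats:

* network: edge list with id, downstream_id (empty = outlet), hydraulic
  columns, covariates prefixed ``cov_``, optional habitat_class;
* eDNA reads: rows = sites, columns = taxa, plus total_reads;
* kick-net: site × taxon 0/1;
* habitat: reach_id, habitat_class;
* detection maps: reach × taxon probability matrix and a 0/1 twin;
* IBCH config: a directory bundle (gi_map.csv, variety.csv, bands.csv,
  optional score_table.csv);
* run config: YAML; each run writes a log with seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import RiverNetwork, build_network
from .edith import EDNASampleTable, DetectionMap
from .ibch import IBCHConfig

__all__ = [
    "read_network", "write_network",
    "read_reads", "write_reads",
    "read_presence", "write_presence",
    "read_habitat", "write_habitat",
    "read_detection_maps", "write_detection_maps",
    "read_ibch_config", "write_ibch_config",
    "read_site_map",
    "write_scenario", "read_scenario_inputs",
    "load_yaml_config", "config_hash", "write_run_log",
    "FormatError",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _read_csv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, **kw)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------- network

def write_network(net: RiverNetwork, path) -> None:
    net.to_frame().to_csv(path, index=False)


def read_network(path) -> RiverNetwork:
    df = _read_csv(path, dtype={"id": str, "downstream_id": str},
                   keep_default_na=False, na_values=[])
    _require_columns(df, ["id", "downstream_id", "length_m", "width_m",
                          "local_area_km2", "discharge_m3s", "velocity_ms"],
                     path)
    for col in ["length_m", "width_m", "local_area_km2", "discharge_m3s",
                "velocity_ms"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric value in column "
                              f"{col!r} at line {line}")
    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    for col in cov_cols:
        df[col] = pd.to_numeric(df[col])
    if "habitat_class" in df.columns:
        df["habitat_class"] = pd.to_numeric(df["habitat_class"],
                                            errors="coerce")
        if df["habitat_class"].isna().all():
            df = df.drop(columns=["habitat_class"])
    return build_network(df)


# ---------------------------------------------------------------- reads

def write_reads(table: EDNASampleTable, path) -> None:
    table.to_frame().to_csv(path)


def read_reads(path) -> EDNASampleTable:
    df = _read_csv(path, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    _require_columns(df, ["total_reads"], path)
    taxa = [c for c in df.columns if c != "total_reads"]
    reads = df[taxa].to_numpy()
    if not np.issubdtype(reads.dtype, np.number) or (reads < 0).any():
        bad = np.argwhere(~(df[taxa].to_numpy() >= 0))
        row, col = bad[0]
        raise FormatError(f"{path}: negative or non-numeric read count at "
                          f"line {row + 2}, column {taxa[col]!r}")
    return EDNASampleTable(sites=list(df.index), taxa=taxa,
                           reads=reads.astype(np.int64),
                           site_depth=df["total_reads"].to_numpy(np.int64))


# ---------------------------------------------------------------- presence

def write_presence(presence: pd.DataFrame, path) -> None:
    presence.astype(int).to_csv(path, index_label=presence.index.name
                                or "unit_id")


def read_presence(path) -> pd.DataFrame:
    df = _read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise FormatError(f"{path}: presence values must be 0/1")
    return df.astype(bool)


# ---------------------------------------------------------------- habitat

def write_habitat(habitat: pd.Series, path) -> None:
    habitat.rename("habitat_class").to_frame().to_csv(
        path, index_label="reach_id")


def read_habitat(path) -> pd.Series:
    df = _read_csv(path, dtype={"reach_id": str})
    _require_columns(df, ["reach_id", "habitat_class"], path)
    return df.set_index("reach_id")["habitat_class"].astype(int)


def read_site_map(path) -> dict[str, str]:
    df = _read_csv(path, dtype=str)
    _require_columns(df, ["site_id", "reach_id"], path)
    return dict(zip(df["site_id"], df["reach_id"]))


# ---------------------------------------------------------------- maps

def write_detection_maps(maps: dict[str, DetectionMap], prob_path,
                         presence_path=None) -> None:
    probs = pd.DataFrame({t: m.detection_prob for t, m in maps.items()})
    probs.to_csv(prob_path, index_label="reach_id")
    if presence_path is not None:
        pres = pd.DataFrame({t: m.presence for t, m in maps.items()})
        pres.astype(int).to_csv(presence_path, index_label="reach_id")


def read_detection_maps(prob_path, threshold: float | None = None
                        ) -> dict[str, DetectionMap]:
    df = _read_csv(prob_path, index_col="reach_id", dtype={"reach_id": str})
    df.index = df.index.astype(str)
    if ((df < 0) | (df > 1)).any().any():
        raise FormatError(f"{prob_path}: detection probabilities outside [0,1]")
    maps = {}
    for t in df.columns:
        m = DetectionMap(taxon=t, detection_prob=df[t])
        if threshold is not None:
            from .edith import apply_presence_threshold
            m = apply_presence_threshold(m, threshold)
        maps[t] = m
    return maps


# ---------------------------------------------------------------- IBCH config

def write_ibch_config(cfg: IBCHConfig, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(cfg.gi_map.items()),
                 columns=["taxon", "gi"]).to_csv(d / "gi_map.csv", index=False)
    pd.DataFrame([(lo, "" if hi is None else hi, cv)
                  for lo, hi, cv in cfg.variety_breakpoints],
                 columns=["min_taxa", "max_taxa", "cv"]
                 ).to_csv(d / "variety.csv", index=False)
    pd.DataFrame(cfg.status_bands, columns=["min", "max", "label"]
                 ).to_csv(d / "bands.csv", index=False)
    if cfg.score_table is not None:
        cfg.score_table.to_csv(d / "score_table.csv", index=False)


def read_ibch_config(directory) -> IBCHConfig:
    d = Path(directory)
    gi = _read_csv(d / "gi_map.csv", dtype={"taxon": str})
    _require_columns(gi, ["taxon", "gi"], d / "gi_map.csv")
    var = _read_csv(d / "variety.csv", keep_default_na=False, na_values=[])
    _require_columns(var, ["min_taxa", "max_taxa", "cv"], d / "variety.csv")
    bands = _read_csv(d / "bands.csv")
    _require_columns(bands, ["min", "max", "label"], d / "bands.csv")
    score = None
    if (d / "score_table.csv").exists():
        score = _read_csv(d / "score_table.csv")
        _require_columns(score, ["gi", "cv", "score"], d / "score_table.csv")
    return IBCHConfig(
        gi_map=dict(zip(gi["taxon"], gi["gi"].astype(int))),
        variety_breakpoints=[
            (int(r.min_taxa),
             None if r.max_taxa in ("", None) else int(r.max_taxa),
             int(r.cv)) for r in var.itertuples()],
        status_bands=[(int(r.min), int(r.max), str(r.label))
                      for r in bands.itertuples()],
        score_table=score)


# ---------------------------------------------------------------- scenario

def write_scenario(scen, directory) -> None:
    """Serialise a synthetic scenario bundle (see synthetic module)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_network(scen.truth.network, d / "network.csv")
    write_reads(scen.edna, d / "edna_reads.csv")
    write_presence(scen.kicknet, d / "kicknet.csv")
    write_habitat(scen.habitat, d / "habitat.csv")
    truth = {
        "seed": scen.seed,
        "taxa": [asdict(t) for t in scen.truth.true_params],
        "true_presence": {t: scen.truth.true_presence[t].astype(int).tolist()
                          for t in scen.truth.true_presence.columns},
        "latent_quality": scen.truth.latent_quality.tolist(),
        "reach_ids": [str(r) for r in scen.truth.network.ids],
        "warnings": scen.truth.warnings,
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    (d / "scenario_config.yaml").write_text(
        yaml.safe_dump(scen.config.as_dict(), sort_keys=True))


def read_scenario_inputs(directory):
    """Load the observable part of a scenario bundle (no truth)."""
    d = Path(directory)
    return (read_network(d / "network.csv"),
            read_reads(d / "edna_reads.csv"),
            read_presence(d / "kicknet.csv"),
            read_habitat(d / "habitat.csv"))


# ---------------------------------------------------------------- config/log

def load_yaml_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_log(outdir, stage: str, seed: int, cfg: dict,
                  extra: dict | None = None) -> Path:
    """Structured one-run log: stage, seed, config hash, versions."""
    import ednascape
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    log = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "python": sys.version.split()[0],
        "ednascape": ednascape.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if extra:
        log.update(extra)
    path = d / f"run_{stage}.log.json"
    path.write_text(json.dumps(log, indent=1, sort_keys=True))
    return path
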