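"""Pipeline configuration: YAML loading, validation, run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

ENRICH_KEYS = {
    "matrix",
    "genes",
    "barcodes",
    "annotation",
    "gene_set",
    "q_max",
    "lfc_min",
    "min_cells",
    "eligibility_fraction",
    "bh_family",
    "epsilon",
    "exact_limit",
    "scale_target",
    "log_base",
}

QUANTIFY_KEYS = {
    "signals",
    "controls",
    "cells",
    "calibration",
    "rules",
}

SC_SIM_KEYS = {
    "n_genes",
    "n_identities",
    "cells_per_identity",
    "baseline_mean_log_mu",
    "baseline_mean_log_sd",
    "nb_dispersion",
    "set_size",
    "planted_identity",
    "planted_set_fraction",
    "planted_fold",
    "seed",
}

SPOT_SIM_KEYS = {
    "cell_types",
    "n_cells",
    "single_intensity_mean",
    "single_intensity_sd",
    "background",
    "cluster_prob",
    "n_control_cells",
    "control_noise_sd",
    "animal_id",
    "section_id",
    "condition",
    "seed",
}


def load_config(path: str | Path | None, allowed: set[str]) -> dict:
    """Load a YAML config, rejecting unknown keys."""
    if path is None:
        return {}
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_manifest(outdir: str | Path, command: str, params: dict) -> Path:
    """Echo the fully resolved configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "run_manifest.json"
    payload = {"command": command, "parameters": params}
    manifest.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return manifest
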