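"""Persistence of run results: results JSON, samples NPZ + CSV, manifest."""

from __future__ import annotations

import dataclasses
import json
import os
from importlib.metadata import PackageNotFoundError, version
from typing import Optional

import numpy as np

from .driver import ApproximationResult
from .errors import InvalidArgumentError

__all__ = ["results_to_dict", "write_results", "load_results", "make_manifest"]


def _pkg_version() -> str:
    try:
        return version("cicfit")
    except PackageNotFoundError:
        return "unknown"


def results_to_dict(result: ApproximationResult) -> dict:
    """JSON-ready summary of an approximation run."""
    return {
        "selected_params": result.selected_params.to_dict(),
        "rho_trajectory": [float(v) for v in result.rho_trajectory],
        "rho_final": float(result.rho_final),
        "rho_final_stderr": float(result.rho_final_stderr),
        "stages": [
            {
                "t": rep.t,
                "selected_k": rep.selected_k,
                "cic_by_k": {str(k): float(v) for k, v in rep.cic_by_k.items()},
                "rho_hat": float(rep.rho_estimate),
                "ess": [float(e) for e in rep.ess_per_stage],
            }
            for rep in result.reports
        ],
        "r_evaluations": int(result.r_evaluations),
        "seed": int(result.seed),
    }


def make_manifest(config_echo: dict, seed: int, result: ApproximationResult, paths: dict) -> dict:
    return {
        "package_version": _pkg_version(),
        "seed": int(seed),
        "config": config_echo,
        "stage_summaries": [
            {"t": rep.t, "selected_k": rep.selected_k, "rho_hat": float(rep.rho_estimate)}
            for rep in result.reports
        ],
        "outputs": {k: os.fspath(v) for k, v in paths.items()},
    }


def write_results(
    result: ApproximationResult,
    out_dir: "str | os.PathLike",
    config_echo: Optional[dict] = None,
) -> dict:
    """Write results.json, samples.npz, samples.csv and manifest.json under
    `out_dir`; returns the path map. JSON is written with sorted keys so
    repeated runs with the same seed are byte-identical."""
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:
        raise InvalidArgumentError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths = {
        "results": os.path.join(out_dir, "results.json"),
        "samples_npz": os.path.join(out_dir, "samples.npz"),
        "samples_csv": os.path.join(out_dir, "samples.csv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    with open(paths["results"], "w") as fh:
        json.dump(results_to_dict(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.archive.to_npz(paths["samples_npz"])
    result.archive.to_csv(paths["samples_csv"])
    manifest = make_manifest(config_echo or {}, result.seed, result, paths)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def load_results(path: "str | os.PathLike") -> dict:
    with open(path, "r") as fh:
        return json.load(fh)
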