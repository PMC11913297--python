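"""Run configuration: YAML/JSON schema, defaults, validation.

A run is described by a small mapping with a required ``target`` section and
optional overrides of the sampling schedule, component grid, EM settings and
initial proposal. Unknown keys anywhere are rejected by name, so typos fail
loudly instead of silently running with a default.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np
import yaml

from .driver import RunConfig
from .em import EMOptions
from .errors import CicFitError, ConfigError
from .model_space import GaussianMixtureParams
from .targets import UnnormalizedTarget, build_target

__all__ = ["parse_config", "DEFAULTS"]

DEFAULTS = {
    "tau": 7,
    "n_initial": 1000,
    "n_stage": 1000,
    "k_grid": list(range(1, 11)),
    "cumulative": True,
    "seed": 0,
}

_TOP_KEYS = {"target", "tau", "n_initial", "n_stage", "k_grid", "cumulative", "seed",
             "em", "initial"}
_EM_KEYS = {"max_iters", "rel_tol", "n_restarts", "eps_cov"}
_INITIAL_KEYS = {"mean", "cov_scale", "cov"}


def _initial_proposal(section: dict, p: int) -> GaussianMixtureParams:
    """Single wide Gaussian unless the config pins one down. The default
    N(0, 5^2 I) is a deliberately broad pilot proposal intended to cover the
    support of typical standardized targets."""
    unknown = set(section) - _INITIAL_KEYS
    if unknown:
        raise ConfigError(f"unknown key in 'initial': {sorted(unknown)[0]!r}")
    mean = np.asarray(section.get("mean", np.zeros(p)), dtype=float)
    if mean.shape != (p,):
        raise ConfigError(f"'initial.mean' must have length {p}")
    if "cov" in section:
        cov = np.asarray(section["cov"], dtype=float)
    else:
        cov = float(section.get("cov_scale", 5.0)) ** 2 * np.eye(p)
    try:
        return GaussianMixtureParams.single(mean, cov)
    except CicFitError as exc:
        raise ConfigError(f"invalid initial proposal: {exc}") from exc


def parse_config(source: "str | os.PathLike") -> Tuple[RunConfig, UnnormalizedTarget]:
    """Parse a YAML/JSON config (path or literal text) into a validated
    ``(RunConfig, target)`` pair with defaults filled in."""
    text = source
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source, "r") as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]!r}")
    if "target" not in raw:
        raise ConfigError("config key 'target' is required")

    try:
        target = build_target(raw["target"])
    except (CicFitError, KeyError, TypeError) as exc:
        raise ConfigError(f"invalid 'target' section: {exc}") from exc

    em_section = raw.get("em", {})
    unknown = set(em_section) - _EM_KEYS
    if unknown:
        raise ConfigError(f"unknown key in 'em': {sorted(unknown)[0]!r}")
    try:
        em = EMOptions(**em_section)
    except CicFitError as exc:
        raise ConfigError(f"invalid 'em' section: {exc}") from exc

    merged = {**DEFAULTS, **{k: v for k, v in raw.items() if k in DEFAULTS}}
    initial = _initial_proposal(raw.get("initial", {}), target.p)
    try:
        config = RunConfig(
            tau=merged["tau"],
            n_initial=merged["n_initial"],
            n_stage=merged["n_stage"],
            initial_params=initial,
            k_grid=merged["k_grid"],
            cumulative=bool(merged["cumulative"]),
            seed=int(merged["seed"]),
            em_options=em,
        )
    except CicFitError as exc:
        raise ConfigError(str(exc)) from exc
    return config, target
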