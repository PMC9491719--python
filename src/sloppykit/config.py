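"""Run configuration: strict YAML parsing and lossless round-tripping.

A run config declares the model, the data source (a CSV file or a seeded
generator spec), the prior, sampler/finite-difference settings, which
sensitivity matrices to build, and the output directory.  Unknown keys are
rejected so that typos fail loudly rather than silently using defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .inference import SMCSettings
from .priors import LogNormalComponent, MultivariateLogNormalBlock, Prior, UniformComponent
from .sensitivity import FDConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "build_prior"]

_MATRIX_KINDS = ("H", "L", "P", "G", "K")


class ConfigError(ValueError):
    """A configuration problem, reported with the path to the offending key."""


def _reject_unknown(d: dict, allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def build_prior(spec: list[dict], path: str = "prior") -> Prior:
    comps = []
    for i, c in enumerate(spec):
        here = f"{path}[{i}]"
        if not isinstance(c, dict) or "dist" not in c:
            raise ConfigError(f"{here}: each prior component needs a 'dist' key")
        dist = c["dist"]
        if dist == "uniform":
            _reject_unknown(c, {"dist", "name", "lo", "hi"}, here)
            try:
                comps.append(UniformComponent(c["name"], float(c["lo"]), float(c["hi"])))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"{here}: {exc}") from exc
        elif dist == "lognormal":
            _reject_unknown(c, {"dist", "name", "mu_log", "sigma_log"}, here)
            try:
                comps.append(LogNormalComponent(c["name"], float(c["mu_log"]), float(c["sigma_log"])))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"{here}: {exc}") from exc
        elif dist == "mvlognormal":
            _reject_unknown(c, {"dist", "names", "mu_log", "cov_log"}, here)
            try:
                comps.append(
                    MultivariateLogNormalBlock(
                        list(c["names"]), np.asarray(c["mu_log"], float), np.asarray(c["cov_log"], float)
                    )
                )
            except (KeyError, ValueError, np.linalg.LinAlgError) as exc:
                raise ConfigError(f"{here}: {exc}") from exc
        else:
            raise ConfigError(f"{here}.dist: unknown distribution {dist!r}")
    try:
        return Prior(comps)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    """Parsed, validated run configuration."""

    model: str
    prior_spec: list[dict]
    data: dict[str, Any]
    smc: SMCSettings = SMCSettings()
    fd: FDConfig = FDConfig()
    matrices: tuple[str, ...] = ("H", "L", "P", "G")
    nuisance: tuple[str, ...] = ()
    threshold: float = 0.2
    similar_threshold: float = 0.9
    theta_init: dict[str, float] | None = None  # None -> posterior mean
    output_dir: str = "sloppykit_out"
    plugin_path: str | None = None
    raw: dict = field(default_factory=dict, compare=False)

    @property
    def prior(self) -> Prior:
        return build_prior(self.prior_spec)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "model": self.model,
            "prior": self.prior_spec,
            "data": self.data,
            "smc": {
                "M": self.smc.M,
                "mh_acceptance_target": self.smc.mh_acceptance_target,
                "ess_reduction": self.smc.ess_reduction,
                "seed": self.smc.seed,
            },
            "fd": {"delta": self.fd.delta},
            "matrices": list(self.matrices),
            "nuisance": list(self.nuisance),
            "threshold": self.threshold,
            "similar_threshold": self.similar_threshold,
            "output_dir": self.output_dir,
        }
        if self.theta_init is not None:
            d["theta_init"] = self.theta_init
        if self.plugin_path is not None:
            d["plugin_path"] = self.plugin_path
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_TOP_KEYS = {
    "model", "prior", "data", "smc", "fd", "matrices", "nuisance",
    "threshold", "similar_threshold", "theta_init", "output_dir", "plugin_path",
}
_DATA_KEYS = {"file", "generator"}
_GEN_KEYS = {"kind", "eps", "sigma", "seed", "x", "theta_R", "output_index"}
_SMC_KEYS = {"M", "mh_acceptance_target", "ess_reduction", "seed"}


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("top level: config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    for key in ("model", "prior", "data"):
        if key not in raw:
            raise ConfigError(f"top level: missing required key {key!r}")

    data = raw["data"]
    if not isinstance(data, dict) or len(set(data) & _DATA_KEYS) != 1:
        raise ConfigError("data: exactly one of 'file' or 'generator' is required")
    _reject_unknown(data, _DATA_KEYS, "data")
    if "generator" in data:
        gen = data["generator"]
        _reject_unknown(gen, _GEN_KEYS, "data.generator")
        kind = gen.get("kind")
        if kind not in ("heteroscedastic", "homoscedastic"):
            raise ConfigError(f"data.generator.kind: expected heteroscedastic|homoscedastic, got {kind!r}")
        if kind == "heteroscedastic":
            if "eps" not in gen or not 0.0 < float(gen["eps"]) < 1.0:
                raise ConfigError("data.generator.eps: required, in (0, 1) for heteroscedastic noise")
        else:
            if "sigma" not in gen or not float(gen["sigma"]) > 0:
                raise ConfigError("data.generator.sigma: required, > 0 for homoscedastic noise")
        if "seed" not in gen:
            raise ConfigError("data.generator.seed: required for reproducibility")
        if "x" not in gen:
            raise ConfigError("data.generator.x: required (list of input conditions)")

    smc_raw = dict(raw.get("smc", {}))
    _reject_unknown(smc_raw, _SMC_KEYS, "smc")
    try:
        smc = SMCSettings(
            M=int(smc_raw.get("M", 10_000)),
            mh_acceptance_target=float(smc_raw.get("mh_acceptance_target", 0.95)),
            ess_reduction=float(smc_raw.get("ess_reduction", 0.001)),
            seed=int(smc_raw.get("seed", 0)),
        )
    except ValueError as exc:
        raise ConfigError(f"smc: {exc}") from exc

    fd_raw = dict(raw.get("fd", {}))
    _reject_unknown(fd_raw, {"delta"}, "fd")
    try:
        fd = FDConfig(delta=float(fd_raw.get("delta", 1e-3)))
    except ValueError as exc:
        raise ConfigError(f"fd.delta: {exc}") from exc

    matrices = tuple(raw.get("matrices", ["H", "L", "P", "G"]))
    bad = [m for m in matrices if m not in _MATRIX_KINDS]
    if bad:
        raise ConfigError(f"matrices: unknown kind(s) {bad}; allowed {_MATRIX_KINDS}")

    prior_spec = raw["prior"]
    build_prior(prior_spec)  # validate now

    cfg = RunConfig(
        model=str(raw["model"]),
        prior_spec=prior_spec,
        data=data,
        smc=smc,
        fd=fd,
        matrices=matrices,
        nuisance=tuple(raw.get("nuisance", [])),
        threshold=float(raw.get("threshold", 0.2)),
        similar_threshold=float(raw.get("similar_threshold", 0.9)),
        theta_init=raw.get("theta_init"),
        output_dir=str(raw.get("output_dir", "sloppykit_out")),
        plugin_path=raw.get("plugin_path"),
        raw=raw,
    )
    return cfg


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return parse_config(raw)
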