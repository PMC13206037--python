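"""Pipeline configuration: one YAML-serializable object, one master seed.

Every stochastic component (generator streams, estimator jitter, surrogate
permutations) derives its sub-seed deterministically from the master seed,
and the resolved configuration is embedded in each stage's run manifest, so
a rerun with the same file reproduces identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .estimators import EstimatorConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # synthetic community
    generations: int = 3
    frames_per_generation: int = 9000
    regimes_by_generation: dict[int, str] = field(default_factory=dict)
    default_regime: str = "coupled"
    # estimation
    k: int = 8
    lag: int = 1
    jitter_scale: float = 1e-10
    stride: int = 1
    # surrogates
    n_perm: int = 50
    surrogate_method: str = "permutation"
    # phases / windows / histograms
    window_samples: int = 3000
    n_bins: int = 50
    # coarse-graining sweep
    blocks: tuple[int, ...] = (1, 5, 10, 20, 50)
    phases: tuple[str, ...] = ("early", "middle", "last")

    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(
            k=self.k, lag=self.lag, jitter_scale=self.jitter_scale, seed=self.seed
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = list(self.blocks)
        d["phases"] = list(self.phases)
        d["regimes_by_generation"] = {
            str(k): v for k, v in self.regimes_by_generation.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "blocks" in d:
            d["blocks"] = tuple(d["blocks"])
        if "phases" in d:
            d["phases"] = tuple(d["phases"])
        if "regimes_by_generation" in d and d["regimes_by_generation"]:
            d["regimes_by_generation"] = {
                int(k): v for k, v in d["regimes_by_generation"].items()
            }
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def manifest(self, stage: str, extra: dict | None = None) -> dict:
        from . import __version__

        m = {"stage": stage, "nticell_version": __version__, "config": self.to_dict()}
        if extra:
            m.update(extra)
        return m

    def write_manifest(self, outdir: str | Path, stage: str, extra: dict | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"manifest_{stage}.json").write_text(
            json.dumps(self.manifest(stage, extra), indent=2, default=str)
        )
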