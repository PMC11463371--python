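"""Run configuration: preprocessing and core parameters, YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning chain.

    spatial_quantile : fraction in (0, 1)
        Quantile of each between-marker distance distribution above
        which a point is flagged spatially incoherent (default 0.92).
    spatial_mode : "per_pair" | "pooled"
        Whether the distance distribution (and threshold) is computed
        per marker pair or pooled over all pairs.
    residual_k : float
        Temporal outliers are smoother residuals with |r| > residual_k
        x robust sigma (scaled MAD of the residuals).
    n_out : int
        Number of time-normalized samples per trial (1% steps -> 100).
    min_likelihood : float | None
        If set, tracker points with likelihood below this are treated
        as missing before cleaning.  Off by default.
    include_markers / exclude_markers
        Optional marker selection applied before building X_i.
    """

    spatial_quantile: float = 0.92
    spatial_mode: str = "per_pair"
    residual_k: float = 3.0
    n_out: int = 100
    min_likelihood: float | None = None
    include_markers: list[str] | None = None
    exclude_markers: list[str] | None = None
    smoother_bass: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.spatial_quantile < 1.0):
            raise ParameterError(
                f"spatial_quantile must be in (0, 1), got {self.spatial_quantile}"
            )
        if self.spatial_mode not in ("per_pair", "pooled"):
            raise ParameterError(f"spatial_mode must be per_pair or pooled, got {self.spatial_mode!r}")
        if self.residual_k <= 0:
            raise ParameterError("residual_k must be > 0")
        if self.n_out < 2:
            raise ParameterError(f"n_out must be >= 2, got {self.n_out}")
        if self.min_likelihood is not None and not (0.0 <= self.min_likelihood <= 1.0):
            raise ParameterError("min_likelihood must be in [0, 1]")


@dataclass
class CoreConfig:
    """Parameters of the KDI computation itself.

    n_components : int
        Retained principal components J (default 3).
    scaling : "zscore" | "center_only"
        Column standardization before each trial's PCA.
    gpa_tol / gpa_max_iter
        Convergence tolerance and iteration cap of the generalized
        Procrustes consensus.
    derived_variables : bool
        If True, digit span and paw angle are appended to X_i
        (requires >= 2 digit markers); off by default.
    """

    n_components: int = 3
    scaling: str = "zscore"
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    derived_variables: bool = False

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")
        if self.scaling not in ("zscore", "center_only"):
            raise ParameterError(f"scaling must be zscore or center_only, got {self.scaling!r}")
        if self.gpa_tol <= 0 or self.gpa_max_iter < 1:
            raise ParameterError("gpa_tol must be > 0 and gpa_max_iter >= 1")


@dataclass
class RunConfig:
    """Full pipeline configuration (also the YAML file schema)."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    core: CoreConfig = field(default_factory=CoreConfig)
    strict: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pp = d.pop("preprocess", {}) or {}
        core = d.pop("core", {}) or {}
        return cls(
            preprocess=PreprocessConfig(**pp),
            core=CoreConfig(**core),
            **{k: v for k, v in d.items() if k in ("strict", "seed", "log_level")},
        )

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def run_record(self) -> dict:
        """Machine-readable record of every parameter in effect, plus a hash."""
        d = self.to_dict()
        digest = hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
        return {"parameters": d, "config_hash": digest}
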