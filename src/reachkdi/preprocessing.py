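"""Trial cleaning: spatial outliers, temporal smoothing, time normalization.

The chain runs in a fixed order on each trial:

1. spatial coherence — per frame, Euclidean distances between marker
   pairs; points whose distances exceed the 0.92 quantile of the
   pair's distance distribution for a strict majority of their pairs
   are removed (set missing);
2. temporal coherence — a supersmoother fit per marker and coordinate;
   observations with large residuals (> residual_k x robust sigma) are
   replaced by the fitted value, and all missing points are imputed
   from the fit;
3. time normalization — every variable linearly interpolated onto 100
   equally spaced samples spanning the trial, each sample representing
   1% of trial duration.

The output is the trial's X_i matrix (100 x p, no missing values) used
by the KDI core, plus a per-trial cleaning report for audit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PreprocessConfig
from .errors import (
    DegenerateInputError,
    ParameterError,
    SchemaError,
    UnrecoverableTraceError,
)
from .io import RawTrial
from .smoothing import predict_at, supersmoother

logger = logging.getLogger(__name__)


@dataclass
class CleaningReport:
    """Audit trail of the cleaning chain for exactly one trial."""

    trial_id: str
    n_spatial_flagged: dict[str, int] = field(default_factory=dict)
    n_temporal_replaced: dict[tuple[str, str], int] = field(default_factory=dict)
    n_imputed: int = 0
    quantile_threshold_used: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def total_spatial_flagged(self) -> int:
        return sum(self.n_spatial_flagged.values())

    @property
    def total_temporal_replaced(self) -> int:
        return sum(self.n_temporal_replaced.values())

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        if other.trial_id != self.trial_id:
            raise ValueError("cannot merge reports from different trials")
        merged = CleaningReport(trial_id=self.trial_id)
        for src in (self, other):
            for k, v in src.n_spatial_flagged.items():
                merged.n_spatial_flagged[k] = merged.n_spatial_flagged.get(k, 0) + v
            for k, v in src.n_temporal_replaced.items():
                merged.n_temporal_replaced[k] = merged.n_temporal_replaced.get(k, 0) + v
            merged.n_imputed += src.n_imputed
            merged.quantile_threshold_used.update(src.quantile_threshold_used)
        return merged

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per recorded count or threshold."""
        rows = []
        for m, v in self.n_spatial_flagged.items():
            rows.append((self.trial_id, "spatial_flagged", m, "", float(v)))
        for (m, c), v in self.n_temporal_replaced.items():
            rows.append((self.trial_id, "temporal_replaced", m, c, float(v)))
        rows.append((self.trial_id, "imputed", "", "", float(self.n_imputed)))
        for (a, b), v in self.quantile_threshold_used.items():
            rows.append((self.trial_id, "pair_threshold_px", a, b, float(v)))
        return pd.DataFrame(
            rows, columns=["trial_id", "quantity", "marker", "detail", "value"]
        )


@dataclass
class NormalizedTrial:
    """The trial's X_i: 100 x p matrix of time-normalized variables.

    Rows run from trial start (row 0) to trial end; columns are x and y
    per included marker (plus optional derived variables), named in
    ``variable_names``.
    """

    matrix: np.ndarray
    variable_names: list[str]
    trial_id: str
    animal_id: str
    condition: str
    endpoint: str
    original_n_frames: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise SchemaError("NormalizedTrial matrix must be 2-D")
        if self.matrix.shape[1] != len(self.variable_names):
            raise SchemaError("variable_names must match matrix columns")
        if np.isnan(self.matrix).any():
            raise SchemaError("NormalizedTrial must have no missing values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.variable_names)
        df.index = pd.RangeIndex(1, self.n_samples + 1, name="n")
        return df


def apply_likelihood_mask(trial: RawTrial, min_likelihood: float) -> RawTrial:
    """Set points with tracker confidence below ``min_likelihood`` missing."""
    out = trial.copy()
    if trial.likelihood is None:
        logger.warning("trial %s: no likelihood column; mask skipped", trial.trial_id)
        return out
    low = trial.likelihood < min_likelihood
    out.xy[low] = np.nan
    return out


def select_markers(
    trial: RawTrial,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> RawTrial:
    """Restrict a trial to a subset of markers, preserving order."""
    keep = [
        m for m in trial.marker_names
        if (include is None or m in include) and (exclude is None or m not in exclude)
    ]
    if not keep:
        raise SchemaError(f"trial {trial.trial_id!r}: marker selection removed all markers")
    idx = [trial.marker_names.index(m) for m in keep]
    out = trial.copy()
    out.marker_names = keep
    out.xy = out.xy[:, idx, :]
    if out.likelihood is not None:
        out.likelihood = out.likelihood[:, idx]
    return out


def flag_spatial_outliers(
    trial: RawTrial,
    quantile: float = 0.92,
    mode: str = "per_pair",
    min_joint_frames: int = 10,
) -> tuple[RawTrial, CleaningReport]:
    """Remove spatially incoherent points via between-marker distances.

    For each marker pair the per-frame Euclidean distance is computed;
    the distribution of those distances over all frames yields a
    threshold at ``quantile`` (per pair by default, or pooled over all
    pairs with ``mode="pooled"``).  A point is set missing when its
    distance exceeds the threshold for a strict majority of that
    marker's pairs in that frame — attributing the incoherence to the
    single displaced marker rather than to both members of every pair.
    """
    if not (0.0 < quantile < 1.0):
        raise ParameterError(f"quantile must be in (0, 1), got {quantile}")
    if mode not in ("per_pair", "pooled"):
        raise ParameterError(f"mode must be per_pair or pooled, got {mode!r}")

    report = CleaningReport(trial_id=trial.trial_id)
    out = trial.copy()
    m = trial.n_markers
    if m < 2:
        logger.warning(
            "trial %s: single marker, spatial outlier step skipped", trial.trial_id
        )
        return out, report

    pairs = list(itertools.combinations(range(m), 2))
    n = trial.n_frames
    dist = np.full((n, len(pairs)), np.nan)
    for k, (a, b) in enumerate(pairs):
        d = trial.xy[:, a, :] - trial.xy[:, b, :]
        dist[:, k] = np.sqrt(np.sum(d * d, axis=1))

    usable = np.zeros(len(pairs), dtype=bool)
    thresholds = np.full(len(pairs), np.inf)
    joint = (~np.isnan(dist)).sum(axis=0)
    usable = joint >= min_joint_frames
    for k in np.flatnonzero(~usable):
        a, b = pairs[k]
        logger.warning(
            "trial %s: pair (%s, %s) has %d jointly observed frames (< %d); pair skipped",
            trial.trial_id, trial.marker_names[a], trial.marker_names[b], joint[k],
            min_joint_frames,
        )
    if mode == "pooled":
        pooled = dist[:, usable]
        pooled = pooled[~np.isnan(pooled)]
        thr = np.quantile(pooled, quantile) if pooled.size else np.inf
        thresholds[usable] = thr
    else:
        for k in np.flatnonzero(usable):
            thresholds[k] = np.nanquantile(dist[:, k], quantile)
    for k in np.flatnonzero(usable):
        a, b = pairs[k]
        report.quantile_threshold_used[
            (trial.marker_names[a], trial.marker_names[b])
        ] = float(thresholds[k])

    # violations per marker per frame vs. number of observable pairs
    viol = np.zeros((n, m), dtype=int)
    nobs = np.zeros((n, m), dtype=int)
    for k in np.flatnonzero(usable):
        a, b = pairs[k]
        observed = ~np.isnan(dist[:, k])
        exceeded = observed & (dist[:, k] > thresholds[k])
        for marker in (a, b):
            nobs[observed, marker] += 1
            viol[exceeded, marker] += 1
    flagged = viol * 2 > nobs  # strict majority
    flagged &= nobs > 0

    for marker in range(m):
        count = int(flagged[:, marker].sum())
        if count:
            report.n_spatial_flagged[trial.marker_names[marker]] = count
            out.xy[flagged[:, marker], marker, :] = np.nan
    return out, report


def smooth_impute(
    trial: RawTrial,
    residual_k: float = 3.0,
    bass: float = 0.0,
) -> tuple[RawTrial, CleaningReport]:
    """Supersmoother-based temporal cleaning and imputation.

    Per marker and coordinate, a supersmoother is fit to the observed
    trace against frame index.  Observations whose residual exceeds
    ``residual_k`` x robust sigma (1.4826 x MAD of the residuals) are
    replaced by the fitted value; all missing points (original or
    spatially flagged) are imputed from the fit.  Traces with fewer
    than 10 observed points fall back to linear interpolation.
    """
    if residual_k <= 0:
        raise ParameterError("residual_k must be > 0")
    report = CleaningReport(trial_id=trial.trial_id)
    out = trial.copy()
    frames = trial.frames
    for marker in range(trial.n_markers):
        name = trial.marker_names[marker]
        for ci, coord in enumerate("xy"):
            y = trial.xy[:, marker, ci]
            obs = ~np.isnan(y)
            n_obs = int(obs.sum())
            n_missing = int((~obs).sum())
            if n_obs == 0:
                raise UnrecoverableTraceError(
                    f"trial {trial.trial_id!r}: trace {name}/{coord} has no observed points"
                )
            if n_obs < 10:
                logger.warning(
                    "trial %s: trace %s/%s has %d observed points; linear fallback",
                    trial.trial_id, name, coord, n_obs,
                )
                out.xy[:, marker, ci] = np.interp(frames, frames[obs], y[obs])
                report.n_imputed += n_missing
                continue
            fit = supersmoother(frames[obs], y[obs], bass=bass)
            resid = y[obs] - fit
            mad = np.median(np.abs(resid - np.median(resid)))
            sigma = 1.4826 * mad
            # absolute floor so a noiseless trace never self-flags
            scale = max(float(np.ptp(y[obs])), 1.0)
            threshold = max(residual_k * sigma, 1e-7 * scale)
            large = np.abs(resid) > threshold
            obs_idx = np.flatnonzero(obs)
            if large.any() and (~large).sum() >= 10:
                # refit without the outliers so the replacement value is
                # not biased by the very points being replaced
                keep = obs_idx[~large]
                refit = supersmoother(frames[keep], y[keep], bass=bass)
                expected = predict_at(frames[keep], refit, frames)
            else:
                expected = predict_at(frames[obs], fit, frames)
            cleaned = y.copy()
            cleaned[obs_idx[large]] = expected[obs_idx[large]]
            if n_missing:
                cleaned[~obs] = expected[~obs]
            out.xy[:, marker, ci] = cleaned
            if large.any():
                report.n_temporal_replaced[(name, coord)] = int(large.sum())
            report.n_imputed += n_missing
    return out, report


def time_normalize(trial: RawTrial, n_out: int = 100) -> NormalizedTrial:
    """Linearly interpolate each variable onto ``n_out`` equally spaced
    samples spanning [first frame, last frame]; each sample represents
    1/(n_out-1) of the trial duration and the endpoints are preserved
    exactly.  The trial must be fully observed.
    """
    if n_out < 2:
        raise ParameterError(f"n_out must be >= 2, got {n_out}")
    if np.isnan(trial.xy).any():
        raise DegenerateInputError(
            f"trial {trial.trial_id!r}: time_normalize requires a fully observed trial"
        )
    grid = np.linspace(trial.frames[0], trial.frames[-1], n_out)
    names: list[str] = []
    cols: list[np.ndarray] = []
    for marker in range(trial.n_markers):
        for ci, coord in enumerate("xy"):
            names.append(f"{trial.marker_names[marker]}_{coord}")
            cols.append(np.interp(grid, trial.frames, trial.xy[:, marker, ci]))
    matrix = np.column_stack(cols)
    # endpoint preservation, exact by construction of the grid
    matrix[0] = trial.xy[0].reshape(-1)
    matrix[-1] = trial.xy[-1].reshape(-1)
    return NormalizedTrial(
        matrix=matrix,
        variable_names=names,
        trial_id=trial.trial_id,
        animal_id=trial.animal_id,
        condition=trial.condition,
        endpoint=trial.endpoint,
        original_n_frames=trial.n_frames,
    )


def _append_derived_variables(nt: NormalizedTrial) -> NormalizedTrial:
    """Append digit span and paw angle columns, computed from the first
    and last digit markers on the normalized grid."""
    digits = sorted({v.rsplit("_", 1)[0] for v in nt.variable_names if v.startswith("digit")})
    if len(digits) < 2:
        raise SchemaError("derived variables need >= 2 digit markers")
    first, last = digits[0], digits[-1]
    cols = {v: i for i, v in enumerate(nt.variable_names)}
    dx = nt.matrix[:, cols[f"{last}_x"]] - nt.matrix[:, cols[f"{first}_x"]]
    dy = nt.matrix[:, cols[f"{last}_y"]] - nt.matrix[:, cols[f"{first}_y"]]
    span = np.hypot(dx, dy)
    angle = np.arctan2(dy, dx)
    return NormalizedTrial(
        matrix=np.column_stack([nt.matrix, span, angle]),
        variable_names=nt.variable_names + ["digit_span", "paw_angle"],
        trial_id=nt.trial_id,
        animal_id=nt.animal_id,
        condition=nt.condition,
        endpoint=nt.endpoint,
        original_n_frames=nt.original_n_frames,
    )


def preprocess_trial(
    trial: RawTrial,
    config: PreprocessConfig | None = None,
    derived_variables: bool = False,
) -> tuple[NormalizedTrial, CleaningReport]:
    """Full cleaning chain: spatial -> temporal -> time normalization."""
    config = config or PreprocessConfig()
    work = trial
    if config.include_markers is not None or config.exclude_markers is not None:
        work = select_markers(work, config.include_markers, config.exclude_markers)
    if config.min_likelihood is not None:
        work = apply_likelihood_mask(work, config.min_likelihood)
    work, spatial_report = flag_spatial_outliers(
        work, quantile=config.spatial_quantile, mode=config.spatial_mode
    )
    work, temporal_report = smooth_impute(
        work, residual_k=config.residual_k, bass=config.smoother_bass
    )
    normalized = time_normalize(work, n_out=config.n_out)
    if derived_variables:
        normalized = _append_derived_variables(normalized)
    return normalized, spatial_report.merge(temporal_report)
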