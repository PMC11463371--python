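"""Kinematic Deviation Index: per-trial PCA, Procrustes alignment, scoring.

Each time-normalized trial matrix X_i (100 x p) is embedded by its own
PCA.  The loadings of the first J (default 3) components of an animal's
successful baseline trials are aligned by Generalized Procrustes
Analysis; the consensus of that alignment, together with the mean of
the rotated baseline score trajectories, forms the subject-specific
kinematic performance reference.  Any trial is then scored by rotating
its loadings toward the consensus (orthogonal Procrustes), projecting
X_i through the rotated loadings to get rotated object scores, and
measuring the per-sample Euclidean distance to the reference
trajectory:

    d_n = || S[n, :] - ref[n, :] ||_2         (KD-trajectory)
    KDI = sum_{n=1}^{100} d_n

KDI is unitless, non-negative, and zero only when a trial reproduces
its reference trajectory exactly.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import svd

from .config import CoreConfig, RunConfig
from .errors import (
    DegenerateGeometryError,
    DimensionalityError,
    ParameterError,
    ReferenceUnavailableError,
    SchemaError,
)
from .io import TrialManifest, load_trial, read_matrix, write_matrix
from .preprocessing import CleaningReport, NormalizedTrial, preprocess_trial

logger = logging.getLogger(__name__)


@dataclass
class TrialEmbedding:
    """Per-trial PCA result.

    ``loadings`` (p x J) are the top right singular vectors with a
    deterministic sign convention (largest-magnitude entry of each
    column positive); ``scores`` (n x J) are the standardized matrix
    projected through them.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    column_centers: np.ndarray
    column_scales: np.ndarray
    trial_id: str
    animal_id: str
    condition: str = ""
    endpoint: str = ""


@dataclass
class KinematicReference:
    """Subject-specific kinematic performance reference.

    ``consensus_loadings`` is the GPA consensus over baseline-success
    trial loadings; ``reference_scores`` is the per-sample mean of the
    baseline trials' rotated score trajectories.
    """

    animal_id: str
    consensus_loadings: np.ndarray
    reference_scores: np.ndarray
    n_baseline_trials: int
    gpa_iterations: int
    gpa_residual: float
    variable_names: list[str]
    scaling: str = "zscore"

    @property
    def n_components(self) -> int:
        return self.consensus_loadings.shape[1]

    def save(self, directory: str | os.PathLike) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        jcols = [f"PC{j + 1}" for j in range(self.n_components)]
        write_matrix(
            pd.DataFrame(self.consensus_loadings, index=self.variable_names, columns=jcols),
            d / f"{self.animal_id}_consensus_loadings.csv",
        )
        write_matrix(
            pd.DataFrame(
                self.reference_scores,
                index=pd.RangeIndex(1, len(self.reference_scores) + 1, name="n"),
                columns=jcols,
            ),
            d / f"{self.animal_id}_reference_scores.csv",
        )
        meta = {
            "animal_id": self.animal_id,
            "n_components": self.n_components,
            "scaling": self.scaling,
            "n_baseline_trials": self.n_baseline_trials,
            "gpa_iterations": self.gpa_iterations,
            "gpa_residual": self.gpa_residual,
        }
        (d / f"{self.animal_id}_reference.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | os.PathLike, animal_id: str) -> "KinematicReference":
        d = Path(directory)
        meta = json.loads((d / f"{animal_id}_reference.json").read_text())
        loadings = read_matrix(d / f"{animal_id}_consensus_loadings.csv")
        scores = read_matrix(d / f"{animal_id}_reference_scores.csv")
        return cls(
            animal_id=animal_id,
            consensus_loadings=loadings.to_numpy(),
            reference_scores=scores.to_numpy(),
            n_baseline_trials=meta["n_baseline_trials"],
            gpa_iterations=meta["gpa_iterations"],
            gpa_residual=meta["gpa_residual"],
            variable_names=list(loadings.index),
            scaling=meta["scaling"],
        )


@dataclass
class KDIResult:
    """KD-trajectory and scalar KDI for one trial."""

    trial_id: str
    animal_id: str
    condition: str
    endpoint: str
    kd_trajectory: np.ndarray
    kdi: float
    rotation_used: np.ndarray = field(repr=False, default=None)


def _standardize(matrix: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = matrix.mean(axis=0)
    if scaling == "zscore":
        scales = matrix.std(axis=0)
        scales = np.where(scales < 1e-12, 1.0, scales)
    elif scaling == "center_only":
        scales = np.ones(matrix.shape[1])
    else:
        raise ParameterError(f"unknown scaling {scaling!r}")
    return (matrix - centers) / scales, centers, scales


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry of each
    loading column is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def embed_trial(
    trial: NormalizedTrial,
    n_components: int = 3,
    scaling: str = "zscore",
) -> TrialEmbedding:
    """PCA of a single trial matrix, performed on that trial alone.

    Columns are centered (and scaled to unit variance under
    ``zscore``; constant columns get scale 1), the SVD is taken, and
    the top ``n_components`` right singular vectors become the
    loadings.  Scores are the standardized matrix times the loadings.
    """
    if trial.p < n_components:
        raise DimensionalityError(
            f"trial {trial.trial_id!r}: p={trial.p} < n_components={n_components}"
        )
    Z, centers, scales = _standardize(trial.matrix, scaling)
    _, s, vt = svd(Z, full_matrices=False)
    total = float(np.sum(s**2))
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if rank < n_components:
        logger.warning(
            "trial %s: rank %d < %d components; trailing components have zero variance",
            trial.trial_id, rank, n_components,
        )
    loadings = _fix_signs(vt[:n_components].T)
    scores = Z @ loadings
    ev = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    return TrialEmbedding(
        loadings=loadings,
        scores=scores,
        explained_variance=ev,
        column_centers=centers,
        column_scales=scales,
        trial_id=trial.trial_id,
        animal_id=trial.animal_id,
        condition=trial.condition,
        endpoint=trial.endpoint,
    )


def procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal matrix R minimizing ||source @ R - target||_F.

    Reflections are allowed (full orthogonal group): PCA loading signs
    are arbitrary, so sign flips must be correctable.  Computed from
    the SVD of source.T @ target as R = U @ Vt.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise SchemaError(f"shape mismatch: {source.shape} vs {target.shape}")
    if not np.any(source) or not np.any(target):
        raise DegenerateGeometryError("zero source or target matrix")
    u, _, vt = svd(source.T @ target)
    return u @ vt


def gpa_consensus(
    loading_set: list[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
    objective_history: list[float] | None = None,
) -> tuple[np.ndarray, list[np.ndarray], int, float]:
    """Generalized Procrustes Analysis over a set of loading matrices.

    Rotation-only (no translation, no scaling): the consensus is
    initialized to the first matrix, then the algorithm alternates
    rotating every matrix toward the consensus and replacing the
    consensus with the element-wise mean of the rotated matrices,
    until the consensus changes by less than ``tol`` (Frobenius).

    Returns (consensus, per-matrix rotations, iterations, final change).
    """
    if not loading_set:
        raise ParameterError("gpa_consensus needs at least one matrix")
    shapes = {m.shape for m in loading_set}
    if len(shapes) != 1:
        raise SchemaError(f"all matrices must share one shape, got {sorted(shapes)}")
    consensus = np.array(loading_set[0], dtype=float)
    rotations = [np.eye(consensus.shape[1]) for _ in loading_set]
    change = np.inf
    iterations = 0
    prev_objective = np.inf
    for iterations in range(1, max_iter + 1):
        rotations = [procrustes_rotation(m, consensus) for m in loading_set]
        rotated = [m @ r for m, r in zip(loading_set, rotations)]
        new_consensus = np.mean(rotated, axis=0)
        objective = float(sum(np.sum((m - new_consensus) ** 2) for m in rotated))
        if objective > prev_objective + 1e-12:
            logger.warning("GPA objective increased (%.3e -> %.3e)", prev_objective, objective)
        prev_objective = objective
        if objective_history is not None:
            objective_history.append(objective)
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            break
    return consensus, rotations, iterations, change


def build_reference(
    baseline_trials: list[NormalizedTrial],
    config: CoreConfig | None = None,
) -> KinematicReference:
    """Build the subject-specific kinematic performance reference.

    Embeds every baseline-success trial, aligns the loadings by GPA,
    and averages the rotated score trajectories per sample.  The
    converged consensus (and all rotations) are finally re-oriented to
    best align with the element-wise mean of the raw loadings — a
    deterministic, order-independent anchor that pins down the global
    rotation GPA leaves free; KDI values are invariant to this choice.
    """
    config = config or CoreConfig()
    if not baseline_trials:
        raise ReferenceUnavailableError("no baseline-success trials provided")
    animals = {t.animal_id for t in baseline_trials}
    if len(animals) != 1:
        raise SchemaError(f"reference trials must come from one animal, got {sorted(animals)}")
    names = baseline_trials[0].variable_names
    for t in baseline_trials:
        if t.variable_names != names:
            raise SchemaError(
                f"trial {t.trial_id!r}: variable names differ from {baseline_trials[0].trial_id!r}"
            )
    if len(baseline_trials) < 3:
        logger.warning(
            "animal %s: only %d baseline-success trial(s); reference may be unstable",
            baseline_trials[0].animal_id, len(baseline_trials),
        )
    embeddings = [
        embed_trial(t, n_components=config.n_components, scaling=config.scaling)
        for t in baseline_trials
    ]
    loadings = [e.loadings for e in embeddings]
    consensus, rotations, iterations, residual = gpa_consensus(
        loadings, tol=config.gpa_tol, max_iter=config.gpa_max_iter
    )
    anchor = np.mean(loadings, axis=0)
    if np.any(anchor):
        g = procrustes_rotation(consensus, anchor)
        consensus = consensus @ g
        rotations = [r @ g for r in rotations]
    rotated_scores = [e.scores @ r for e, r in zip(embeddings, rotations)]
    reference_scores = np.mean(rotated_scores, axis=0)
    return KinematicReference(
        animal_id=baseline_trials[0].animal_id,
        consensus_loadings=consensus,
        reference_scores=reference_scores,
        n_baseline_trials=len(baseline_trials),
        gpa_iterations=iterations,
        gpa_residual=residual,
        variable_names=list(names),
        scaling=config.scaling,
    )


def score_trial(
    trial: NormalizedTrial,
    reference: KinematicReference,
    config: CoreConfig | None = None,
) -> KDIResult:
    """Score one trial against a subject-specific reference.

    The trial is embedded by its own PCA (its own centers and scales),
    its loadings are rotated toward the consensus, and the rotated
    object scores are compared to the reference trajectory sample by
    sample.  The KDI is the plain left-to-right sum of the
    KD-trajectory.
    """
    config = config or CoreConfig()
    if trial.variable_names != reference.variable_names:
        raise SchemaError(
            f"trial {trial.trial_id!r}: variables do not match reference of "
            f"animal {reference.animal_id!r}"
        )
    if config.n_components != reference.n_components:
        raise DimensionalityError(
            f"configured J={config.n_components} but reference has J={reference.n_components}"
        )
    embedding = embed_trial(trial, n_components=config.n_components, scaling=config.scaling)
    rotation = procrustes_rotation(embedding.loadings, reference.consensus_loadings)
    rotated_scores = embedding.scores @ rotation
    if rotated_scores.shape != reference.reference_scores.shape:
        raise SchemaError(
            f"trial {trial.trial_id!r}: score trajectory shape {rotated_scores.shape} "
            f"does not match reference {reference.reference_scores.shape}"
        )
    diff = rotated_scores - reference.reference_scores
    kd_trajectory = np.sqrt(np.sum(diff * diff, axis=1))
    kdi = 0.0
    for value in kd_trajectory:  # accumulate in trajectory order n = 1..100
        kdi += float(value)
    return KDIResult(
        trial_id=trial.trial_id,
        animal_id=trial.animal_id,
        condition=trial.condition,
        endpoint=trial.endpoint,
        kd_trajectory=kd_trajectory,
        kdi=kdi,
        rotation_used=rotation,
    )


def build_cohort_references(
    normalized: dict[str, list[NormalizedTrial]],
    flags: dict[tuple[str, str], bool],
    config: CoreConfig,
    strict: bool = False,
) -> dict[str, KinematicReference]:
    """One reference per animal from its baseline-success trials.

    ``flags[(animal_id, trial_id)]`` marks baseline successes.  Animals
    without any are skipped with a logged error (or raise under
    ``strict``).
    """
    references: dict[str, KinematicReference] = {}
    for animal_id, trials in normalized.items():
        baseline = [t for t in trials if flags.get((animal_id, t.trial_id), False)]
        if not baseline:
            msg = f"animal {animal_id!r}: no baseline-success trials; cannot build reference"
            if strict:
                raise ReferenceUnavailableError(msg)
            logger.error("%s; animal skipped", animal_id)
            continue
        references[animal_id] = build_reference(baseline, config)
    return references


def score_cohort(
    manifest: TrialManifest,
    config: RunConfig | None = None,
    dialect: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, KinematicReference], list[CleaningReport]]:
    """Preprocess and score every trial in a manifest.

    Builds one reference per animal from its baseline-success trials
    and scores every trial (baseline successes included) against its
    own animal's reference.  Returns the tidy KDI table, the
    long-format KD-trajectory table, the references, and the cleaning
    reports.
    """
    config = config or RunConfig()
    normalized: dict[str, list[NormalizedTrial]] = {}
    flags: dict[tuple[str, str], bool] = {}
    reports: list[CleaningReport] = []
    for _, row in manifest.table.iterrows():
        raw = load_trial(manifest, row, dialect=dialect)
        nt, report = preprocess_trial(
            raw, config.preprocess, derived_variables=config.core.derived_variables
        )
        normalized.setdefault(raw.animal_id, []).append(nt)
        flags[(raw.animal_id, raw.trial_id)] = bool(row["is_baseline_success"])
        reports.append(report)

    references = build_cohort_references(normalized, flags, config.core, strict=config.strict)

    kdi_rows = []
    traj_rows = []
    for animal_id, trials in normalized.items():
        if animal_id not in references:
            continue
        ref = references[animal_id]
        for nt in trials:
            result = score_trial(nt, ref, config.core)
            kdi_rows.append(
                {
                    "animal_id": result.animal_id,
                    "trial_id": result.trial_id,
                    "condition": result.condition,
                    "endpoint": result.endpoint,
                    "kdi": result.kdi,
                }
            )
            for n, d in enumerate(result.kd_trajectory, start=1):
                traj_rows.append(
                    {
                        "animal_id": result.animal_id,
                        "trial_id": result.trial_id,
                        "n": n,
                        "d": float(d),
                    }
                )
    kdi_table = pd.DataFrame(kdi_rows, columns=["animal_id", "trial_id", "condition", "endpoint", "kdi"])
    trajectories = pd.DataFrame(traj_rows, columns=["animal_id", "trial_id", "n", "d"])
    return kdi_table, trajectories, references, reports
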