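"""Synthetic single-pellet-reach track generator.

Emulates the geometry of a mouse skilled-reaching assay recorded at
720 x 540 px (image convention, y down): four digit markers riding a
common paw path through a lift-advance-grasp-withdraw arc toward a
static pellet, plus per-frame Gaussian tracking noise, trial-to-trial
waypoint and duration variability, endpoint-specific perturbations
(shortened reaches, altered grasps, tremor, slowing) and optional
tracking corruption (jump outliers, missing points).  Everything is
deterministic given a seed, so pipeline behaviour can be validated
against exact ground truth without animal data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ParameterError
from .io import RawTrial, TrialManifest, load_manifest

DIGIT_MARKERS = ("digit2", "digit3", "digit4", "digit5")
MARKERS = DIGIT_MARKERS + ("pellet",)

FRAME_SIZE = (720, 540)
NOMINAL_FPS = 327.0
# reference tracking-noise s.d. (px); perturbation amplitudes are
# expressed as multiples of this baseline, independent of the noise
# actually rendered on a given trial
BASELINE_NOISE_SD = 1.5

PERTURBATION_KINDS = (
    "none", "truncate_reach", "grasp_alteration", "amplitude_scale",
    "tremor_noise", "slowing",
)

SCENARIOS = ("endpoint_validity", "chronic_injury", "silencing")


@dataclass
class PerturbationSpec:
    """A movement perturbation applied to part of a trial.

    ``amplitude`` is a unitless multiple of the baseline tracking-noise
    standard deviation (``BASELINE_NOISE_SD`` px), so perturbations keep
    their physical size even on noiseless renders; ``segment`` is the
    fraction interval of trial duration it affects.
    """

    kind: str = "none"
    amplitude: float = 0.0
    segment: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ParameterError(f"unknown perturbation kind {self.kind!r}")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        a, b = self.segment
        if not (0.0 <= a <= b <= 1.0):
            raise ParameterError(f"segment must be within [0, 1], got {self.segment}")


@dataclass
class CorruptionSpec:
    """Tracking-failure injection: jump outliers and missing points."""

    spike_rate: float = 0.0
    spike_magnitude: float = 200.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("spike_rate", self.spike_rate), ("missing_rate", self.missing_rate)):
            if not (0.0 <= rate <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {rate}")
        if self.spike_magnitude <= 0:
            raise ParameterError("spike_magnitude must be > 0")


@dataclass
class CorruptionMask:
    """Exact record of injected corruption (points = marker-frames)."""

    spike: np.ndarray   # (n_frames, n_markers) bool
    missing: np.ndarray  # (n_frames, n_markers) bool

    @property
    def any(self) -> np.ndarray:
        return self.spike | self.missing

    @property
    def n_corrupted(self) -> int:
        return int(self.any.sum())


@dataclass
class ReachTemplate:
    """Parametric noiseless reach: a smooth paw arc through waypoints,
    digit offsets around it, and a static pellet.

    ``waypoints`` are 2-D paw positions (pixels, y down) at the phases
    in ``waypoint_phases``: rest, lift, slot, pellet contact (grasp),
    withdraw end.  Digit markers sit at fixed offsets from the paw,
    modulated by a smooth grasp-aperture profile, and never stray more
    than ``digit_spread_max`` px from the paw path.
    """

    waypoints: np.ndarray
    waypoint_phases: tuple[float, ...] = (0.0, 0.2, 0.45, 0.65, 1.0)
    duration: int = 327
    digit_offsets: np.ndarray = field(
        default_factory=lambda: np.array(
            [[6.0, -9.0], [9.0, -3.0], [9.0, 4.0], [6.0, 10.0]]
        )
    )
    pellet_pos: np.ndarray = field(default_factory=lambda: np.array([432.0, 392.0]))
    fps: float = NOMINAL_FPS
    digit_spread_max: float = 20.0

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.waypoints.shape != (len(self.waypoint_phases), 2):
            raise ParameterError(
                f"waypoints must be ({len(self.waypoint_phases)}, 2), got {self.waypoints.shape}"
            )
        if not np.all(np.isfinite(self.waypoints)):
            raise ParameterError("waypoints must be finite")
        self._spline = CubicSpline(
            np.asarray(self.waypoint_phases), self.waypoints, bc_type="clamped"
        )

    def paw_path(self, phases: np.ndarray) -> np.ndarray:
        """Noiseless paw position at each phase in [0, 1]; shape (n, 2)."""
        return self._spline(np.clip(phases, 0.0, 1.0))

    def aperture(self, phases: np.ndarray) -> np.ndarray:
        """Grasp aperture profile: digits spread slightly approaching the
        pellet and close at the grasp phase."""
        grasp = self.waypoint_phases[3]
        open_bump = 0.25 * np.exp(-(((phases - grasp + 0.12) / 0.1) ** 2))
        close_dip = 0.35 * np.exp(-(((phases - grasp) / 0.06) ** 2))
        return 1.0 + open_bump - close_dip

    def marker_paths(self, phases: np.ndarray) -> np.ndarray:
        """Noiseless positions of all markers; shape (n, n_markers, 2)."""
        paw = self.paw_path(phases)
        ap = self.aperture(phases)[:, None]
        out = np.empty((len(phases), len(MARKERS), 2))
        for k, off in enumerate(self.digit_offsets):
            out[:, k, :] = paw + ap * off[None, :]
        out[:, len(DIGIT_MARKERS), :] = self.pellet_pos[None, :]
        return out


def canonical_template(duration: int = 327) -> ReachTemplate:
    """The stereotyped reach: rest at the slot, lift, advance through
    the slot, contact the pellet 12 mm (~ 120 px here) beyond, withdraw
    along a lower return path (a loop, not a retrace)."""
    waypoints = np.array(
        [
            [300.0, 408.0],  # rest
            [316.0, 380.0],  # lift
            [360.0, 386.0],  # slot
            [430.0, 392.0],  # pellet contact
            [306.0, 420.0],  # withdraw end
        ]
    )
    return ReachTemplate(waypoints=waypoints, duration=duration)


def subject_template(rng: np.random.Generator, duration: int | None = None,
                     waypoint_jitter: float = 6.0) -> ReachTemplate:
    """An animal-specific template: canonical waypoints jittered to model
    individual movement-strategy differences."""
    base = canonical_template()
    waypoints = base.waypoints + rng.normal(0.0, waypoint_jitter, base.waypoints.shape)
    if duration is None:
        duration = int(rng.integers(200, 501))
    pellet = base.pellet_pos + rng.normal(0.0, 2.0, 2)
    # keep the contact waypoint on the pellet
    waypoints[3] = pellet + np.array([-2.0, 0.0])
    return ReachTemplate(waypoints=waypoints, duration=duration, pellet_pos=pellet)


def _segment_window(phases: np.ndarray, segment: tuple[float, float]) -> np.ndarray:
    """Smooth sin^2 bump supported exactly on [a, b], zero outside."""
    a, b = segment
    if b <= a:
        return np.zeros_like(phases)
    w = np.zeros_like(phases)
    inside = (phases > a) & (phases < b)
    w[inside] = np.sin(np.pi * (phases[inside] - a) / (b - a)) ** 2
    return w


def _apply_perturbation(
    template: ReachTemplate,
    phases: np.ndarray,
    spec: PerturbationSpec,
) -> np.ndarray:
    """Return perturbed marker paths (noiseless) for the given phases."""
    scale = spec.amplitude * BASELINE_NOISE_SD  # displacement scale in px
    if spec.kind == "slowing":
        a, b = spec.segment
        eps = (b - a) * 0.25 * np.tanh(spec.amplitude / 4.0)
        warped = phases - eps * _segment_window(phases, spec.segment)
        return template.marker_paths(warped)

    markers = template.marker_paths(phases)
    if spec.kind == "none" or spec.amplitude == 0.0:
        return markers
    w = _segment_window(phases, spec.segment)
    paw_like = slice(0, len(DIGIT_MARKERS))  # pellet never perturbed

    if spec.kind == "truncate_reach":
        # pull the advance back so no paw marker reaches the pellet x
        start_x = template.waypoints[0, 0]
        margin = 12.0 + 2.0 * spec.amplitude
        cap = template.pellet_pos[0] - margin
        x = markers[:, paw_like, 0]
        over = x > cap
        x[over] = cap - (x[over] - cap) * 0.15
        markers[:, paw_like, 0] = np.maximum(x, start_x - 40.0)
    elif spec.kind == "grasp_alteration":
        direction = np.array([0.5, -0.866])  # deviate up and forward
        markers[:, paw_like, :] += scale * w[:, None, None] * direction[None, None, :]
    elif spec.kind == "amplitude_scale":
        start = template.waypoints[0]
        extent = markers[:, paw_like, :] - start[None, None, :]
        norms = np.linalg.norm(extent.reshape(len(phases), -1), axis=1)
        max_extent = max(float(norms.max()), 1.0)
        factor = 1.0 - (scale / max_extent) * w
        markers[:, paw_like, :] = start[None, None, :] + extent * factor[:, None, None]
    elif spec.kind == "tremor_noise":
        a, b = spec.segment
        span = max(b - a, 1e-9)
        direction = np.array([0.707, -0.707])
        cycles = 4.0
        osc = np.sin(2.0 * np.pi * cycles * (phases - a) / span)
        markers[:, paw_like, :] += scale * (w * osc)[:, None, None] * direction[None, None, :]
    return markers


def generate_trial(
    template: ReachTemplate,
    endpoint: str = "success",
    perturbation: PerturbationSpec | None = None,
    noise_sd: float = 1.5,
    duration_jitter: float = 0.0,
    seed: int = 0,
    trial_id: str = "trial",
    animal_id: str = "animal",
    condition: str = "baseline",
) -> RawTrial:
    """Sample one synthetic trial from a template.

    Duration is jittered multiplicatively, the perturbation applies to
    its phase segment, and isotropic Gaussian tracking noise of
    ``noise_sd`` px is added per marker per frame.  Deterministic given
    ``seed``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    perturbation = perturbation or PerturbationSpec()
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0)  # always drawn, so the stream is jitter-invariant
    duration = max(int(round(template.duration * (1.0 + duration_jitter * u))), 20)
    phases = np.linspace(0.0, 1.0, duration)
    markers = _apply_perturbation(template, phases, perturbation)
    if noise_sd > 0:
        markers = markers + rng.normal(0.0, noise_sd, markers.shape)
    likelihood = rng.uniform(0.9, 1.0, (duration, len(MARKERS)))
    return RawTrial(
        trial_id=trial_id,
        animal_id=animal_id,
        condition=condition,
        endpoint=endpoint,
        marker_names=list(MARKERS),
        frames=np.arange(duration, dtype=float),
        xy=markers,
        likelihood=likelihood,
    )


def inject_corruption(trial: RawTrial, spec: CorruptionSpec) -> tuple[RawTrial, CorruptionMask]:
    """Inject tracking failures, returning the exact corruption mask.

    Spikes displace a point by ``spike_magnitude`` px in a random
    direction; missing points are blanked.  A point receives at most
    one kind of corruption.
    """
    rng = np.random.default_rng(spec.seed)
    out = trial.copy()
    shape = (trial.n_frames, trial.n_markers)
    spike = rng.random(shape) < spec.spike_rate
    missing = (~spike) & (rng.random(shape) < spec.missing_rate)
    angles = rng.uniform(0.0, 2.0 * np.pi, shape)
    disp = spec.spike_magnitude * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    out.xy = out.xy + np.where(spike[..., None], disp, 0.0)
    out.xy[missing] = np.nan
    return out, CorruptionMask(spike=spike, missing=missing)


def _dlc_frame(trial: RawTrial, scorer: str = "synthetic") -> pd.DataFrame:
    cols, data = [], {}
    for k, name in enumerate(trial.marker_names):
        for coord in ("x", "y", "likelihood"):
            cols.append((scorer, name, coord))
            if coord == "likelihood":
                lk = trial.likelihood[:, k] if trial.likelihood is not None else np.ones(trial.n_frames)
                data[(scorer, name, coord)] = lk
            else:
                data[(scorer, name, coord)] = trial.xy[:, k, 0 if coord == "x" else 1]
    return pd.DataFrame(
        data, columns=pd.MultiIndex.from_tuples(cols, names=["scorer", "bodyparts", "coords"])
    )


def write_dlc_csv(trial: RawTrial, path: str | os.PathLike) -> None:
    """Write a trial in the 3-header-row pose-track CSV dialect."""
    _dlc_frame(trial).to_csv(path, float_format="%.6f")


def _scenario_plan(scenario: str, trials_per_condition: int) -> list[dict]:
    """Per-animal trial plan: (condition, endpoint, perturbation) rows."""
    plan: list[dict] = []
    if scenario == "endpoint_validity":
        specs = {
            "success": PerturbationSpec("none"),
            "grasp_fail": PerturbationSpec("grasp_alteration", amplitude=12.0, segment=(0.68, 1.0)),
            "reach_fail": PerturbationSpec("truncate_reach", amplitude=12.0, segment=(0.3, 1.0)),
        }
        for endpoint, spec in specs.items():
            for _ in range(trials_per_condition):
                plan.append({"condition": "baseline", "endpoint": endpoint, "perturbation": spec})
    elif scenario == "chronic_injury":
        for _ in range(trials_per_condition):
            plan.append({"condition": "baseline", "endpoint": "success",
                         "perturbation": PerturbationSpec("none")})
        injury = PerturbationSpec("tremor_noise", amplitude=10.0, segment=(0.25, 1.0))
        for _ in range(trials_per_condition):
            plan.append({"condition": "chronic", "endpoint": "unknown", "perturbation": injury})
    elif scenario == "silencing":
        for _ in range(trials_per_condition):
            plan.append({"condition": "baseline", "endpoint": "success",
                         "perturbation": PerturbationSpec("none")})
        silenced = PerturbationSpec("tremor_noise", amplitude=8.0, segment=(0.25, 0.75))
        for _ in range(trials_per_condition):
            plan.append({"condition": "silencing", "endpoint": "unknown", "perturbation": silenced})
    else:
        raise ParameterError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return plan


def generate_cohort(
    n_animals: int,
    trials_per_condition: int,
    scenario: str,
    seed: int,
    out_dir: str | os.PathLike,
    noise_sd: float = 1.5,
    duration_jitter: float = 0.15,
) -> TrialManifest:
    """Simulate a cohort to disk: pose-track CSVs, a manifest, and a
    ground-truth JSON (templates and perturbation specs per trial).

    Each animal gets its own jittered template (subject heterogeneity).
    Fully deterministic given ``seed``.
    """
    if n_animals < 1 or trials_per_condition < 1:
        raise ParameterError("n_animals and trials_per_condition must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    truth: dict = {"scenario": scenario, "seed": seed, "animals": {}}
    for ai in range(n_animals):
        animal_id = f"animal{ai + 1:02d}"
        arng = np.random.default_rng(master.integers(0, 2**31))
        template = subject_template(arng)
        truth["animals"][animal_id] = {
            "waypoints": template.waypoints.tolist(),
            "duration": template.duration,
            "trials": {},
        }
        for ti, item in enumerate(_scenario_plan(scenario, trials_per_condition)):
            trial_id = f"t{ti + 1:03d}"
            trial_seed = int(arng.integers(0, 2**31))
            trial = generate_trial(
                template,
                endpoint=item["endpoint"],
                perturbation=item["perturbation"],
                noise_sd=noise_sd,
                duration_jitter=duration_jitter,
                seed=trial_seed,
                trial_id=trial_id,
                animal_id=animal_id,
                condition=item["condition"],
            )
            fname = f"{animal_id}_{trial_id}.csv"
            write_dlc_csv(trial, out_dir / fname)
            rows.append(
                {
                    "trial_id": trial_id,
                    "animal_id": animal_id,
                    "condition": item["condition"],
                    "endpoint": item["endpoint"],
                    "track_path": fname,
                }
            )
            spec = item["perturbation"]
            truth["animals"][animal_id]["trials"][trial_id] = {
                "seed": trial_seed,
                "perturbation": {
                    "kind": spec.kind, "amplitude": spec.amplitude,
                    "segment": list(spec.segment),
                },
            }
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return load_manifest(manifest_path)
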