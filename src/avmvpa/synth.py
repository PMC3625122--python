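"""Synthetic inputs for the audiovisual pattern-reliability pipeline.

This module generates everything the analysis stages consume: event-related
experimental designs, per-trial multivoxel activation patterns, 4D BOLD runs
built from those patterns via HRF convolution, simple brain geometry (grey
matter plus three retinotopic ROI slabs), and phase-encoded retinotopic
mapping time series with known ground-truth phases.

The generative model for a trial pattern of stimulus ``s`` in condition ``c``
is::

    pattern = g_c * template_s + sigma_c * eta + intercept

where ``template_s`` is a unit-norm stimulus template shared across
conditions, ``g_c`` is a condition gain (0 for the auditory-only condition,
equal across visual conditions by default), ``eta`` is i.i.d. standard
normal pattern noise, and ``sigma_c`` a condition-specific noise SD.  Mean
amplitude is therefore identical across visual conditions while the
trial-to-trial scatter of patterns about the stimulus mean is controlled by
``sigma_c`` alone — the dissociation the downstream analyses are designed to
detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from . import glm as _glm
from .mvpa import PatternSet

#: Condition labels in canonical order.
CONDITIONS = ("AV_congruent", "AV_incongruent", "V", "A")
#: Conditions containing a visual stimulus.
VISUAL_CONDITIONS = ("AV_congruent", "AV_incongruent", "V")
#: Label used for blank (baseline) trials; stimulus index is -1.
BLANK = "blank"

DEFAULT_GAINS = {"AV_congruent": 1.0, "AV_incongruent": 1.0, "V": 1.0, "A": 0.0}
#: Baseline per-voxel pattern-noise SD for all conditions.
DEFAULT_SIGMA = 0.75
#: Elevated pattern-noise SD for the AV-incongruent condition in the
#: noise-modulated ROI (the V2 analogue).
DEFAULT_SIGMA_INCONGRUENT = 1.3


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the event-related design.

    Defaults mirror the target experiment: 18 runs of 16 stimulus trials
    (4 stimuli x 4 conditions) plus 4 blanks, 3 s stimuli with 2 s ISI,
    TR 2.72 s, 42 volumes per run including 3 leading and 2 trailing
    dummy volumes (run duration 114.24 s).
    """

    n_runs: int = 18
    n_stimuli: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    n_blanks_per_run: int = 4
    stim_duration: float = 3.0
    isi: float = 2.0
    tr: float = 2.72
    volumes_per_run: int = 42
    n_dummy_start: int = 3
    n_dummy_end: int = 2

    @property
    def trials_per_run(self) -> int:
        return self.n_stimuli * len(self.conditions) + self.n_blanks_per_run

    @property
    def run_duration(self) -> float:
        """Total run duration in seconds, dummies included."""
        return self.volumes_per_run * self.tr

    @property
    def usable_duration(self) -> float:
        """Seconds available for trials after removing dummy volumes."""
        n_task = self.volumes_per_run - self.n_dummy_start - self.n_dummy_end
        return n_task * self.tr

    def validate(self) -> None:
        if not 17 <= self.n_runs <= 24:
            raise ValueError(f"n_runs must be within 17-24, got {self.n_runs}")
        if self.n_stimuli < 2:
            raise ValueError("need at least two stimuli")
        needed = self.trials_per_run * (self.stim_duration + self.isi)
        if needed > self.usable_duration + 1e-9:
            raise ValueError(
                f"run too short: {self.trials_per_run} trials need {needed:.2f} s "
                f"but only {self.usable_duration:.2f} s are available after dummies"
            )


@dataclass
class ExperimentDesign:
    """Ordered trial events for all runs.

    ``events`` columns: run (0-based), onset (seconds from run start after
    dummy removal), duration, stimulus (0..n_stimuli-1, or -1 for blanks),
    condition, n_color_changes.
    """

    events: pd.DataFrame
    spec: DesignSpec

    def run_events(self, run: int) -> pd.DataFrame:
        return self.events[self.events["run"] == run].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, spec: DesignSpec) -> "ExperimentDesign":
        return cls(pd.read_csv(path, sep="\t"), spec)


@dataclass
class BrainGeometry:
    """Voxel grid, affine, grey-matter mask and disjoint ROI masks."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    grey_mask: np.ndarray
    roi_masks: dict[str, np.ndarray]

    def validate(self) -> None:
        for name, mask in self.roi_masks.items():
            if mask.shape != self.shape:
                raise ValueError(f"ROI {name} shape mismatch")
            if np.any(mask & ~self.grey_mask):
                raise ValueError(f"ROI {name} leaves the grey-matter mask")
        names = list(self.roi_masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(self.roi_masks[a] & self.roi_masks[b]):
                    raise ValueError(f"ROIs {a} and {b} overlap")

    def roi_size(self, name: str) -> int:
        return int(self.roi_masks[name].sum())


@dataclass
class GroundTruth:
    """Everything the simulator knows and the analyses try to recover.

    ``noise_sd`` maps roi -> condition -> per-voxel pattern-noise SD, so a
    single ROI (the V2 analogue) can carry the incongruence-related noise
    increase while the others stay at baseline.
    """

    templates: dict[str, np.ndarray]          # roi -> (n_stimuli, n_voxels)
    gains: dict[str, float]                   # condition -> gain
    noise_sd: dict[str, dict[str, float]]     # roi -> condition -> SD
    intercepts: dict[str, np.ndarray]         # roi -> (n_voxels,)
    retino_phases: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for roi, tpl in self.templates.items():
            if tpl.ndim != 2:
                raise ValueError("templates must be 2-D (stimuli x voxels)")
            if self.intercepts[roi].shape != (tpl.shape[1],):
                raise ValueError(f"intercept shape mismatch for {roi}")
            for cond, sd in self.noise_sd[roi].items():
                if sd < 0:
                    raise ValueError(f"negative noise SD for {roi}/{cond}")
        for cond, g in self.gains.items():
            if g < 0:
                raise ValueError(f"negative gain for {cond}")

    def to_json(self, path) -> None:
        payload = {
            "templates": {k: v.tolist() for k, v in self.templates.items()},
            "gains": self.gains,
            "noise_sd": self.noise_sd,
            "intercepts": {k: v.tolist() for k, v in self.intercepts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def generate_design(spec: DesignSpec, seed: int) -> ExperimentDesign:
    """Randomised trial order for every run.

    Each run contains exactly one trial per (stimulus, condition) pair plus
    ``n_blanks_per_run`` blanks, in a seeded uniform random order on a fixed
    grid of ``stim_duration + isi`` seconds per trial.  The number of
    fixation-dot colour changes (1-3) is drawn per trial.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    slot = spec.stim_duration + spec.isi
    stims = np.array(
        [s for s in range(spec.n_stimuli) for _ in spec.conditions]
        + [-1] * spec.n_blanks_per_run
    )
    conds = np.array(
        [c for _ in range(spec.n_stimuli) for c in spec.conditions]
        + [BLANK] * spec.n_blanks_per_run,
        dtype=object,
    )
    n_trials = len(stims)
    orders = np.array([rng.permutation(n_trials) for _ in range(spec.n_runs)])
    changes = rng.integers(1, 4, size=(spec.n_runs, n_trials))
    events = pd.DataFrame(
        {
            "run": np.repeat(np.arange(spec.n_runs), n_trials),
            "onset": np.tile(np.arange(n_trials) * slot, spec.n_runs),
            "duration": spec.stim_duration,
            "stimulus": stims[orders].ravel(),
            "condition": conds[orders].ravel(),
            "n_color_changes": changes.ravel(),
        }
    )
    return ExperimentDesign(events, spec)


def default_geometry(
    shape: tuple[int, int, int] = (40, 40, 20),
    voxel_size_mm: float = 3.0,
    roi_voxels: int = 150,
    roi_names: tuple[str, ...] = ("V1", "V2", "V3"),
) -> BrainGeometry:
    """Desk-scale stand-in for a segmented brain with three ROI slabs.

    The grey-matter mask is a centred box; the ROIs are disjoint slabs of
    ``roi_voxels`` voxels each placed inside it.
    """
    grey = np.zeros(shape, dtype=bool)
    gx, gy, gz = shape
    grey[gx // 8: gx - gx // 8, gy // 8: gy - gy // 8, gz // 8: gz - gz // 8] = True

    # carve disjoint contiguous slabs out of the grey-matter scan order
    # (x fastest), evenly spaced so the ROIs are spatially separated
    coords = np.argwhere(grey.transpose(2, 1, 0))[:, ::-1]
    n_grey = len(coords)
    needed = len(roi_names) * roi_voxels
    if n_grey < needed:
        raise ValueError(
            f"grid too small: {n_grey} grey voxels cannot hold "
            f"{len(roi_names)} ROIs of {roi_voxels} voxels"
        )
    gap = (n_grey - needed) // (len(roi_names) + 1)
    roi_masks = {}
    for k, name in enumerate(roi_names):
        start = gap + k * (roi_voxels + gap)
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(coords[start: start + roi_voxels].T)] = True
        roi_masks[name] = mask
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    geom = BrainGeometry(shape, affine, grey, roi_masks)
    geom.validate()
    return geom


def default_ground_truth(
    geometry: BrainGeometry,
    seed: int,
    gains: dict[str, float] | None = None,
    sigma: float = DEFAULT_SIGMA,
    sigma_incongruent: float = DEFAULT_SIGMA_INCONGRUENT,
    modulated_roi: str | None = "V2",
    intercept_mean: float = 1.0,
    intercept_sd: float = 0.1,
    conditions: tuple[str, ...] = CONDITIONS,
    n_stimuli: int = 4,
) -> GroundTruth:
    """Ground truth with the noise-modulated (headline) configuration.

    All conditions share the stimulus templates and, by default, equal
    visual gains; only ``sigma_incongruent`` in ``modulated_roi`` elevates
    the AV-incongruent pattern noise.  Pass ``modulated_roi=None`` for the
    fully null configuration (equal noise everywhere).
    """
    rng = np.random.default_rng(seed)
    gains = dict(DEFAULT_GAINS if gains is None else gains)
    templates, intercepts, noise_sd = {}, {}, {}
    for roi, mask in geometry.roi_masks.items():
        n_vox = int(mask.sum())
        tpl = rng.standard_normal((n_stimuli, n_vox))
        tpl /= np.linalg.norm(tpl, axis=1, keepdims=True)
        templates[roi] = tpl
        intercepts[roi] = intercept_mean + intercept_sd * rng.standard_normal(n_vox)
        sds = {c: sigma for c in conditions}
        if roi == modulated_roi:
            sds["AV_incongruent"] = sigma_incongruent
        noise_sd[roi] = sds
    truth = GroundTruth(templates, gains, noise_sd, intercepts)
    truth.validate()
    return truth


def null_ground_truth(geometry: BrainGeometry, seed: int, **kwargs) -> GroundTruth:
    """Equal noise SD in every ROI and condition (no reliability effect)."""
    kwargs.setdefault("modulated_roi", None)
    return default_ground_truth(geometry, seed, **kwargs)


def _pattern_rows(spec: DesignSpec):
    """Deterministic (run, condition, stimulus) row order for pattern sets."""
    for run in range(spec.n_runs):
        for cond in spec.conditions:
            for stim in range(spec.n_stimuli):
                yield run, cond, stim


def generate_trial_patterns(
    truth: GroundTruth, design: ExperimentDesign, seed: int
) -> dict[str, PatternSet]:
    """Per-trial activation patterns for every ROI.

    Rows are ordered run-major, then condition (canonical order), then
    stimulus.  The auditory-only condition has zero gain, so its patterns
    are intercept plus noise only and carry no stimulus information.
    """
    truth.validate()
    spec = design.spec
    rng = np.random.default_rng(seed)
    out = {}
    for roi, tpl in truth.templates.items():
        n_vox = tpl.shape[1]
        rows, labels, runs, conds = [], [], [], []
        for run, cond, stim in _pattern_rows(spec):
            g = truth.gains[cond]
            sd = truth.noise_sd[roi][cond]
            eta = rng.standard_normal(n_vox)
            rows.append(g * tpl[stim] + sd * eta + truth.intercepts[roi])
            labels.append(stim)
            runs.append(run)
            conds.append(cond)
        out[roi] = PatternSet(
            vectors=np.asarray(rows),
            labels=np.asarray(labels),
            runs=np.asarray(runs),
            conditions=np.asarray(conds, dtype=object),
            roi=roi,
        )
    return out


@dataclass
class BoldRun:
    """One simulated 4D run plus its events and dummy-volume bookkeeping."""

    image: nib.Nifti1Image
    events: pd.DataFrame
    n_dummy_start: int
    n_dummy_end: int
    tr: float = 2.72

    @property
    def data(self) -> np.ndarray:
        return np.asarray(self.image.dataobj)

    def task_data(self) -> np.ndarray:
        """Volumes with the flagged dummies stripped."""
        d = self.data
        stop = d.shape[-1] - self.n_dummy_end
        return d[..., self.n_dummy_start: stop]


def generate_bold_runs(
    truth: GroundTruth,
    design: ExperimentDesign,
    geometry: BrainGeometry,
    noise_sd_ts: float,
    seed: int,
    patterns: dict[str, PatternSet] | None = None,
) -> list[BoldRun]:
    """Realise the pattern model as 4D BOLD time series.

    Each ROI voxel's series is the superposition, across that run's stimulus
    trials, of the trial's pattern amplitude times an HRF-convolved 3 s
    boxcar, plus white noise of SD ``noise_sd_ts`` everywhere in the grid.
    Blank trials generate no signal.  Dummy volumes are part of the series
    and flagged on the returned :class:`BoldRun`.

    If ``patterns`` is given (from :func:`generate_trial_patterns`) those
    exact amplitudes are injected; otherwise they are generated from
    ``seed`` first, so the GLM stage can be validated against a known
    pattern set either way.
    """
    if noise_sd_ts < 0:
        raise ValueError("noise_sd_ts must be non-negative")
    geometry.validate()
    spec = design.spec
    rng = np.random.default_rng(seed)
    if patterns is None:
        patterns = generate_trial_patterns(truth, design, int(rng.integers(2 ** 31)))

    shape = geometry.shape
    n_vol = spec.volumes_per_run
    dummy_offset = spec.n_dummy_start * spec.tr
    runs = []
    for run in range(spec.n_runs):
        ev = design.run_events(run)
        stim_ev = ev[ev["stimulus"] >= 0].reset_index(drop=True)
        # regressors on the full (dummy-inclusive) timeline
        reg = _glm.convolve_boxcars(
            stim_ev["onset"].to_numpy() + dummy_offset,
            np.full(len(stim_ev), spec.stim_duration),
            n_vol,
            spec.tr,
        )  # (n_vol, n_trials)
        data = rng.standard_normal((*shape, n_vol)) * noise_sd_ts
        for roi, mask in geometry.roi_masks.items():
            pset = patterns[roi]
            amps = np.empty((len(stim_ev), pset.n_voxels))
            for i, row in stim_ev.iterrows():
                amps[i] = pset.trial_vector(run, row["condition"], int(row["stimulus"]))
            signal = reg @ amps  # (n_vol, n_vox)
            flat = data.reshape(-1, n_vol, order="F")
            idx = np.flatnonzero(mask.ravel(order="F"))
            flat[idx] += signal.T
            data = flat.reshape(*shape, n_vol, order="F")
        img = nib.Nifti1Image(data.astype(np.float64), geometry.affine)
        img.header.set_zooms((*np.diag(geometry.affine)[:3], spec.tr))
        runs.append(BoldRun(img, ev, spec.n_dummy_start, spec.n_dummy_end, spec.tr))
    return runs


def generate_trial_volume_maps(
    truth: GroundTruth,
    design: ExperimentDesign,
    geometry: BrainGeometry,
    map_noise_sd: float,
    seed: int,
    patterns: dict[str, PatternSet] | None = None,
) -> list[_glm.TrialMaps]:
    """Volumetric per-trial-type maps straight from the pattern model.

    Produces the same per-run map structure the GLM stage emits (one
    volume per stimulus x condition), with ROI voxels carrying the exact
    trial pattern values and all other grey voxels carrying white noise of
    SD ``map_noise_sd`` (chance-level patterns).  This is the desk-scale
    input for searchlight analyses when the full BOLD + GLM realisation is
    not required; beta and t volumes are identical here.
    """
    if map_noise_sd < 0:
        raise ValueError("map_noise_sd must be non-negative")
    geometry.validate()
    spec = design.spec
    rng = np.random.default_rng(seed)
    if patterns is None:
        patterns = generate_trial_patterns(truth, design, int(rng.integers(2 ** 31)))
    types = [(s, c) for c in spec.conditions for s in range(spec.n_stimuli)]
    out = []
    for run in range(spec.n_runs):
        vols = np.full((len(types), *geometry.shape), np.nan)
        for k, (stim, cond) in enumerate(types):
            vol = np.full(geometry.shape, np.nan)
            grey = geometry.grey_mask
            vol[grey] = map_noise_sd * rng.standard_normal(int(grey.sum()))
            for roi, mask in geometry.roi_masks.items():
                vol[mask] = patterns[roi].trial_vector(run, cond, stim)
            vols[k] = vol
        out.append(
            _glm.TrialMaps(
                betas=vols,
                tstats=vols.copy(),
                types=list(types),
                resid_var=np.ones(geometry.shape),
                df=1,
                run=run,
            )
        )
    return out


STIM_FREQ = {"wedge": 12, "ring": 20}
#: Steps per cycle of the mapping stimuli (wedge: 12 cycles x 20 steps,
#: ring: 20 cycles x 12 steps -> 240 timepoints either way).
STEPS_PER_CYCLE = {"wedge": 20, "ring": 12}


def generate_retino_series(
    geometry: BrainGeometry,
    stim: str,
    n_timepoints: int = 240,
    amplitude: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    baseline: float = 100.0,
) -> tuple[nib.Nifti1Image, np.ndarray, np.ndarray]:
    """Phase-encoded mapping run with known ground-truth phases.

    Responsive voxels (the union of the ROI masks) follow
    ``baseline + amplitude * cos(2*pi*f*t/N - phase)`` with ``f`` = 12
    (wedge) or 20 (ring) cycles per run; all other grey voxels are noise
    only.  Returns ``(image, phase_volume, responsive_mask)`` where the
    phase volume is NaN outside responsive voxels.
    """
    if stim not in STIM_FREQ:
        raise ValueError(f"stim must be one of {sorted(STIM_FREQ)}")
    f = STIM_FREQ[stim]
    if n_timepoints % f:
        raise ValueError(f"n_timepoints must be divisible by {f} cycles")
    if f >= n_timepoints / 2:
        raise ValueError("stimulus frequency at or above the Nyquist bin")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    responsive = np.zeros(geometry.shape, dtype=bool)
    for mask in geometry.roi_masks.values():
        responsive |= mask
    phases = np.full(geometry.shape, np.nan)
    phases[responsive] = rng.uniform(0.0, 2.0 * np.pi, int(responsive.sum()))

    t = np.arange(n_timepoints)
    data = np.zeros((*geometry.shape, n_timepoints))
    data[geometry.grey_mask] = baseline
    phi = phases[responsive][:, None]
    data[responsive] += amplitude * np.cos(2 * np.pi * f * t[None, :] / n_timepoints - phi)
    data[geometry.grey_mask] += noise_sd * rng.standard_normal(
        (int(geometry.grey_mask.sum()), n_timepoints)
    )
    img = nib.Nifti1Image(data, geometry.affine)
    return img, phases, responsive


def write_run(run: BoldRun, nifti_path, events_path) -> None:
    nib.save(run.image, str(nifti_path))
    run.events.to_csv(events_path, sep="\t", index=False)


def small_design_spec(n_runs: int = 18, **overrides) -> DesignSpec:
    """Convenience constructor used by tests and desk-scale drivers."""
    return replace(DesignSpec(), n_runs=n_runs, **overrides)
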