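"""Per-run trial-wise general linear model.

One HRF-convolved boxcar regressor per trial type (16 stimulus types plus
one blank regressor), a response-interval regressor, optional nuisance
columns, and a constant.  Estimation is ordinary least squares with i.i.d.
noise; per-type t maps are the decoding features downstream, beta maps feed
the univariate amplitude analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

HRF_SUPPORT_S = 32.0
OVERSAMPLE = 16


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled on [0, 32] s at ``dt``.

    h(t) = pdf_Gamma(t; 6, 1) - pdf_Gamma(t; 16, 1) / 6, scaled so the
    peak equals 1.  The positive lobe peaks near 5 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_SUPPORT_S + dt / 2, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def convolve_boxcars(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_volumes: int,
    tr: float,
    oversample: int = OVERSAMPLE,
) -> np.ndarray:
    """HRF-convolved boxcar regressors sampled at volume acquisition times.

    The neural boxcar is laid out on a grid of ``tr / oversample`` seconds,
    convolved with the canonical HRF at that resolution, then sampled at
    t = k * tr.  Returns an (n_volumes, n_events) matrix with one column
    per event.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    dt = tr / oversample
    hrf = canonical_hrf(dt)
    n_hi = n_volumes * oversample
    out = np.zeros((n_volumes, len(onsets)))
    for k, (onset, dur) in enumerate(zip(onsets, durations)):
        box = np.zeros(n_hi)
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:min(i1, n_hi)] = 1.0
        conv = np.convolve(box, hrf)[:n_hi]
        out[:, k] = conv[::oversample]
    return out


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # (n_volumes, n_regressors)
    names: list[str]
    #: (stimulus, condition) for each trial-type column, aligned with the
    #: leading columns of ``matrix``.
    trial_types: list[tuple[int, str]]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _collinear_columns(x: np.ndarray, names) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    return [n for n, b in zip(names, bad) if b]


def build_design_matrix(
    events,
    n_volumes: int,
    tr: float,
    nuisance: np.ndarray | None = None,
    stim_duration: float = 3.0,
    isi: float = 2.0,
    conditions=None,
    n_stimuli: int = 4,
) -> DesignMatrix:
    """Design matrix for a single run (dummy volumes already discarded).

    Columns: one HRF-convolved boxcar per trial type present (condition-
    major, stimulus within condition), a blank regressor, a response-
    interval regressor covering the ISI after every trial, any nuisance
    columns, and a constant last.
    """
    import pandas as pd

    events = pd.DataFrame(events)
    cols, names = [], []
    trial_types: list[tuple[int, str]] = []

    if len(events):
        if events["run"].nunique() > 1:
            raise ValueError("events must belong to a single run")
        stim_ev = events[events["stimulus"] >= 0]
        if conditions is None:
            conditions = list(dict.fromkeys(stim_ev["condition"]))
        for cond in conditions:
            for stim in range(n_stimuli):
                sel = stim_ev[
                    (stim_ev["condition"] == cond) & (stim_ev["stimulus"] == stim)
                ]
                if not len(sel):
                    continue
                reg = convolve_boxcars(
                    sel["onset"].to_numpy(),
                    np.full(len(sel), stim_duration),
                    n_volumes,
                    tr,
                ).sum(axis=1)
                cols.append(reg)
                names.append(f"{cond}_s{stim}")
                trial_types.append((stim, cond))
        blanks = events[events["stimulus"] < 0]
        if len(blanks):
            reg = convolve_boxcars(
                blanks["onset"].to_numpy(),
                np.full(len(blanks), stim_duration),
                n_volumes,
                tr,
            ).sum(axis=1)
            cols.append(reg)
            names.append("blank")
        # response intervals: the ISI window after every trial
        reg = convolve_boxcars(
            events["onset"].to_numpy() + stim_duration,
            np.full(len(events), isi),
            n_volumes,
            tr,
        ).sum(axis=1)
        cols.append(reg)
        names.append("response")

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance rows must equal n_volumes")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(f"nuisance_{k}")

    cols.append(np.ones(n_volumes))
    names.append("constant")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(x, names, trial_types)


@dataclass
class TrialMaps:
    """Per-run beta and t volumes for each (stimulus, condition) trial type."""

    betas: np.ndarray         # (n_types, nx, ny, nz)
    tstats: np.ndarray        # (n_types, nx, ny, nz)
    types: list[tuple[int, str]]
    resid_var: np.ndarray     # (nx, ny, nz)
    df: int
    run: int = 0


def fit_glm(data, design: DesignMatrix, mask: np.ndarray, run: int = 0) -> TrialMaps:
    """OLS fit of a run; returns beta/t maps for the trial-type columns.

    ``data`` is a 4-D array (or NIfTI image) whose last axis matches the
    design matrix rows.  Out-of-mask voxels are NaN-filled.  t statistics
    are beta / SE; where the residual variance is exactly zero (noiseless
    data) the t value is set to 0.
    """
    if hasattr(data, "dataobj"):
        data = np.asarray(data.dataobj)
    data = np.asarray(data, dtype=float)
    x = design.matrix
    if data.shape[-1] != x.shape[0]:
        raise ValueError(
            f"data has {data.shape[-1]} volumes but design has {x.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(x)
    df = x.shape[0] - rank
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")

    mask = np.asarray(mask, dtype=bool)
    y = data[mask].T                       # (T, V)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y               # (P, V)
    resid = y - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df

    shape = data.shape[:-1]
    n_types = len(design.trial_types)
    betas = np.full((n_types,) + shape, np.nan)
    tstats = np.full((n_types,) + shape, np.nan)
    resid_var = np.full(shape, np.nan)
    resid_var[mask] = sigma2
    for k in range(n_types):
        c = np.zeros(x.shape[1])
        c[k] = 1.0
        se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
        b = beta[k]
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), 0.0)
        vol_b = np.full(shape, np.nan)
        vol_t = np.full(shape, np.nan)
        vol_b[mask] = b
        vol_t[mask] = t
        betas[k] = vol_b
        tstats[k] = vol_t
    return TrialMaps(betas, tstats, list(design.trial_types), resid_var, df, run)


def fit_runs(bold_runs, nuisance=None) -> list[TrialMaps]:
    """Fit every run of a session, stripping the flagged dummy volumes."""
    out = []
    for run_idx, run in enumerate(bold_runs):
        data = run.task_data()
        spec_cols = build_design_matrix(
            run.events,
            data.shape[-1],
            run.tr,
            nuisance=nuisance,
        )
        mask = np.ones(data.shape[:-1], dtype=bool)
        out.append(fit_glm(data, spec_cols, mask, run=run_idx))
    return out


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 3.0) -> np.ndarray:
    """3-D Gaussian smoothing for synthetic volumes (default off upstream)."""
    if fwhm_mm <= 0:
        return np.asarray(volume, dtype=float)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma)
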