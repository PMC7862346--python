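"""Synthetic single-slice resting-state cohorts with planted state dynamics.

Every downstream stage (frame clustering, matching, metrics, statistics,
classification) is exercised on cohorts produced here: recurring spatial
co-(de)activation states visited by a Markov chain with geometric dwell
times, additive Gaussian sensor noise, and optional group-specific effects
(right-ward shift of positive activation mass and occurrence-rate changes
in transgenic animals).

The generator is a test harness, not a biophysical model: no hemodynamic
convolution, no scanner drift, single 2D slice only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .config import ConfigurationError, Group, SimulationConfig

__all__ = [
    "SpatialTemplate",
    "SubjectRecording",
    "make_mask",
    "make_state_templates",
    "apply_lateral_shift",
    "simulate_subject",
    "simulate_cohort",
    "make_qpp_windows",
]


@dataclass
class SpatialTemplate:
    """One recurring co-(de)activation state on the masked grid."""

    template_id: int
    amplitude_map: np.ndarray  # (rows, cols), zero off-mask
    mask: np.ndarray  # (rows, cols) bool

    def masked_values(self) -> np.ndarray:
        return self.amplitude_map[self.mask]

    def __post_init__(self):
        if not np.any(np.abs(self.amplitude_map[self.mask]) > 0):
            raise ConfigurationError("template must activate at least one voxel")


@dataclass
class SubjectRecording:
    """One animal's masked voxel time-series plus metadata.

    ``frames`` is T x V where V is the number of in-mask voxels in
    row-major mask order.  ``true_state_sequence`` (0-based state ids) is
    only available for synthetic data.
    """

    subject_id: str
    group: Group
    frames: np.ndarray  # (T, V)
    tr_seconds: float
    mask: np.ndarray  # (rows, cols) bool
    motion_regressors: Optional[np.ndarray] = None  # (T, 6)
    true_state_sequence: Optional[np.ndarray] = None  # (T,)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x V matrix with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"frames have {self.frames.shape[1]} voxels but mask has "
                f"{int(self.mask.sum())} in-mask voxels"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.frames.shape[1]

    def replace_frames(self, frames: np.ndarray, trim: Tuple[int, int] = (0, 0)) -> "SubjectRecording":
        """Copy of this recording with new frames (and trimmed metadata)."""
        lo, hi = trim
        sl = slice(lo, self.n_frames - hi)
        return SubjectRecording(
            subject_id=self.subject_id,
            group=self.group,
            frames=frames,
            tr_seconds=self.tr_seconds,
            mask=self.mask,
            motion_regressors=None
            if self.motion_regressors is None
            else self.motion_regressors[sl],
            true_state_sequence=None
            if self.true_state_sequence is None
            else self.true_state_sequence[sl],
        )


def make_mask(grid_rows: int, grid_cols: int) -> np.ndarray:
    """Elliptical brain-like mask, mirror-symmetric across the column midline."""
    if grid_rows < 4 or grid_cols < 8:
        raise ConfigurationError("grid too small for a usable mask (need >= 4 x 8)")
    r = (np.arange(grid_rows) - (grid_rows - 1) / 2.0) / (grid_rows / 2.0)
    c = (np.arange(grid_cols) - (grid_cols - 1) / 2.0) / (grid_cols / 2.0)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    mask = rr**2 + cc**2 <= 0.95
    # enforce exact mirror symmetry (guards against float asymmetries)
    mask = mask | mask[:, ::-1]
    return mask


def _blob(grid_rows, grid_cols, row, col, sigma) -> np.ndarray:
    img = np.zeros((grid_rows, grid_cols))
    img[row, col] = 1.0
    return gaussian_filter(img, sigma, mode="constant")


def _mirror(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def make_state_templates(config: SimulationConfig) -> List[SpatialTemplate]:
    """Build ``n_states`` distinct, mirror-symmetric activation templates.

    Each template is a sum of positive and negative Gaussian blobs placed
    in the left hemisphere and mirrored to the right.  Templates are
    organized as anti-correlated pairs — state 2i+1 is a perturbed sign
    flip of state 2i — plus an unpaired final state when ``n_states`` is
    odd.  Co-activation patterns on real frame series show exactly this
    structure (e.g. a default-mode-like pattern and its inverse), and it
    is what gives the explained-variance curve its concave, saturating
    shape: each successive partition resolves one opposition, with
    diminishing occupancy.

    Pairwise Pearson correlation between templates stays below 0.9
    (paired states correlate near -1, which is maximally distant under
    correlation distance).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    rows, cols = config.grid_rows, config.grid_cols
    mask = make_mask(rows, cols)
    half = cols // 2
    left_cells = [(i, j) for i in range(rows) for j in range(half) if mask[i, j]]
    if len(left_cells) < 4 * config.n_states:
        raise ConfigurationError(
            "grid too small to place the requested number of state blobs"
        )
    sigma = max(1.0, min(rows, cols) / 12.0)

    def draw_half_pattern() -> np.ndarray:
        img = np.zeros((rows, cols))
        picks = rng.choice(len(left_cells), size=4, replace=False)
        signs = (1.0, 1.0, -1.0, -1.0)
        for p, s in zip(picks, signs):
            i, j = left_cells[p]
            img += s * rng.uniform(0.8, 1.2) * _blob(rows, cols, i, j, sigma)
        return img + _mirror(img)

    def admissible(amp: np.ndarray, prev: List[np.ndarray]):
        amp = amp * mask
        peak = np.abs(amp[mask]).max()
        if peak == 0:
            return None
        amp = amp / peak
        vals = amp[mask]
        if all(_pearson(vals, pv) < 0.9 for pv in prev):
            return amp, vals
        return None

    templates: List[SpatialTemplate] = []
    flat_prev: List[np.ndarray] = []
    base: Optional[np.ndarray] = None
    for s in range(config.n_states):
        for _attempt in range(200):
            if s % 2 == 0:
                candidate = draw_half_pattern()
                # keep pair bases mutually dissimilar (|r| < 0.5)
                vals0 = (candidate * mask)[mask]
                if any(abs(_pearson(vals0, pv)) >= 0.5 for pv in flat_prev[::2]):
                    continue
            else:
                # moderately anti-correlated counterpart of the pair's base
                # (real CAP pairs anti-correlate around r ~ -0.4, not -1)
                beta = 0.5
                fresh = draw_half_pattern()
                fresh = fresh / max(1e-12, np.abs(fresh[mask]).max())
                scale = np.abs(base[mask]).max()
                candidate = -beta * base + np.sqrt(1 - beta**2) * scale * fresh
            result = admissible(candidate, flat_prev)
            if result is not None:
                amp, vals = result
                break
        else:  # pragma: no cover - extremely unlikely with 200 draws
            raise ConfigurationError("could not draw sufficiently distinct templates")
        if s % 2 == 0:
            base = amp
        flat_prev.append(vals)
        templates.append(SpatialTemplate(template_id=s, amplitude_map=amp, mask=mask))
    return templates


def apply_lateral_shift(template: SpatialTemplate, shift: float) -> SpatialTemplate:
    """Move ``shift`` of the template's left-hemisphere positive mass to the right.

    The left-hemisphere positive amplitudes are attenuated by (1 - shift)
    and the removed mass is added to the right-hemisphere positive
    amplitudes (scaled proportionally), so total positive mass is
    conserved while the pattern becomes right-lateralized.
    """
    if shift == 0:
        return template
    amp = template.amplitude_map.copy()
    half = amp.shape[1] // 2
    left = np.zeros_like(amp, dtype=bool)
    left[:, :half] = True
    pos = amp > 0
    lmass = amp[left & pos].sum()
    rmass = amp[(~left) & pos].sum()
    amp[left & pos] *= 1.0 - shift
    if rmass > 0:
        amp[(~left) & pos] *= 1.0 + shift * lmass / rmass
    return SpatialTemplate(template.template_id, amp, template.mask)


def _transition_matrix(probs: np.ndarray, dwell_mean_frames: float) -> np.ndarray:
    """First-order chain: self-transition 1 - 1/dwell, off-diagonal ~ occupancy."""
    n = probs.size
    p_stay = 1.0 - 1.0 / dwell_mean_frames
    P = np.zeros((n, n))
    for i in range(n):
        off = probs.copy()
        off[i] = 0.0
        tot = off.sum()
        if tot <= 0:
            P[i, i] = 1.0
            continue
        P[i] = (1.0 - p_stay) * off / tot
        P[i, i] = p_stay
    return P


def _simulate_chain(probs: np.ndarray, P: np.ndarray, n_frames: int, rng) -> np.ndarray:
    states = np.empty(n_frames, dtype=int)
    cum0 = np.cumsum(probs)
    states[0] = int(np.searchsorted(cum0, rng.random()))
    cums = np.cumsum(P, axis=1)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        states[t] = int(np.searchsorted(cums[states[t - 1]], u[t - 1]))
    return states


def _motion_regressors(n_frames: int, rng) -> np.ndarray:
    """Six smooth low-frequency random walks (3 translations, 3 rotations)."""
    walks = np.cumsum(rng.normal(0.0, 0.01, size=(n_frames, 6)), axis=0)
    return gaussian_filter1d(walks, sigma=10.0, axis=0)


def simulate_subject(
    templates: Sequence[SpatialTemplate],
    config: SimulationConfig,
    group: Group,
    seed: int,
    subject_id: Optional[str] = None,
) -> SubjectRecording:
    """Simulate one animal: hidden Markov state sequence + Gaussian noise.

    Frame t equals the active state's template (the TG variant for TG
    animals when ``tg_lateral_shift`` > 0) plus i.i.d. N(0, noise_sd) per
    voxel.  The planted state sequence is recorded.
    """
    group = Group(group)
    probs = config.state_probs(group)
    if probs.size != len(templates):
        raise ConfigurationError("occurrence-probability vector length != n templates")
    rng = np.random.default_rng(int(seed))
    if group == Group.TG and config.tg_lateral_shift > 0:
        templates = [apply_lateral_shift(t, config.tg_lateral_shift) for t in templates]
    mask = templates[0].mask
    tmpl = np.stack([t.masked_values() for t in templates])  # (S, V)

    P = _transition_matrix(probs, config.dwell_mean_frames)
    states = _simulate_chain(probs, P, config.n_frames_per_subject, rng)
    frames = tmpl[states]
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    return SubjectRecording(
        subject_id=subject_id or f"{group.value}-{seed}",
        group=group,
        frames=frames,
        tr_seconds=config.tr_seconds,
        mask=mask,
        motion_regressors=_motion_regressors(config.n_frames_per_subject, rng),
        true_state_sequence=states,
    )


def simulate_cohort(config: SimulationConfig) -> List[SubjectRecording]:
    """Simulate the full cohort (n_wt WT then n_tg TG), deterministically."""
    templates = make_state_templates(config)
    ss = np.random.SeedSequence([int(config.seed), 202])
    seeds = ss.generate_state(config.n_wt + config.n_tg) % (2**31)
    cohort = []
    for i in range(config.n_wt):
        cohort.append(
            simulate_subject(templates, config, Group.WT, int(seeds[i]), f"WT{i+1:02d}")
        )
    for i in range(config.n_tg):
        cohort.append(
            simulate_subject(
                templates, config, Group.TG, int(seeds[config.n_wt + i]), f"TG{i+1:02d}"
            )
        )
    return cohort


def make_qpp_windows(
    recording: SubjectRecording, target_state: int, window_len_frames: int
) -> List[Tuple[int, int]]:
    """Non-overlapping (start, length) windows anchored at target-state frames.

    Windows are half-open [start, start + length) in 0-based frame
    indices, greedily placed left-to-right wherever the planted state
    occurs, and never extend past the end of the recording.  A state that
    never occurs yields an empty list.
    """
    if recording.true_state_sequence is None:
        raise ValueError("recording has no planted state sequence")
    if window_len_frames < 1:
        raise ValueError("window length must be >= 1")
    seq = recording.true_state_sequence
    T = seq.size
    windows: List[Tuple[int, int]] = []
    t = 0
    while t <= T - window_len_frames:
        if seq[t] == target_state:
            windows.append((t, window_len_frames))
            t += window_len_frames
        else:
            t += 1
    return windows
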