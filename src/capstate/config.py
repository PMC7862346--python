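"""Configuration objects shared across the pipeline stages.

All stage parameters live in plain dataclasses so a whole run can be
serialized to one YAML/JSON document and reproduced bit-identically from
its config + seed.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence


class ConfigurationError(ValueError):
    """Raised when a stage configuration is internally inconsistent."""


class DegenerateInputError(ValueError):
    """Raised when an input is numerically degenerate (e.g. rank-deficient)."""


class Group(str, enum.Enum):
    WT = "WT"
    TG = "TG"


def _default_occupancies(n_states: int) -> tuple:
    """Graded state occupancies, largest first.

    Real CAP occurrence rates are not uniform: dominant configurations
    recur more often than rare ones.  A mild geometric grading (ratio
    0.9) reproduces that shape without starving the rare states of
    frames.
    """
    import numpy as np

    probs = 0.9 ** np.arange(n_states)
    probs = probs / probs.sum()
    return tuple(float(p) for p in probs)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for a synthetic single-slice resting-state cohort.

    Defaults are desk-scale (32x16 grid, 600 frames) while keeping the
    cohort composition of the modelled study: 8 wild-type and 10
    transgenic animals, 7 recurring co-(de)activation states, TR 0.5 s.
    """

    grid_rows: int = 16
    grid_cols: int = 32
    n_states: int = 7
    n_frames_per_subject: int = 600
    tr_seconds: float = 0.5
    n_wt: int = 8
    n_tg: int = 10
    dwell_mean_frames: float = 10.0
    wt_state_probs: Optional[Sequence[float]] = None
    tg_state_probs: Optional[Sequence[float]] = None
    tg_lateral_shift: float = 0.0
    tg_occurrence_boost: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 2:
            raise ConfigurationError("n_states must be >= 2")
        if self.grid_cols % 2 != 0:
            raise ConfigurationError(
                "grid_cols must be even so the midline splits hemispheres"
            )
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.dwell_mean_frames < 1:
            raise ConfigurationError("dwell_mean_frames must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not (0.0 <= self.tg_lateral_shift < 1.0):
            raise ConfigurationError("tg_lateral_shift must lie in [0, 1)")
        for probs in (self.wt_state_probs, self.tg_state_probs):
            if probs is not None:
                import numpy as np

                p = np.asarray(probs, dtype=float)
                if p.size != self.n_states or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(
                        "state occurrence probabilities must be a length-n_states "
                        "non-negative vector summing to 1"
                    )

    def state_probs(self, group: "Group"):
        """Occurrence-probability vector for one group."""
        import numpy as np

        if group == Group.WT:
            if self.wt_state_probs is not None:
                return np.asarray(self.wt_state_probs, dtype=float)
            return np.asarray(_default_occupancies(self.n_states))
        if self.tg_state_probs is not None:
            return np.asarray(self.tg_state_probs, dtype=float)
        base = np.asarray(self.state_probs(Group.WT))
        if self.tg_occurrence_boost > 0:
            p = base.copy()
            p[0] = p[0] * (1.0 + self.tg_occurrence_boost)
            return p / p.sum()
        return base

    @classmethod
    def strong_effect(cls, **overrides) -> "SimulationConfig":
        """Preset with a strong planted TG effect.

        Half of the positive activation mass of every template is moved
        from the left to the right hemisphere in TG animals, and the
        dominant state occurs ~50% more often.
        """
        params = dict(tg_lateral_shift=0.5, tg_occurrence_boost=0.5)
        params.update(overrides)
        return cls(**params)

    @classmethod
    def null_effect(cls, **overrides) -> "SimulationConfig":
        """Preset with zero planted group difference."""
        params = dict(tg_lateral_shift=0.0, tg_occurrence_boost=0.0)
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class PreprocessConfig:
    """Post-realignment signal-conditioning parameters.

    The chain is: motion regression -> spatial smoothing -> FIR band-pass
    -> quadratic detrend -> unit-variance normalization -> trim/mask.
    Global-signal regression is deliberately absent.
    """

    band_low_hz: float = 0.01
    band_high_hz: float = 0.2
    smoothing_sigma_pixels: float = 2.0
    n_trim_start: int = 20
    n_trim_end: int = 20
    fir_order: Optional[int] = None  # None -> 4x slowest-period samples, capped by T
    do_motion_regression: bool = True
    zscore: bool = True

    def validate_against_tr(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise ConfigurationError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist} Hz)"
            )


def config_hash(*configs) -> str:
    """Stable short hash of one or more dataclass configs (for run logs)."""
    payload = json.dumps(
        [dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c for c in configs],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
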