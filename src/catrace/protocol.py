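"""Recording protocol and analysis configuration.

A recording is a uniformly sampled fluorescence time series with three
scheduled pharmacological events: the receptor stimulus (ATP, KCl, or DHPG),
the calcium ionophore ionomycin, and the extracellular chelator EGTA.
:class:`StimulusProtocol` is the single source of timing truth for every
other module: the synthetic generator places pulses on its grid, and the
feature extractor takes window maxima over the half-open intervals it
defines.

Windows are half-open by convention, so every frame belongs to exactly one
window and the event frame itself belongs to the window the event opens:

* baseline        ``[0, n_baseline_frames)`` (frame indices)
* receptor (RMR)  ``[t_stimulus, t_ionomycin)``
* ionomycin       ``[t_ionomycin, t_egta)``
* EGTA tail       ``[t_egta, t_end]``
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

STIMULI = ("ATP", "KCl", "DHPG")
GROUPS = ("ASD", "control")
STAGES = ("iPSC", "Diff1wk", "Diff4wk")

#: Stage vocabulary of the transcriptomic screen (differentiation course:
#: pluripotent, neural induction, neurosphere, differentiated neuron).
SCREEN_STAGES = ("iPSC", "NI", "NSP", "Diff")


@dataclass(frozen=True)
class StimulusProtocol:
    """Event timing and sampling grid of one recording.

    Defaults encode the standard 500 s acquisition: ~1 s frames, receptor
    stimulus at second 20, 4 uM ionomycin at second 200, EGTA at second 400,
    baseline defined as the first three frames.
    """

    frame_interval: float = 1.0
    t_end: float = 500.0
    t_stimulus: float = 20.0
    t_ionomycin: float = 200.0
    t_egta: float = 400.0
    n_baseline_frames: int = 3
    stimulus_name: str = "ATP"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        if not (0 < self.t_stimulus < self.t_ionomycin < self.t_egta <= self.t_end):
            raise ValidationError(
                "event times must satisfy 0 < t_stimulus < t_ionomycin < t_egta <= t_end"
            )
        if self.n_baseline_frames < 1:
            raise ValidationError("n_baseline_frames must be >= 1")
        if self.n_baseline_frames * self.frame_interval > self.t_stimulus:
            raise ValidationError("baseline window must end before the stimulus")
        if self.stimulus_name not in STIMULI:
            raise ValidationError(f"stimulus_name must be one of {STIMULI}")

    @property
    def n_frames(self) -> int:
        return int(round(self.t_end / self.frame_interval))

    @property
    def times(self) -> np.ndarray:
        """Sampling grid: frame k at time k * frame_interval, spanning [0, t_end)."""
        return np.arange(self.n_frames) * self.frame_interval

    # -- window helpers ---------------------------------------------------
    def baseline_slice(self) -> slice:
        return slice(0, self.n_baseline_frames)

    def rmr_mask(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.t_stimulus) & (times < self.t_ionomycin)

    def ionomycin_mask(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.t_ionomycin) & (times < self.t_egta)

    def egta_mask(self, times: np.ndarray) -> np.ndarray:
        return times >= self.t_egta

    @property
    def rmr_duration(self) -> float:
        return self.t_ionomycin - self.t_stimulus

    @property
    def ionomycin_duration(self) -> float:
        return self.t_egta - self.t_ionomycin

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StimulusProtocol":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class AnalysisConfig:
    """Knobs of the extraction/statistics pipeline.

    doubling_threshold
        Fold level a cell's maximum receptor-mediated response must reach to
        count as a responder ("doubled its response"); boundary inclusive.
    sem_unit_amplitude / sem_unit_fraction
        Unit over which the SEM of amplitude/time metrics (resp. responder
        percentages) is computed: "cell" pools all cells, "replicate" takes
        the spread of replicate means.
    test_unit
        Granularity of the Mann-Whitney comparison ("cell" or "replicate").
    baseline_anchor
        "start": baseline = first n_baseline_frames of the recording;
        "prestim": the n frames immediately preceding the stimulus.
        Identical for flat baselines; "start" is the default reading.
    """

    doubling_threshold: float = 2.0
    sem_unit_amplitude: str = "cell"
    sem_unit_fraction: str = "replicate"
    test_unit: str = "cell"
    baseline_anchor: str = "start"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.doubling_threshold <= 1:
            raise ValidationError("doubling_threshold must exceed 1")
        for name in ("sem_unit_amplitude", "sem_unit_fraction", "test_unit"):
            if getattr(self, name) not in ("cell", "replicate"):
                raise ValidationError(f"{name} must be 'cell' or 'replicate'")
        if self.baseline_anchor not in ("start", "prestim"):
            raise ValidationError("baseline_anchor must be 'start' or 'prestim'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)


DEFAULT_PROTOCOL = StimulusProtocol()
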