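"""Fixed-length sliding-window segmentation of labelled recordings.

Each continuous labelled interval is first clipped by ``clip_s`` at both
ends (to discard possible annotation slop at behaviour transitions), then
cut into windows of ``window_s`` advancing by ``step_s``. A window whose
end coincides exactly with the clipped interval end is admitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyDatasetError, ValidationError
from .synth import CHANNELS, InertialRecording, LabelInterval, LabelTrack

logger = logging.getLogger(__name__)

_EPS = 1e-9  # guards float noise at the inclusive end boundary


@dataclass(frozen=True)
class SegmentationConfig:
    clip_s: float = 1.0
    window_s: float = 1.3
    step_s: float = 0.5

    def __post_init__(self):
        if min(self.clip_s, self.window_s, self.step_s) <= 0:
            raise ValidationError("clip_s, window_s, step_s must all be > 0")
        if self.step_s > self.window_s:
            raise ValidationError("step_s must not exceed window_s")

    def n_window_samples(self, rate: float) -> int:
        return int(round(self.window_s * rate))


@dataclass(frozen=True)
class Window:
    individual_id: str
    group_id: str
    behaviour: str
    start_s: float
    samples: np.ndarray  # (n_window_samples, 9)
    channels: tuple[str, ...] = CHANNELS
    sampling_rate: float = 50.0


def window_count(interval_length_s: float, config: SegmentationConfig) -> int:
    """Closed-form number of windows fitting a clipped interval.

    floor((L - 2*clip - window) / step) + 1 when the clipped core admits at
    least one window, else 0.
    """
    core = interval_length_s - 2.0 * config.clip_s - config.window_s
    if core < -_EPS:
        return 0
    return int(math.floor(core / config.step_s + _EPS)) + 1


def clip_and_window(
    interval: LabelInterval,
    recording: InertialRecording,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[Window]:
    """Windows of one labelled interval; short intervals yield an empty list.

    Window k starts at ``interval.start + clip_s + k*step_s`` and must end
    at or before ``interval.end - clip_s``. Starts are snapped to sample
    boundaries; every window has exactly ``n_window_samples`` samples.
    """
    if interval.start_s < -_EPS or interval.end_s > recording.duration + _EPS:
        raise ValidationError(
            f"interval [{interval.start_s}, {interval.end_s}) outside "
            f"recording of {recording.duration} s"
        )
    rate = recording.meta.sampling_rate
    nw = config.n_window_samples(rate)
    n = window_count(interval.end_s - interval.start_s, config)
    if n == 0:
        logger.debug("interval %r too short for any window", interval)
    out = []
    for k in range(n):
        start = interval.start_s + config.clip_s + k * config.step_s
        i0 = int(round(start * rate))
        if i0 + nw > recording.n_samples:
            break  # trailing partial window (rounding at recording end)
        out.append(Window(
            recording.meta.individual_id,
            recording.meta.group_id,
            interval.behaviour,
            start,
            recording.samples[i0:i0 + nw],
            sampling_rate=rate,
        ))
    return out


def recording_windows(recording, track: LabelTrack,
                      config: SegmentationConfig = SegmentationConfig()
                      ) -> list[Window]:
    out = []
    for interval in track:
        out.extend(clip_and_window(interval, recording, config))
    return out


def dataset_windows(pairs, config: SegmentationConfig = SegmentationConfig()
                    ) -> list[Window]:
    """Windows of every (recording, label-track) pair, concatenated.

    Raises :class:`EmptyDatasetError` when no interval is long enough to
    contribute a single window.
    """
    out = []
    for recording, track in pairs:
        out.extend(recording_windows(recording, track, config))
    if not out:
        raise EmptyDatasetError(
            "segmentation produced no windows; every labelled interval is "
            f"shorter than {2 * config.clip_s + config.window_s} s"
        )
    by_class: dict[str, int] = {}
    by_ind: dict[str, int] = {}
    for w in out:
        by_class[w.behaviour] = by_class.get(w.behaviour, 0) + 1
        by_ind[w.individual_id] = by_ind.get(w.individual_id, 0) + 1
    logger.info("windows per class: %s; per individual: %s", by_class, by_ind)
    return out
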