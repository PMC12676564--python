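"""Exclusion rule, epoch construction, and segment splitting.

A recording is eligible iff its stimulus interval is strictly longer than 30 s.
Each eligible interval contributes a fixed number of partially overlapping 24-s
epochs whose starts are evenly spaced across the interval, and each epoch is cut
into 12 contiguous non-overlapping 2-s segments — the unit on which DMD runs.

Time-to-sample convention, applied everywhere: start sample = floor(t * fs),
half-open windows ``[s, s + n)``, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecording, StimulusInterval

EPOCH_LEN = 24.0      #: epoch length, seconds
SEG_LEN = 2.0         #: segment length, seconds
N_EPOCHS = 10         #: epochs per eligible recording
MIN_DURATION = 30.0   #: exclusion threshold, seconds (retain iff duration > this)


class InfeasibleEpochingError(ValueError):
    pass


@dataclass
class Epoch:
    """One 24-s window of a recording (channels x samples, 19 x 12000 at 500 Hz)."""

    subject_id: str
    epoch_index: int
    start: float            # absolute start time, seconds
    data: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class Segment:
    """One 2-s slice of an epoch (channels x samples, 19 x 1000 at 500 Hz)."""

    subject_id: str
    epoch_index: int
    segment_index: int
    data: np.ndarray
    fs: float

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


def apply_exclusion(intervals, min_duration: float = MIN_DURATION):
    """Split intervals into (eligible, excluded) by the usable-duration rule.

    A recording is retained iff ``offset - onset > min_duration`` (strictly).
    On the published 88-subject stimulus table this excludes exactly four
    recordings (subjects 15, 64, 65, 78).
    """
    eligible = [iv for iv in intervals if iv.duration > min_duration]
    excluded = [iv for iv in intervals if iv.duration <= min_duration]
    return eligible, excluded


def make_epochs(rec: EEGRecording, interval: StimulusInterval,
                n_epochs: int = N_EPOCHS, epoch_len: float = EPOCH_LEN
                ) -> list[Epoch]:
    """Carve ``n_epochs`` evenly spaced, partially overlapping epochs from the
    stimulus interval.

    Start times are ``onset + i * (duration - epoch_len) / (n_epochs - 1)``; even
    spacing is the unique scheme that uses the full interval and equalizes
    overlap while giving every subject the same epoch count.  Callers must run
    :func:`apply_exclusion` first: intervals no longer than ``epoch_len`` are
    infeasible.
    """
    duration = interval.duration
    if duration <= epoch_len:
        raise InfeasibleEpochingError(
            f"interval duration {duration:.2f}s <= epoch length {epoch_len}s")
    n_samp = int(round(epoch_len * rec.fs))
    if n_epochs < 2:
        starts = [interval.onset]
    else:
        step = (duration - epoch_len) / (n_epochs - 1)
        starts = [interval.onset + i * step for i in range(n_epochs)]
    epochs = []
    for i, start in enumerate(starts):
        s0 = int(np.floor(start * rec.fs))
        if s0 + n_samp > rec.n_samples:
            raise InfeasibleEpochingError(
                f"epoch {i} of subject {rec.subject_id} extends past the "
                f"recording end ({(s0 + n_samp) / rec.fs:.2f}s > "
                f"{rec.duration:.2f}s)")
        epochs.append(Epoch(rec.subject_id, i, start,
                            rec.data[:, s0:s0 + n_samp], rec.fs))
    return epochs


def segment_epoch(epoch: Epoch, seg_len: float = SEG_LEN) -> list[Segment]:
    """Cut an epoch into contiguous non-overlapping segments of ``seg_len``.

    The epoch length must be an exact multiple of ``seg_len``; concatenating
    the returned segments reproduces the epoch matrix.
    """
    n_seg_samp = int(round(seg_len * epoch.fs))
    n_total = epoch.data.shape[1]
    if n_total % n_seg_samp != 0:
        raise ValueError(
            f"epoch length {n_total} samples is not divisible by segment "
            f"length {n_seg_samp} samples")
    n_segs = n_total // n_seg_samp
    return [
        Segment(epoch.subject_id, epoch.epoch_index, j,
                epoch.data[:, j * n_seg_samp:(j + 1) * n_seg_samp], epoch.fs)
        for j in range(n_segs)
    ]
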