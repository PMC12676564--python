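"""Seeded synthetic eyes-open EEG cohorts.

The generator emulates the statistical structure the pipeline assumes: 19-channel
recordings at 500 Hz, a single photic-stimulation interval per subject, band-limited
oscillatory components with group-dependent amplitude and scalp topography, an SSVEP
term locked to the stimulus, and 1/f background noise synthesized by spectral shaping
of white noise.

Group signatures are configuration, not code.  The defaults encode the qualitative
eyes-open picture for the three diagnostic groups: a posterior 10 Hz alpha rhythm in
controls (partially suppressed relative to eyes-closed), generalized 6 Hz theta
elevation with reduced alpha in the AD-like group, and anterior-temporal theta
emphasis in the FTD-like group.  Any other contrast — including a null contrast for
calibration — is constructible by passing explicit ``band_components``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import EEGRecording, StimulusInterval, MONTAGE_10_20, GROUPS

_POSTERIOR = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")
_ANTERIOR = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "T4")


def _topography(labels, emphasized, base=0.3, peak=1.0):
    """Weight vector with ``peak`` on emphasized electrodes, ``base`` elsewhere."""
    return np.array([peak if lbl in emphasized else base for lbl in labels])


def default_band_components(labels=MONTAGE_10_20) -> dict:
    """Per-group list of (frequency Hz, topography weights, amplitude uV)."""
    flat = np.ones(len(labels))
    post = _topography(labels, _POSTERIOR)
    ant = _topography(labels, _ANTERIOR)
    return {
        # CN: partially suppressed but still posterior-dominant alpha (3x the
        # AD-like amplitude), diffuse beta
        "CN": [(10.0, post, 4.5), (20.0, flat, 1.0), (6.0, flat, 1.0)],
        # AD-like: generalized slowing — elevated theta, reduced alpha
        "AD": [(10.0, post, 1.5), (20.0, flat, 1.0), (6.0, flat, 3.0)],
        # FTD-like: anterior-temporal theta emphasis, reduced posterior activity
        "FTD": [(10.0, post, 2.0), (20.0, flat, 1.0), (6.0, ant, 3.0)],
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``band_components`` maps each group to a list of
    ``(frequency_hz, topography, amplitude_uv)`` triples; topography vectors must
    have length ``n_channels``.  ``noise_exponent`` is the slope of the 1/f
    background (power ~ f**-exponent) and ``noise_scale`` its per-channel RMS in
    microvolts.  The SSVEP term (``stim_frequency``/``stim_amplitude``) is added
    only inside the stimulus interval.
    """

    n_subjects_per_group: int = 5
    duration: float = 90.0
    fs: float = 500.0
    n_channels: int = 19
    band_components: Mapping[str, Sequence[tuple]] = field(
        default_factory=default_band_components)
    stim_frequency: float = 15.0
    stim_amplitude: float = 1.0
    stim_onset: float = 10.0
    stim_offset: float | None = None  # default: duration - 2 s
    noise_exponent: float = 1.0
    noise_scale: float = 3.0
    seed: int = 0
    groups: tuple = GROUPS
    channel_labels: tuple = MONTAGE_10_20

    def __post_init__(self):
        if self.n_channels != len(self.channel_labels):
            self.channel_labels = tuple(f"ch{i}" for i in range(self.n_channels))
        if self.stim_offset is None:
            self.stim_offset = self.duration - 2.0
        nyq = self.fs / 2
        for group, comps in self.band_components.items():
            for f, topo, amp in comps:
                if amp < 0:
                    raise ValueError("component amplitudes must be >= 0")
                if f >= nyq:
                    raise ValueError(f"component frequency {f} >= Nyquist {nyq}")
                if len(np.atleast_1d(topo)) != self.n_channels:
                    raise ValueError(
                        f"topography for group {group} must have length "
                        f"{self.n_channels}")
        if self.stim_amplitude < 0 or self.noise_scale < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (0 <= self.stim_onset < self.stim_offset <= self.duration):
            raise ValueError("stimulus interval must lie within the recording")


def null_contrast(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with identical band components for every group.

    The CN component set is used for all groups, so any downstream classifier
    sees pure noise-level differences between groups (chance-level contrast).
    """
    cn = spec.band_components["CN"]
    return replace(spec, band_components={g: cn for g in spec.groups})


def _pink_noise(rng, n_channels, n_samples, fs, exponent, scale):
    """1/f^exponent noise by spectral shaping of white Gaussian noise.

    The amplitude spectrum is shaped as f**(-exponent/2) so the periodogram
    slope on log-log axes is -exponent.  DC is zeroed; the result is rescaled
    to per-channel RMS ``scale``.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return scale * shaped / rms


def generate_recording(spec: CohortSpec, subject_index: int, group: str
                       ) -> tuple[EEGRecording, StimulusInterval]:
    """One subject's recording plus its stimulus interval, deterministically
    seeded from ``(spec.seed, subject_index)``."""
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng([spec.seed, subject_index])
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    data = np.zeros((spec.n_channels, n))
    for f, topo, amp in spec.band_components[group]:
        phase = rng.uniform(0, 2 * np.pi)
        data += amp * np.outer(np.atleast_1d(topo), np.sin(2 * np.pi * f * t + phase))
    interval = StimulusInterval(f"S{subject_index:03d}", spec.stim_onset,
                                spec.stim_offset)
    if spec.stim_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        on = (t >= interval.onset) & (t < interval.offset)
        data[:, on] += spec.stim_amplitude * np.sin(
            2 * np.pi * spec.stim_frequency * t[on] + phase)
    if spec.noise_scale > 0:
        data += _pink_noise(rng, spec.n_channels, n, spec.fs,
                            spec.noise_exponent, spec.noise_scale)
    rec = EEGRecording(interval.subject_id, group, data, spec.fs,
                       spec.channel_labels)
    return rec, interval


def generate_cohort(spec: CohortSpec):
    """All subjects of all groups: list of (EEGRecording, StimulusInterval).

    Subject indices run consecutively across groups so every subject has a
    distinct deterministic seed stream.
    """
    out = []
    idx = 0
    for group in spec.groups:
        for _ in range(spec.n_subjects_per_group):
            out.append(generate_recording(spec, idx, group))
            idx += 1
    return out
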