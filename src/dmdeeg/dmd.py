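"""Hankel shift-stack Dynamic Mode Decomposition of short EEG segments.

DMD approximates a multichannel time series by a linear evolution
``y_{k+1} ~= A y_k`` and eigendecomposes a low-dimensional SVD surrogate of A.
Each eigenvalue ``lambda_j`` encodes one mode's oscillation frequency (and
growth/decay) through ``omega_j = Im(log lambda_j) / (2 pi dt)`` in Hz; the
associated mode vector ``phi_j`` gives its spatial (channel) pattern.

Because a 2-s, 19-channel EEG segment has far fewer channels than dynamical
degrees of freedom, the segment is first time-delay embedded: ``S`` shifted
copies of the signal are stacked row-block-wise into an ``(M S) x (N - S + 1)``
Hankel matrix, enriching the spectrum DMD can resolve.  The reference
configuration for 2-s segments at 500 Hz uses ``S = 48`` and truncation rank
``R = 100``, giving a 912 x 953 Hankel matrix for 19 channels.

The band-filtered mode-magnitude map (:func:`mode_map`) keeps the modes whose
eigenfrequencies fall in a passband (4-40 Hz in the main analysis, 0.5-40 Hz
when the delta band is retained), sorts them by ascending frequency, and
returns per-channel magnitudes — the raw material for the 50x50 feature images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .epochs import Segment

DEFAULT_STACK = 48
DEFAULT_RANK = 100
#: main-analysis passband (delta excluded) and the delta-retaining alternative
BAND_NO_DELTA = (4.0, 40.0)
BAND_WITH_DELTA = (0.5, 40.0)

#: relative singular-value floor: components below ``RANK_GUARD * sigma_max``
#: are truncated before inverting Sigma, preventing noise amplification.
RANK_GUARD = 1e-12


@dataclass
class HankelMatrix:
    """Shift-stack Hankel embedding of one segment.

    ``values`` has shape ``(M*S, N - S + 1)``: block-row ``s`` (0-based) holds
    the segment delayed by ``s`` samples.
    """

    values: np.ndarray
    M: int
    S: int
    dt: float

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class DMDResult:
    """Modes, eigenvalues, and amplitudes of one segment's DMD.

    ``modes`` is complex ``(M*S) x R``; ``eigenvalues`` length-R complex;
    ``amplitudes`` the least-squares solution of ``Phi c ~= y_1``.  For real
    input the eigenvalue multiset is closed under conjugation.
    """

    modes: np.ndarray
    eigenvalues: np.ndarray
    amplitudes: np.ndarray
    rank: int
    dt: float
    M: int
    S: int
    n_snapshots: int = 0

    @property
    def is_empty(self) -> bool:
        return self.rank == 0


@dataclass
class ModeMap:
    """Band-filtered per-channel mode magnitudes, columns in ascending frequency.

    ``magnitudes`` is a nonnegative ``M x K`` matrix; ``frequencies`` the K
    retained eigenfrequencies in Hz, all inside ``band``.  ``K`` varies from
    segment to segment (and may be 0), which is why the downstream image step
    interpolates to a fixed raster.
    """

    magnitudes: np.ndarray
    frequencies: np.ndarray
    band: tuple

    @property
    def K(self) -> int:
        return self.magnitudes.shape[1]


def build_hankel(segment, S: int, dt: float | None = None) -> HankelMatrix:
    """Shift-stack a segment into its ``(M*S) x (N - S + 1)`` Hankel matrix.

    ``segment`` may be a :class:`~dmdeeg.epochs.Segment` or a plain
    channels-x-samples array (then ``dt`` is required).  ``S = 1`` returns the
    segment itself.
    """
    if isinstance(segment, Segment):
        X, dt = segment.data, segment.dt
    else:
        X = np.asarray(segment)
        if dt is None:
            raise ValueError("dt is required when passing a bare array")
    if X.ndim != 2:
        raise ValueError("segment must be channels x samples")
    M, N = X.shape
    if S < 1:
        raise ValueError("stack size S must be >= 1")
    if S >= N:
        raise ValueError(f"stack size S={S} must be < number of samples N={N}")
    n_cols = N - S + 1
    Y = np.empty((M * S, n_cols), dtype=X.dtype)
    for s in range(S):
        Y[s * M:(s + 1) * M, :] = X[:, s:s + n_cols]
    return HankelMatrix(Y, M=M, S=S, dt=float(dt))


def fit_dmd(hankel: HankelMatrix, R: int = DEFAULT_RANK,
            mode_convention: str = "exact") -> DMDResult:
    """Fit the DMD operator on a Hankel matrix and eigendecompose it.

    The snapshot matrix is split into ``Y1`` (columns 1..N_S-1) and ``Y2``
    (columns 2..N_S); the least-squares propagator is represented by its
    rank-r SVD surrogate ``A_tilde = U* Y2 V Sigma^-1`` with
    ``r = min(R, numerical rank of Y1)``.  Eigenvectors ``W`` of ``A_tilde``
    are lifted to data space as exact-DMD modes ``Phi = Y2 V Sigma^-1 W``
    (``mode_convention="projected"`` uses ``Phi = U W`` instead).  Amplitudes
    solve ``min ||Phi c - y_1||`` in the least-squares sense; with tall
    ``Phi`` the anchor ``y_1 = Phi c`` is generally not exactly satisfiable.

    All-zero input yields an empty (rank-0) result rather than NaNs.
    """
    if R < 1:
        raise ValueError("truncation rank R must be >= 1")
    if mode_convention not in ("exact", "projected"):
        raise ValueError(f"unknown mode convention {mode_convention!r}")
    Y = hankel.values
    if Y.shape[1] < 2:
        raise ValueError("need at least 2 snapshots")
    if not np.any(Y):
        warnings.warn("all-zero segment: returning empty DMD result")
        cdtype = np.result_type(Y.dtype, np.complex64)
        empty = np.zeros((Y.shape[0], 0), dtype=cdtype)
        return DMDResult(empty, np.zeros(0, cdtype), np.zeros(0, cdtype),
                         rank=0, dt=hankel.dt, M=hankel.M, S=hankel.S)
    Y1, Y2 = Y[:, :-1], Y[:, 1:]
    max_rank = Y1.shape[1]
    if R > max_rank:
        warnings.warn(f"rank R={R} exceeds snapshot count {max_rank}; clipping")
        R = max_rank
    U, s, Vh = scipy.linalg.svd(Y1, full_matrices=False, lapack_driver="gesdd")
    n_keep = int(np.sum(s > RANK_GUARD * s[0]))
    r = min(R, n_keep)
    U, s, Vh = U[:, :r], s[:r], Vh[:r, :]
    # A_tilde = U* Y2 V Sigma^-1  (r x r surrogate of the propagator)
    B = (Y2 @ Vh.conj().T) / s  # = Y2 V Sigma^-1, reused for exact modes
    A_tilde = U.conj().T @ B
    eigvals, W = np.linalg.eig(A_tilde)
    Phi = B @ W if mode_convention == "exact" else U @ W
    y1 = Y[:, 0].astype(Phi.dtype)
    amplitudes = np.linalg.lstsq(Phi, y1, rcond=None)[0]
    return DMDResult(Phi, eigvals, amplitudes, rank=r, dt=hankel.dt,
                     M=hankel.M, S=hankel.S, n_snapshots=Y.shape[1])


def eigenfrequencies(result: DMDResult, return_index: bool = False):
    """Signed mode frequencies in Hz: ``Im(log lambda_j) / (2 pi dt)``.

    Uses the principal branch of the complex logarithm, so frequencies lie in
    ``(-fs/2, fs/2]``.  Zero eigenvalues (log undefined) are dropped with a
    warning; with ``return_index=True`` the surviving eigenvalue indices are
    returned alongside.
    """
    if result.dt <= 0:
        raise ValueError("dt must be positive")
    lam = result.eigenvalues
    nonzero = lam != 0
    if not np.all(nonzero):
        warnings.warn(f"dropping {int(np.sum(~nonzero))} zero eigenvalue(s)")
    idx = np.flatnonzero(nonzero)
    freqs = np.log(lam[idx]).imag / (2 * np.pi * result.dt)
    return (freqs, idx) if return_index else freqs


def reconstruct(result: DMDResult, k: int) -> np.ndarray:
    """Snapshot ``k`` (1-based) of the DMD approximation: ``Phi Lambda^{k-1} c``.

    Returns the real part (length ``M*S``); for real data the imaginary
    residual is at round-off level when conjugate pairs are intact.
    """
    if k < 1:
        raise ValueError("snapshot index k is 1-based")
    if result.is_empty:
        return np.zeros(result.M * result.S)
    vec = result.modes @ (result.eigenvalues ** (k - 1) * result.amplitudes)
    return vec.real


def reconstruct_series(result: DMDResult, n_times: int) -> np.ndarray:
    """Channel-level reconstruction ``x_tilde`` of the original series.

    Evaluates ``x_tilde_i(t_k) = sum_j lambda_j^{k-1} Phi(i,j) c_j`` for
    ``i = 1..M`` (the first block row of the stacked mode vectors) and
    ``k = 1..n_times``, returning an ``M x n_times`` real matrix.
    """
    if result.is_empty:
        return np.zeros((result.M, n_times))
    powers = result.eigenvalues[:, None] ** np.arange(n_times)[None, :]
    series = result.modes[: result.M, :] @ (powers * result.amplitudes[:, None])
    return series.real


def _mode_weights(result: DMDResult, idx: np.ndarray, weighting: str):
    """Column scale factors turning raw mode vectors into contribution maps.

    Eigendecomposition returns unit-norm eigenvectors, so raw exact-DMD mode
    columns all have comparable norm regardless of how much signal they carry;
    the energy bookkeeping lives in the amplitudes ``c`` (and in ``|lambda|``,
    which governs decay across the window).  ``"amplitude"`` scales column j
    by ``|c_j|``; ``"sustained"`` (default) additionally multiplies by the
    mean of ``|lambda_j|^(k-1)`` over the fitted snapshots, i.e. the mode's
    average amplitude across the segment, which suppresses fast-decaying noise
    modes relative to persistent oscillations.  ``"none"`` leaves raw ``|phi|``.
    """
    if weighting == "none":
        return np.ones(idx.size)
    w = np.abs(result.amplitudes[idx])
    if weighting == "sustained" and result.n_snapshots >= 2:
        n = result.n_snapshots
        r = np.abs(result.eigenvalues[idx])
        with np.errstate(over="ignore", invalid="ignore"):
            sustain = np.where(np.isclose(r, 1.0),
                               1.0, (1 - r ** n) / (n * (1 - r)))
        w = w * np.where(np.isfinite(sustain), sustain, 1.0)
    return w


def mode_map(result: DMDResult, band: tuple = BAND_NO_DELTA,
             reduction: str = "first_block",
             weighting: str = "sustained") -> ModeMap:
    """Band-filtered mode-magnitude matrix, columns sorted by ascending frequency.

    Eigenfrequency-mode pairs are sorted ascending in frequency and only those
    with ``lo <= omega <= hi`` retained (negative-frequency conjugate partners
    fall outside any positive band automatically).  Magnitudes are ``|phi|``
    reduced from the stacked ``(M*S)``-row mode vector to ``M`` rows either by
    taking the first block row (the unshifted copy of the signal; default) or
    by averaging the magnitude over all ``S`` block rows
    (``reduction="block_mean"``), then scaled per column according to
    ``weighting`` (see :func:`_mode_weights`) so that a column's brightness
    tracks the mode's actual contribution to the segment.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    if reduction not in ("first_block", "block_mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if weighting not in ("sustained", "amplitude", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if result.is_empty:
        return ModeMap(np.zeros((result.M, 0)), np.zeros(0), (lo, hi))
    freqs, idx = eigenfrequencies(result, return_index=True)
    order = np.argsort(freqs, kind="stable")
    freqs, idx = freqs[order], idx[order]
    keep = (freqs >= lo) & (freqs <= hi)
    freqs, idx = freqs[keep], idx[keep]
    if freqs.size == 0:
        warnings.warn("no modes inside the passband; empty mode map")
        return ModeMap(np.zeros((result.M, 0)), freqs, (lo, hi))
    mags = np.abs(result.modes[:, idx])
    if reduction == "first_block":
        mags = mags[: result.M, :]
    else:
        mags = mags.reshape(result.S, result.M, -1).mean(axis=0)
    mags = mags * _mode_weights(result, idx, weighting)
    return ModeMap(mags, freqs, (lo, hi))
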