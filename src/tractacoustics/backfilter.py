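"""Glottal back-filtering: from microphone audio to glottal source signals.

The FEM transfer functions are approximated by stable discrete-time filters
at fs = 20 kHz (twice the 10 kHz analysis band).  Recorded sound pressure is
high-pass filtered (10th-order Butterworth at 0.8 f_o, zero phase),
resampled to 20 kHz, Hann-windowed, and deconvolved with the impulse
response of the glottis-to-lips filter to recover the glottal particle
velocity v_g(t); the glottal pressure p_g(t) then follows by filtering
v_g with the glottis-to-glottis filter.

Deconvolution is time-domain polynomial long division (exact inverse of
discrete convolution for finite sequences); when the impulse response is
ill-conditioned for the recursion, a regularized frequency-domain division
is used instead and recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal as sps

from .helmholtz import TransferFunction
from .synthetic import AudioSignal

__all__ = [
    "IIRFilter",
    "GlottalSignals",
    "DeconvolutionResult",
    "preprocess_audio",
    "fit_iir",
    "impulse_response",
    "deconvolve",
    "glottal_pressure",
]

TARGET_FS = 20000.0


@dataclass
class IIRFilter:
    """Rational discrete-time approximant of a transfer function.

    Invariants: real coefficients, leading denominator coefficient 1, and
    every denominator root strictly inside the unit circle (checked on
    construction).  ``fit_rms_error`` is the RMS of ``|H - H_hat|`` over the
    design grid, in the units of the fitted transfer-function kind.
    """

    b: np.ndarray
    a: np.ndarray
    fs: float = TARGET_FS
    kind: str = ""
    fit_rms_error: float = np.nan

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.a[0] == 0:
            raise ValueError("leading denominator coefficient must be nonzero")
        if self.a[0] != 1.0:
            self.b = self.b / self.a[0]
            self.a = self.a / self.a[0]
        pm = self.max_pole_magnitude()
        if pm >= 1.0:
            raise ValueError(f"unstable filter: max pole magnitude {pm:.6f} >= 1")

    def max_pole_magnitude(self) -> float:
        a = np.trim_zeros(self.a, "b")
        if len(a) <= 1:
            return 0.0
        return float(np.abs(np.roots(a)).max())

    def response(self, frequencies: np.ndarray) -> np.ndarray:
        """Complex response at the given frequencies (Hz)."""
        w = 2.0 * np.pi * np.asarray(frequencies) / self.fs
        _, h = sps.freqz(self.b, self.a, worN=w)
        return h


@dataclass
class GlottalSignals:
    """Back-computed glottal particle velocity (m/s) and pressure (Pa)."""

    v_g: np.ndarray
    p_g: np.ndarray
    fs: float
    f_o: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.v_g = np.asarray(self.v_g, dtype=float)
        self.p_g = np.asarray(self.p_g, dtype=float)
        if len(self.v_g) != len(self.p_g):
            raise ValueError("v_g and p_g must share one time base")
        if not (np.isfinite(self.v_g).all() and np.isfinite(self.p_g).all()):
            raise ValueError("non-finite glottal signals")


def preprocess_audio(p: AudioSignal, f_o: float) -> AudioSignal:
    """High-pass (10th-order Butterworth, corner 0.8 f_o, zero phase) and
    resample to 20 kHz.

    Zero-phase application runs the filter forward and backward, so the
    magnitude response is applied twice (-6 dB at the corner).
    """
    if p.fs < TARGET_FS:
        raise ValueError(f"fs {p.fs} Hz < 20 kHz: audio must cover the 10 kHz band")
    sos = sps.butter(10, 0.8 * f_o, btype="highpass", fs=p.fs, output="sos")
    x = sps.sosfiltfilt(sos, p.samples)
    if not np.isclose(p.fs, TARGET_FS):
        from fractions import Fraction

        frac = Fraction(int(round(TARGET_FS)), int(round(p.fs)))
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_target = int(round(len(p.samples) * TARGET_FS / p.fs))
    x = x[:n_target]
    return AudioSignal(samples=x, fs=TARGET_FS, calibration=p.calibration, f_o=f_o)


# ---------------------------------------------------------------------------
# filter fitting
# ---------------------------------------------------------------------------


def _design_matrix(theta: np.ndarray, n: int) -> np.ndarray:
    return np.exp(-1j * np.outer(theta, np.arange(n)))


def _real_lstsq(A: np.ndarray, y: np.ndarray, rcond: float = 1e-6) -> np.ndarray:
    """Least squares with complex equations and real unknowns.

    Small singular values are truncated (``rcond`` relative to the largest):
    when the design grid covers only part of the Nyquist band the complex
    exponential basis is nearly collinear, and untruncated least squares
    returns enormous coefficients that behave wildly off the grid.
    """
    As = np.concatenate([A.real, A.imag])
    ys = np.concatenate([y.real, y.imag])
    x, *_ = np.linalg.lstsq(As, ys, rcond=rcond)
    return x


def fit_iir(
    tf: TransferFunction,
    n: int = 256,
    n_poles: int = 0,
    fs: float = TARGET_FS,
    sk_iterations: int = 8,
) -> IIRFilter:
    """Least-squares rational approximation of a sampled frequency response.

    With ``n_poles = 0`` (default) the fit is a length-``n`` numerator over a
    trivial denominator — an exact linear least-squares problem on the grid,
    unconditionally stable, with error non-increasing in ``n``.  With
    ``n_poles > 0`` a Sanathanan-Koerner iteration fits a pole-zero model;
    any unstable poles are reflected inside the unit circle (which preserves
    the magnitude response shape) and the numerator is refit.
    """
    if n < 2:
        raise ValueError("numerator length n must be >= 2")
    f = np.asarray(tf.frequencies, dtype=float)
    H = np.asarray(tf.values, dtype=complex)
    ok = np.isfinite(H)
    f, H = f[ok], H[ok]
    theta = 2.0 * np.pi * f / fs
    Eb = _design_matrix(theta, n)

    if n_poles == 0:
        if len(theta) < 8:
            raise ValueError(
                f"grid too sparse: {len(theta)} frequencies cannot support a fit"
            )
        rows, targets = [Eb], [H]
        # a grid stopping short of Nyquist leaves half the basis unconstrained;
        # extend the target with a zero (band-limiting) response up to fs/2
        df = float(np.median(np.diff(f))) if len(f) > 1 else fs / (2 * n)
        if f.max() < 0.49 * fs:
            f_ext = np.arange(f.max() + df, fs / 2.0, df)
            if len(f_ext):
                E_ext = _design_matrix(2.0 * np.pi * f_ext / fs, n)
                rows.append(0.3 * E_ext)
                targets.append(np.zeros(len(f_ext), dtype=complex))
        # mild ridge keeps the coefficients bounded in any residual null space
        lam = 1e-4 * float(np.sqrt(np.mean(np.abs(H) ** 2))) + 1e-300
        rows.append(lam * np.eye(n).astype(complex))
        targets.append(np.zeros(n, dtype=complex))
        b = _real_lstsq(np.concatenate(rows), np.concatenate(targets))
        a = np.zeros(n)
        a[0] = 1.0
        hhat = Eb @ b
        err = float(np.sqrt(np.mean(np.abs(H - hhat) ** 2)))
        return IIRFilter(b=b, a=a, fs=fs, kind=tf.kind, fit_rms_error=err)

    Ea = _design_matrix(theta, n_poles + 1)[:, 1:]
    w = np.ones(len(theta))
    ba = None
    for _ in range(max(1, sk_iterations)):
        A = np.concatenate([Eb * w[:, None], -(H * w)[:, None] * Ea], axis=1)
        ba = _real_lstsq(A, H * w)
        a_full = np.concatenate([[1.0], ba[n:]])
        w = 1.0 / np.maximum(np.abs(_design_matrix(theta, n_poles + 1) @ a_full), 1e-12)
    a_full = np.concatenate([[1.0], ba[n:]])
    roots = np.roots(a_full)
    outside = np.abs(roots) >= 1.0
    if outside.any():
        roots[outside] = roots[outside] / np.abs(roots[outside]) ** 2 * (1 - 1e-9)
        a_full = np.real(np.poly(roots))
    # final numerator refit with the (stabilized) denominator fixed
    Aresp = _design_matrix(theta, len(a_full)) @ a_full
    wf = 1.0 / np.maximum(np.abs(Aresp), 1e-12)
    b = _real_lstsq(Eb * wf[:, None], H * Aresp * wf)
    if not np.isfinite(b).all():
        raise RuntimeError("IIR fit diverged: non-finite numerator")
    hhat = (Eb @ b) / Aresp
    err = float(np.sqrt(np.mean(np.abs(H - hhat) ** 2)))
    return IIRFilter(b=b, a=a_full, fs=fs, kind=tf.kind, fit_rms_error=err)


def impulse_response(filt: IIRFilter, length: int = 4096) -> np.ndarray:
    """First ``length`` samples of the unit-impulse response.

    Warns when the truncated tail still carries more than 1e-4 of the total
    impulse-response energy (estimated over twice the requested length).
    """
    x = np.zeros(2 * length)
    x[0] = 1.0
    h = sps.lfilter(filt.b, filt.a, x)
    total = float(np.sum(h**2))
    if total > 0 and float(np.sum(h[length:] ** 2)) > 1e-4 * total:
        warnings.warn(
            f"impulse response truncated at {length} samples still carries "
            ">1e-4 of its energy in the tail",
            stacklevel=2,
        )
    return h[:length]


@dataclass
class DeconvolutionResult:
    v_g: np.ndarray
    method: str  # "long-division" or "frequency-domain"


def deconvolve(
    p_sound: AudioSignal | np.ndarray,
    h: np.ndarray,
    regularization: float = 1e-8,
) -> DeconvolutionResult:
    """Recover the source sequence ``v`` with ``conv(v, h) = p``.

    Polynomial long division: exact for finite sequences, with output length
    ``len(p) - len(h) + 1``.  Falls back to regularized frequency-domain
    division when the leading impulse-response sample is tiny or the
    recursion blows up (non-minimum-phase ``h``); the method used is
    recorded in the result.
    """
    p = p_sound.samples if isinstance(p_sound, AudioSignal) else np.asarray(p_sound, float)
    h = np.asarray(h, dtype=float)
    hmax = np.abs(h).max()
    if hmax == 0:
        raise ValueError("all-zero impulse response")
    nz = np.nonzero(np.abs(h) > 1e-14 * hmax)[0]
    h_trim = h[nz[0] :]
    n_out = len(p) - len(h) + 1
    if n_out < 1:
        raise ValueError("input shorter than the impulse response")

    def freq_fallback() -> np.ndarray:
        N = int(2 ** np.ceil(np.log2(len(p) + len(h))))
        Hf = np.fft.rfft(h, N)
        Pf = np.fft.rfft(p, N)
        Vf = Pf * np.conj(Hf) / (np.abs(Hf) ** 2 + regularization * np.abs(Hf).max() ** 2)
        return np.fft.irfft(Vf, N)[:n_out]

    if np.abs(h_trim[0]) < 1e-6 * hmax:
        return DeconvolutionResult(freq_fallback(), "frequency-domain")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # the recursion may overflow for non-minimum-phase h; that case is
        # detected below and handed to the frequency-domain fallback
        warnings.simplefilter("ignore")
        v, _ = sps.deconvolve(p, h_trim)
    v = v[:n_out]
    bound = 1e9 * np.abs(p).max() / np.abs(h_trim[0])
    if not np.isfinite(v).all() or np.abs(v).max() > bound:
        return DeconvolutionResult(freq_fallback(), "frequency-domain")
    return DeconvolutionResult(v, "long-division")


def glottal_pressure(v_g: np.ndarray, filt_gg: IIRFilter) -> np.ndarray:
    """Glottal pressure: direct-form filtering of v_g with the H_gg filter."""
    return sps.lfilter(filt_gg.b, filt_gg.a, np.asarray(v_g, dtype=float))


def save_filter(path, filt: IIRFilter) -> None:
    """Write filter coefficients as JSON {kind, fs, b, a, fit_rms_error}."""
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "kind": filt.kind,
                "fs": filt.fs,
                "b": filt.b.tolist(),
                "a": filt.a.tolist(),
                "fit_rms_error": None
                if np.isnan(filt.fit_rms_error)
                else filt.fit_rms_error,
            },
            fh,
        )


def load_filter(path) -> IIRFilter:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return IIRFilter(
        b=np.asarray(d["b"]),
        a=np.asarray(d["a"]),
        fs=d["fs"],
        kind=d.get("kind", ""),
        fit_rms_error=d["fit_rms_error"] if d.get("fit_rms_error") is not None else np.nan,
    )
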