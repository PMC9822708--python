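"""Glottal sound-intensity efficiency measures.

The central quantity is the instantaneous sound intensity at the glottis,

    I(t) = p_g(t) * v_g(t)   [W/m^2],

the product of the back-computed glottal pressure and particle velocity.
I(t) is smoothed by a moving average spanning 100 fundamental periods, the
magnitude of its analytic signal (Hilbert envelope) is taken, and the
effective intensity I_eff is the RMS of that envelope over the valid region
(one smoothing window trimmed from each end).  Multiplying by the glottal
area A_g gives the radiated-at-the-glottis sound power P_eff = I_eff * A_g.

For equal-loudness comparison the microphone signal is first normalized to
-23 LUFS (EBU R 128); because the whole back-filtering chain is linear, the
normalized intensity follows from the same pipeline run on the scaled
audio.  L_eq = 20 log10(p_rms / 20 uPa) at the microphone serves as a
plausibility check.  Lower I_eff at equal loudness marks a vocal-tract
configuration that needs less source intensity for the same output — a more
efficient shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sps

from .backfilter import GlottalSignals, IIRFilter, deconvolve, glottal_pressure
from .loudness import integrated_loudness, normalize_loudness
from .synthetic import AudioSignal

__all__ = [
    "IntensityResult",
    "sound_intensity",
    "smooth_and_envelope",
    "effective_intensity",
    "loudness_normalize",
    "leq",
    "efficiency_report",
]

P_REF = 20e-6  # Pa, SPL reference


@dataclass
class IntensityResult:
    """Efficiency measures for one task (raw and loudness-normalized)."""

    I_eff: float  # W/m^2
    P_eff: float  # W
    I_eff_norm: float
    P_eff_norm: float
    A_g: float  # m^2
    L_eq: float  # dB SPL at the microphone
    L_eq_norm: float
    f_o: float | None = None

    def __post_init__(self):
        assert self.I_eff >= 0 and self.I_eff_norm >= 0
        if not np.isclose(self.P_eff, self.I_eff * self.A_g):
            raise ValueError("P_eff must equal I_eff * A_g")

    def intensity_level_dB(self) -> float:
        """10 log10(I_eff / 1 W m^-2)."""
        return 10.0 * np.log10(self.I_eff)


def sound_intensity(g: GlottalSignals) -> np.ndarray:
    """Instantaneous intensity I(t) = p_g(t) v_g(t), W/m^2."""
    if len(g.p_g) != len(g.v_g):
        raise ValueError("p_g and v_g must have equal length")
    return g.p_g * g.v_g


def smooth_and_envelope(
    I_t: np.ndarray, f_o: float, fs: float
) -> tuple[np.ndarray, np.ndarray, slice]:
    """Moving average over 100 periods, then Hilbert envelope.

    Returns ``(smoothed, envelope, valid)`` where ``valid`` is the slice
    excluding one smoothing window at each end (edge transients of both the
    moving average and the analytic signal).
    """
    I_t = np.asarray(I_t, dtype=float)
    win = int(round(100.0 * fs / f_o))
    if len(I_t) <= win:
        raise ValueError(
            f"signal ({len(I_t)} samples) shorter than the 100-period "
            f"smoothing window ({win} samples)"
        )
    kernel = np.full(win, 1.0 / win)
    smoothed = sps.fftconvolve(I_t, kernel, mode="same")
    envelope = np.abs(sps.hilbert(smoothed))
    valid = slice(win, max(win + 1, len(I_t) - win))
    return smoothed, envelope, valid


def effective_intensity(envelope: np.ndarray, valid: slice | None = None) -> float:
    """RMS of the intensity envelope over the valid region."""
    env = np.asarray(envelope, dtype=float)
    if valid is not None:
        env = env[valid]
    if len(env) == 0:
        raise ValueError("empty valid region")
    return float(np.sqrt(np.mean(env**2)))


def loudness_normalize(
    p: AudioSignal, target_lufs: float = -23.0
) -> tuple[AudioSignal, float]:
    """Normalize audio to the target integrated loudness (default -23 LUFS).

    Returns the scaled signal and the applied gain in dB.  Rejects silence
    (below the absolute gate).
    """
    scaled, gain_db = normalize_loudness(p.samples, p.fs, target_lufs)
    out = AudioSignal(samples=scaled, fs=p.fs, calibration=p.calibration, f_o=p.f_o)
    return out, gain_db


def leq(p: AudioSignal) -> float:
    """Equivalent continuous sound pressure level, dB SPL re 20 uPa."""
    pa = p.pascals
    rms = float(np.sqrt(np.mean(pa**2)))
    if rms == 0:
        raise ValueError("silent signal has no defined L_eq")
    return 20.0 * np.log10(rms / P_REF)


def glottal_signals_from_audio(
    p_mic: AudioSignal,
    h_gl: np.ndarray,
    filt_gg: IIRFilter,
    window: bool = True,
) -> GlottalSignals:
    """Back-filter microphone audio to glottal velocity and pressure.

    The (already preprocessed) segment is Hann-windowed, deconvolved with
    the glottis-to-lips impulse response to v_g, and filtered with the
    glottis-to-glottis filter to p_g.
    """
    x = p_mic.pascals
    if window:
        x = x * np.hanning(len(x))
    res = deconvolve(x, h_gl)
    v_g = res.v_g
    p_g = glottal_pressure(v_g, filt_gg)
    return GlottalSignals(
        v_g=v_g, p_g=p_g, fs=p_mic.fs, f_o=p_mic.f_o,
        metadata={"deconvolution": res.method},
    )


def efficiency_report(
    g: GlottalSignals,
    p_mic: AudioSignal,
    A_g: float,
    h_gl: np.ndarray | None = None,
    filt_gg: IIRFilter | None = None,
) -> IntensityResult:
    """Compose the efficiency measures for one task.

    The normalized quantities re-run the back-filtering on the -23 LUFS
    version of the microphone audio when the filters are supplied; without
    them, linearity of the chain is used (intensity scales with the square
    of the loudness gain).
    """
    f_o = g.f_o or p_mic.f_o
    if f_o is None:
        raise ValueError("fundamental frequency required for smoothing window")
    I_t = sound_intensity(g)
    _, env, valid = smooth_and_envelope(I_t, f_o, g.fs)
    I_eff = effective_intensity(env, valid)

    p_norm, gain_db = loudness_normalize(p_mic)
    if h_gl is not None and filt_gg is not None:
        g_norm = glottal_signals_from_audio(p_norm, h_gl, filt_gg)
        I_tn = sound_intensity(g_norm)
        _, env_n, valid_n = smooth_and_envelope(I_tn, f_o, g_norm.fs)
        I_eff_norm = effective_intensity(env_n, valid_n)
    else:
        I_eff_norm = I_eff * 10.0 ** (gain_db / 10.0)

    return IntensityResult(
        I_eff=I_eff,
        P_eff=I_eff * A_g,
        I_eff_norm=I_eff_norm,
        P_eff_norm=I_eff_norm * A_g,
        A_g=A_g,
        L_eq=leq(p_mic),
        L_eq_norm=leq(p_norm),
        f_o=f_o,
    )
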