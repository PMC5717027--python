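"""Monophonic audio to stimulus streams.

The pipeline mirrors classic speech front-ends: a short-time Fourier
transform with a window whose duration matches the note length, the
highest spectral peak per window as the instantaneous pitch f(t), optional
resampling of the track, and delay embedding
eta(t) = (f(t), f(t + tau), ..., f(t + (m-1) tau)) to code ordered
multi-note phrases as vectors.  WAV I/O goes through scipy.io.wavfile
(PCM only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidInputError
from .series import StimulusSeries
from .synth import MelodySpec

__all__ = [
    "PitchTrack",
    "EmbeddingSpec",
    "read_wav",
    "write_wav",
    "synthesize_melody_wav",
    "track_peak_frequency",
    "resample_track",
    "delay_embed",
]

_PCM_SCALE = {np.dtype("int16"): 32768.0, np.dtype("int32"): 2147483648.0}


@dataclass
class PitchTrack:
    """A uniformly sampled pitch track f(t) in Hz.

    ``freqs`` may contain NaN for windows where no pitch could be measured
    (silence); such samples are dropped when the track is turned into a
    stimulus stream.
    """

    freqs: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float).ravel()
        if self.freqs.size == 0:
            raise InvalidInputError("pitch track is empty")
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")
        valid = self.freqs[np.isfinite(self.freqs)]
        if np.any(valid <= 0):
            raise InvalidInputError("pitch values must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.freqs)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.freqs) / self.rate

    def to_series(self) -> StimulusSeries:
        """Scalar stimulus stream; missing (NaN) samples are dropped."""
        ok = np.isfinite(self.freqs)
        if not ok.any():
            raise InvalidInputError("pitch track has no valid samples")
        return StimulusSeries(values=self.freqs[ok], dt=1.0 / self.rate, t0=self.t0)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time": self.times, "freq": self.freqs}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PitchTrack":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        if "time" not in df.columns or "freq" not in df.columns:
            raise FormatError(f"{path}: expected columns time, freq")
        t = df["time"].to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(freqs=df["freq"].to_numpy(dtype=float), rate=rate, t0=float(t[0]))


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay embedding: dim consecutive pitch values spaced by ``delay``
    seconds (one beat), coding a multi-beat phrase as a vector."""

    delay: float = 0.75
    dim: int = 4

    def __post_init__(self):
        if self.delay <= 0:
            raise InvalidInputError("delay must be positive")
        if self.dim < 1:
            raise InvalidInputError("dim must be >= 1")


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as a mono float waveform in [-1, 1].

    Multi-channel input is averaged to mono; the native sampling rate is
    preserved.  Returns ``(samples, rate)``.
    """
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        data = data.astype(float) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, int(rate)


def write_wav(path, samples: np.ndarray, rate: int) -> None:
    """Write a mono float waveform in [-1, 1] as 16-bit PCM WAV."""
    from scipy.io import wavfile

    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(rate), (x * 32767.0).astype(np.int16))


def synthesize_melody_wav(
    spec: MelodySpec = MelodySpec(),
    fs: int = 8000,
    amplitude: float = 0.5,
    seed: int | None = None,
    ramp: float = 0.01,
) -> np.ndarray:
    """Render the song as phase-continuous pure tones (a test fixture for
    the pitch tracker).

    With a seed, each beat's frequency is jittered by N(0, jitter_sd) to
    mimic a performer's intonation; without one the tones are exact.  A
    short raised-cosine ramp at each beat boundary avoids clicks.
    """
    n_beats = spec.reps * len(spec.sequence)
    spb = int(round(spec.beat * fs))
    freqs = np.asarray([spec.tuning[spec.sequence[b % len(spec.sequence)]] for b in range(n_beats)])
    if seed is not None and spec.jitter_sd > 0:
        rng = np.random.default_rng(seed)
        freqs = freqs + spec.jitter_sd * rng.standard_normal(n_beats)
    inst = np.repeat(freqs, spb)
    phase = 2.0 * np.pi * np.cumsum(inst) / fs
    wave = amplitude * np.sin(phase)
    if ramp > 0:
        nr = min(int(ramp * fs), spb // 2)
        if nr > 0:
            env = np.ones(spb)
            win = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
            env[:nr] = win
            env[-nr:] = win[::-1]
            wave = wave * np.tile(env, n_beats)
    return wave


def track_peak_frequency(
    samples: np.ndarray,
    rate: int,
    window: float = 0.75,
    hop: float = 0.125,
    window_fn: str = "hann",
    band: tuple = (80.0, 2000.0),
) -> PitchTrack:
    """Pitch track by highest-spectral-peak extraction.

    A window of ``window`` seconds slides in steps of ``hop`` seconds; in
    each position the magnitude spectrum is searched for its maximum
    within ``band`` (Hz) and the peak frequency is refined by parabolic
    interpolation of the log-magnitude over the three bins around the
    maximum.  Silent (all-zero) windows yield NaN.  Track rate = 1/hop and
    track times refer to window centers.
    """
    x = np.asarray(samples, dtype=float).ravel()
    nwin = int(round(window * rate))
    nhop = int(round(hop * rate))
    if nwin < 2:
        raise InvalidInputError("window too short: need window * rate >= 2")
    if nhop < 1:
        raise InvalidInputError("hop must be positive")
    if len(x) < nwin:
        raise InvalidInputError("signal shorter than one analysis window")
    if window_fn == "hann":
        w = np.hanning(nwin)
    elif window_fn in ("rect", "rectangular", "boxcar"):
        w = np.ones(nwin)
    else:
        raise InvalidInputError(f"unknown window function {window_fn!r}")
    freqs_axis = np.fft.rfftfreq(nwin, d=1.0 / rate)
    in_band = (freqs_axis >= band[0]) & (freqs_axis <= band[1])
    if not in_band.any():
        raise InvalidInputError(f"band {band} contains no FFT bin at this window length")
    band_idx = np.where(in_band)[0]

    n_frames = 1 + (len(x) - nwin) // nhop
    out = np.empty(n_frames)
    tiny = np.finfo(float).tiny
    for i in range(n_frames):
        frame = x[i * nhop : i * nhop + nwin]
        if not np.any(frame):
            out[i] = np.nan
            continue
        mag = np.abs(np.fft.rfft(frame * w))
        k = band_idx[np.argmax(mag[band_idx])]
        if 0 < k < len(mag) - 1:
            la, lb, lc = np.log(mag[k - 1 : k + 2] + tiny)
            denom = la - 2.0 * lb + lc
            delta = 0.5 * (la - lc) / denom if denom < 0 else 0.0
        else:
            delta = 0.0
        out[i] = (k + delta) * rate / nwin
    return PitchTrack(freqs=out, rate=1.0 / hop, t0=window / 2.0)


def resample_track(track: PitchTrack, rate: float) -> PitchTrack:
    """Nearest-sample resampling of a pitch track onto a uniform grid at
    the new rate (same time span)."""
    if rate <= 0:
        raise InvalidInputError("rate must be positive")
    if rate == track.rate:
        return PitchTrack(freqs=track.freqs.copy(), rate=track.rate, t0=track.t0)
    n_new = max(int(round(len(track.freqs) * rate / track.rate)), 1)
    t_new = np.arange(n_new) / rate
    idx = np.clip(np.round(t_new * track.rate).astype(int), 0, len(track.freqs) - 1)
    return PitchTrack(freqs=track.freqs[idx], rate=rate, t0=track.t0)


def delay_embed(track: PitchTrack, spec: EmbeddingSpec = EmbeddingSpec()) -> StimulusSeries:
    """Delay-embed a pitch track into m-dimensional phrase vectors.

    eta(t) = (f(t), f(t + tau), ..., f(t + (m-1) tau)), emitted at the
    track rate for every t where all components exist; rows containing a
    missing (NaN) pitch are dropped.  Output length is
    ``len(track) - (m-1) * round(tau * rate)``.
    """
    lag = int(round(spec.delay * track.rate))
    if spec.dim > 1 and lag < 1:
        raise InvalidInputError("delay is below one track sample")
    n_out = len(track.freqs) - (spec.dim - 1) * lag
    if n_out < 1:
        raise InvalidInputError(
            f"track too short for embedding: need more than {(spec.dim - 1) * lag} samples"
        )
    cols = [track.freqs[j * lag : j * lag + n_out] for j in range(spec.dim)]
    vals = np.stack(cols, axis=-1)
    ok = np.all(np.isfinite(vals), axis=1)
    if not ok.any():
        raise InvalidInputError("no complete phrase vector without missing pitches")
    return StimulusSeries(values=vals[ok], dt=1.0 / track.rate, t0=track.t0)
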