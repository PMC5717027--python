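"""End-to-end experiment drivers.

These compose the primitive operations into the two musical experiments
(note discovery on a 1-D landscape, phrase discovery on a delay-embedded
4-D landscape) for either the synthetic melody generator or a recorded
monophonic WAV performance.  They are what the command-line interface and
the acceptance checks call.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .audio import (
    EmbeddingSpec,
    PitchTrack,
    delay_embed,
    read_wav,
    resample_track,
    track_peak_frequency,
)
from .flow import MinimaSet, descend, find_minima
from .kernel import Kernel
from .landscape import GridLandscape, MeshfreeLandscape, learn
from .series import StimulusSeries
from .synth import MelodySpec, gen_melody

__all__ = [
    "learn_notes",
    "melody_note_analysis",
    "melody_phrase_analysis",
    "wav_pitch_track",
    "wav_note_analysis",
    "wav_phrase_analysis",
    "quantize_to_notes",
    "phrase_counts",
    "reconstruct_sequence",
]

SIGMA_NOTE = float(np.sqrt(5.0))  # kernel width (Hz) used for musical stimuli


def learn_notes(
    series: StimulusSeries,
    sigma_z: float = SIGMA_NOTE,
    k: float = 0.0,
    form: str = "V",
    substeps: int = 1,
    snapshot_every: int | None = None,
):
    """Stream a scalar pitch series into a fresh 1-D grid landscape."""
    L = GridLandscape.for_series(series, Kernel(sigma_z, 1), k=k, form=form)
    return learn(L, series, substeps=substeps, snapshot_every=snapshot_every)


def melody_note_analysis(
    spec: MelodySpec = MelodySpec(),
    seed: int = 0,
    sigma_z: float = SIGMA_NOTE,
    k: float = 0.0,
    n_starts: int = 64,
) -> dict:
    """Synthetic counterpart of the note-discovery experiment: jittered
    melody -> 1-D V-form landscape -> minima catalogue."""
    series = gen_melody(spec, seed=seed)
    L, _ = learn_notes(series, sigma_z=sigma_z, k=k, form="V")
    minima = find_minima(L, n_starts=n_starts, seed=seed + 1)
    return {"series": series, "landscape": L, "minima": minima}


def quantize_to_notes(vector, tuning: dict) -> tuple:
    """Map each component of a phrase vector to the nearest tuned note name."""
    names = list(tuning)
    freqs = np.asarray([tuning[n] for n in names])
    return tuple(names[int(np.argmin(np.abs(freqs - f)))] for f in np.atleast_1d(vector))


def phrase_counts(series_values: np.ndarray, tuning: dict) -> Counter:
    """How often each (quantized) phrase occurs among embedded vectors."""
    c: Counter = Counter()
    for v in np.atleast_2d(series_values):
        c[quantize_to_notes(v, tuning)] += 1
    return c


def melody_phrase_analysis(
    spec: MelodySpec = MelodySpec(),
    seed: int = 0,
    sigma_z: float = SIGMA_NOTE,
    k: float = 0.0,
    dim: int = 4,
    n_starts: int = 400,
) -> dict:
    """Synthetic counterpart of the phrase-discovery experiment.

    The jittered pitch stream is delay-embedded into ``dim``-beat phrase
    vectors, absorbed into a mesh-free landscape, and the phrase memories
    are recovered by restart descent.  Restarts are drawn from the
    embedded samples themselves: in four dimensions the dents fill a
    vanishing fraction of the bounding box, so uniform starts would almost
    surely sit on flat foam.

    The result bundles the minima, a ranked phrase table (deepest first,
    with each minimum quantized to note names and its occurrence count in
    the stream), and the song reconstructed from beat-aligned recognition.
    """
    series = gen_melody(spec, seed=seed)
    track = PitchTrack(freqs=series.values[:, 0], rate=spec.rate)
    emb = delay_embed(track, EmbeddingSpec(delay=spec.beat, dim=dim))
    kern = Kernel(sigma_z, dim)
    M = MeshfreeLandscape(kernel=kern, k=k)
    learn(M, emb)
    # a single absorbed sample presses a dent of depth g(0)/n; memories
    # must be imprinted by more than a couple of events to count
    minima = find_minima(
        M, n_starts=n_starts, seed=seed + 1, starts=emb.values, min_depth=2.5 * kern.g0 / emb.n
    )

    counts = phrase_counts(emb.values, spec.tuning)
    table = []
    for i in range(len(minima)):
        notes = quantize_to_notes(minima.locations[i], spec.tuning)
        table.append(
            {
                "rank": i + 1,
                "phrase": "".join(notes),
                "depth": float(minima.depths[i]),
                "basin_count": int(minima.basin_counts[i]),
                "occurrences": counts.get(notes, 0),
                **{f"f{j + 1}": float(minima.locations[i][j]) for j in range(dim)},
            }
        )
    recon = reconstruct_sequence(M, minima, track, spec, dim=dim)
    return {
        "series": series,
        "embedded": emb,
        "landscape": M,
        "minima": minima,
        "table": table,
        "reconstruction": recon,
    }


def reconstruct_sequence(
    landscape,
    minima: MinimaSet,
    track: PitchTrack,
    spec: MelodySpec,
    dim: int = 4,
) -> list:
    """Rebuild the note sequence from beat-aligned phrase recognition.

    At each beat boundary the phrase vector starting there is recognized
    (reset-and-descend); the recognized minimum's first component names
    the note on that beat, and the final phrase contributes its remaining
    components.  Unrecognized phrases contribute None entries.
    """
    spb = int(round(spec.beat * spec.rate))
    emb = delay_embed(track, EmbeddingSpec(delay=spec.beat, dim=dim))
    n_phrases = emb.n // spb + (1 if emb.n % spb else 0)
    # the match radius must cover performer jitter, including outliers that
    # settle in a micro-dent beside the main minimum; it stays far below
    # half the minimal category separation (>= 24 Hz), so no ambiguity
    radius = 6.0 * landscape.kernel.sigma_z
    notes: list = []
    last_vec = None
    for b in range(n_phrases):
        i = min(b * spb, emb.n - 1)
        tr = descend(landscape, emb.values[i], record_path=False)
        idx = minima.match(tr.endpoint, radius=radius)
        if idx is None:
            notes.append(None)
            last_vec = None
            continue
        vec = minima.locations[idx]
        notes.append(quantize_to_notes(vec[:1], spec.tuning)[0])
        last_vec = vec
    if last_vec is not None:
        notes.extend(quantize_to_notes(last_vec[1:], spec.tuning))
    else:
        notes.extend([None] * (dim - 1))
    return notes


# ------------------------------------------------------------ WAV route


def wav_pitch_track(
    path,
    window: float = 0.75,
    hop: float = 0.125,
    resample_rate: float | None = 8.0,
    band: tuple = (80.0, 2000.0),
    window_fn: str = "hann",
) -> PitchTrack:
    """WAV file -> pitch track at the working rate (default 8 Hz)."""
    samples, fs = read_wav(path)
    track = track_peak_frequency(samples, fs, window=window, hop=hop, band=band, window_fn=window_fn)
    if resample_rate is not None and resample_rate != track.rate:
        track = resample_track(track, resample_rate)
    return track


def wav_note_analysis(
    path,
    sigma_z: float = SIGMA_NOTE,
    k: float = 0.0,
    n_starts: int = 64,
    seed: int = 0,
    **track_kwargs,
) -> dict:
    """Full note-discovery pipeline on a recorded monophonic performance."""
    track = wav_pitch_track(path, **track_kwargs)
    series = track.to_series()
    L, _ = learn_notes(series, sigma_z=sigma_z, k=k, form="V")
    minima = find_minima(L, n_starts=n_starts, seed=seed + 1)
    return {"track": track, "series": series, "landscape": L, "minima": minima}


def wav_phrase_analysis(
    path,
    tuning: dict,
    sigma_z: float = SIGMA_NOTE,
    k: float = 0.0,
    dim: int = 4,
    delay: float = 0.75,
    n_starts: int = 400,
    seed: int = 0,
    **track_kwargs,
) -> dict:
    """Full phrase-discovery pipeline on a recorded monophonic performance."""
    track = wav_pitch_track(path, **track_kwargs)
    emb = delay_embed(track, EmbeddingSpec(delay=delay, dim=dim))
    kern = Kernel(sigma_z, dim)
    M = MeshfreeLandscape(kernel=kern, k=k)
    learn(M, emb)
    minima = find_minima(
        M, n_starts=n_starts, seed=seed + 1, starts=emb.values, min_depth=2.5 * kern.g0 / emb.n
    )
    counts = phrase_counts(emb.values, tuning)
    table = []
    for i in range(len(minima)):
        notes = quantize_to_notes(minima.locations[i], tuning)
        table.append(
            {
                "rank": i + 1,
                "phrase": "".join(notes),
                "depth": float(minima.depths[i]),
                "basin_count": int(minima.basin_counts[i]),
                "occurrences": counts.get(notes, 0),
                **{f"f{j + 1}": float(minima.locations[i][j]) for j in range(dim)},
            }
        )
    return {"track": track, "embedded": emb, "landscape": M, "minima": minima, "table": table}
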