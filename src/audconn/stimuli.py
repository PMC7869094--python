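"""Stochastic figure-ground (SFG) stimulus generation.

An SFG stimulus is a sequence of abutting short chords.  Each chord contains
a random cloud of pure tones ("background") drawn from a fixed logarithmic
frequency grid.  A "figure" — a small set of frequencies that repeats
unchanged chord after chord — is superimposed for part of the stimulus.
Because figure and background occupy the same frequency range, the figure
can only be detected by integrating across time (temporal coherence), not by
spectral separation.

The listener's task is to report whether a brief gap interrupted the figure.
On gap-in-figure trials the figure tones are omitted from a few consecutive
chords; on the remaining trials an equal number of background tones is
omitted instead, so the two trial types are energetically matched.

Level of the figure relative to the background is expressed as a
target-to-masker ratio (TMR) in dB, applied as an RMS ratio between the
summed figure tones and the summed background tones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "SFGParams",
    "SFGStimulus",
    "build_frequency_grid",
    "sample_stimulus",
    "synthesize_waveform",
    "write_wav",
    "write_chord_manifest",
]


@dataclass(frozen=True)
class SFGParams:
    """Structural parameters of one figure-ground stimulus.

    Defaults give a 3.1-s stimulus of 62 abutting 50-ms chords, with a
    42-chord, 3-component figure starting at chord 10, and a 4-chord
    (200-ms) gap whose onset falls 20-42 chords after stimulus onset.
    """

    chord_dur: float = 0.050          # s
    ramp_dur: float = 0.010           # s, raised-cosine on/off ramp
    freq_lo: float = 179.0            # Hz
    freq_hi: float = 7246.0           # Hz
    grid_step: float = 1.0 / 24.0     # octaves between grid frequencies
    n_bg_min: int = 5
    n_bg_max: int = 15
    n_fig: int = 3                    # figure components
    n_fig_chords: int = 42            # figure duration in chords
    n_bg_chords: int = 62             # stimulus duration in chords
    fig_onset_chords: int = 10        # figure onset (chords after stimulus onset)
    gap_chords: int = 4               # gap duration in chords
    gap_onset_min: int = 20           # earliest gap onset (chords after stimulus onset)
    gap_onset_max: int = 42           # latest gap onset
    sample_rate: float = 44100.0      # Hz

    def __post_init__(self) -> None:
        if not (0 < self.freq_lo < self.freq_hi):
            raise ValueError("require 0 < freq_lo < freq_hi")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        counts = (self.n_bg_min, self.n_bg_max, self.n_fig_chords,
                  self.n_bg_chords, self.gap_chords)
        if any(c <= 0 for c in counts) or self.n_fig < 0:
            raise ValueError("counts must be positive")
        if self.fig_onset_chords + self.n_fig_chords > self.n_bg_chords:
            raise ValueError("figure must end within the stimulus")

    @property
    def duration(self) -> float:
        """Total stimulus duration in seconds."""
        return self.n_bg_chords * self.chord_dur


@dataclass
class SFGStimulus:
    """One sampled figure-ground trial: tone lists per chord plus metadata.

    ``chords[k]`` lists the background tone frequencies of chord *k*;
    ``figure_freqs`` lists the (constant) figure frequencies.  The rendered
    waveform is attached by :func:`synthesize_waveform`.
    """

    chords: list[np.ndarray]
    figure_freqs: np.ndarray
    figure_chords: np.ndarray          # chord indices containing figure tones
    gap_in_figure: bool
    gap_onset: int                     # chord index of first gap chord
    params: SFGParams
    waveform: np.ndarray | None = None
    tmr_db: float | None = None
    bg_removed: dict[int, np.ndarray] = field(default_factory=dict)


def build_frequency_grid(params: SFGParams) -> np.ndarray:
    """Logarithmic tone-frequency grid from ``freq_lo`` up to ``freq_hi``.

    Consecutive grid frequencies are separated by ``grid_step`` octaves;
    the grid starts exactly at ``freq_lo`` and stops at the last frequency
    not exceeding ``freq_hi``.
    """
    n = int(np.floor(np.log2(params.freq_hi / params.freq_lo) / params.grid_step)) + 1
    return params.freq_lo * 2.0 ** (params.grid_step * np.arange(n))


def sample_stimulus(params: SFGParams, gap_in_figure: bool,
                    rng: np.random.Generator) -> SFGStimulus:
    """Draw the chord-by-chord tone content of one stimulus.

    Background tone counts are uniform on [n_bg_min, n_bg_max] per chord and
    frequencies are re-drawn independently for every chord.  Figure
    frequencies are drawn once (without replacement) and repeat in every
    figure chord.  The gap removes either the figure tones (gap-in-figure
    trials) or ``n_fig`` background tones per chord (gap-in-background
    trials) from ``gap_chords`` consecutive chords; in both cases the gap
    lies inside the figure interval.
    """
    grid = build_frequency_grid(params)
    fig_lo = params.fig_onset_chords
    fig_hi = params.fig_onset_chords + params.n_fig_chords  # half-open

    # gap onset: uniform integer on [gap_onset_min, gap_onset_max], clipped
    # so the gap ends while the figure is present
    hi = min(params.gap_onset_max, fig_hi - params.gap_chords)
    lo = max(params.gap_onset_min, fig_lo)
    if lo > hi:
        raise ValueError("gap cannot be placed inside the figure interval")
    gap_onset = int(rng.integers(lo, hi + 1))
    gap_set = set(range(gap_onset, gap_onset + params.gap_chords))

    fig_freqs = rng.choice(grid, size=params.n_fig, replace=False) if params.n_fig else np.empty(0)

    chords: list[np.ndarray] = []
    bg_removed: dict[int, np.ndarray] = {}
    for k in range(params.n_bg_chords):
        n_bg = int(rng.integers(params.n_bg_min, params.n_bg_max + 1))
        if not gap_in_figure and k in gap_set:
            # background gap: need at least n_fig background tones to remove
            while n_bg < params.n_fig:
                n_bg = int(rng.integers(params.n_bg_min, params.n_bg_max + 1))
        tones = rng.choice(grid, size=n_bg, replace=False)
        if not gap_in_figure and k in gap_set:
            drop = rng.choice(n_bg, size=params.n_fig, replace=False)
            bg_removed[k] = tones[drop].copy()
            tones = np.delete(tones, drop)
        chords.append(np.sort(tones))

    if params.n_fig:
        fig_chords = [k for k in range(fig_lo, fig_hi)
                      if not (gap_in_figure and k in gap_set)]
    else:
        fig_chords = []

    return SFGStimulus(
        chords=chords,
        figure_freqs=np.sort(fig_freqs),
        figure_chords=np.asarray(fig_chords, dtype=int),
        gap_in_figure=gap_in_figure,
        gap_onset=gap_onset,
        params=params,
        bg_removed=bg_removed,
    )


def _tone_bank(freqs: np.ndarray, params: SFGParams) -> np.ndarray:
    """Sum of unit-amplitude ramped sinusoids lasting one chord."""
    n = int(round(params.chord_dur * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    if freqs.size == 0:
        return np.zeros(n)
    x = np.sin(2 * np.pi * np.asarray(freqs)[:, None] * t[None, :]).sum(axis=0)
    n_ramp = int(round(params.ramp_dur * params.sample_rate))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env = np.ones(n)
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    return x * env


def _render_parts(stim: SFGStimulus, params: SFGParams) -> tuple[np.ndarray, np.ndarray]:
    """Render background and figure contributions separately (unit tones)."""
    n_chord = int(round(params.chord_dur * params.sample_rate))
    n_total = params.n_bg_chords * n_chord
    bg = np.zeros(n_total)
    fig = np.zeros(n_total)
    fig_set = set(int(k) for k in stim.figure_chords)
    for k, tones in enumerate(stim.chords):
        sl = slice(k * n_chord, (k + 1) * n_chord)
        bg[sl] = _tone_bank(tones, params)
        if k in fig_set:
            fig[sl] = _tone_bank(stim.figure_freqs, params)
    return bg, fig


def synthesize_waveform(stim: SFGStimulus, params: SFGParams | None = None,
                        tmr_db: float = 0.0) -> np.ndarray:
    """Render the stimulus to audio at a given TMR.

    Each tone is a sinusoid lasting one chord with raised-cosine on/off
    ramps; chords abut with no inter-chord silence.  Figure tones are scaled
    so that 20*log10(RMS_figure / RMS_background) = ``tmr_db``.  The result
    is peak-normalized to 0.9 and attached to ``stim.waveform``.
    """
    params = params or stim.params
    if params.sample_rate < 2 * params.freq_hi:
        raise ValueError(
            f"sample_rate {params.sample_rate} Hz aliases tones up to {params.freq_hi} Hz")
    if not stim.chords:
        raise ValueError("stimulus has no chords; run sample_stimulus first")
    bg, fig = _render_parts(stim, params)
    rms_bg = np.sqrt(np.mean(bg ** 2))
    rms_fig = np.sqrt(np.mean(fig ** 2))
    if rms_fig > 0 and rms_bg > 0:
        gain = 10 ** (tmr_db / 20) * rms_bg / rms_fig
    else:
        gain = 1.0
    y = bg + gain * fig
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.9 * y / peak
    stim.waveform = y
    stim.tmr_db = tmr_db
    return y


def write_wav(stim: SFGStimulus, path: str | Path) -> Path:
    """Write the synthesized waveform as 32-bit float WAV."""
    if stim.waveform is None:
        raise ValueError("waveform not synthesized; call synthesize_waveform first")
    path = Path(path)
    wavfile.write(path, int(stim.params.sample_rate),
                  stim.waveform.astype(np.float32))
    return path


def write_chord_manifest(stim: SFGStimulus, path: str | Path) -> Path:
    """CSV manifest: one row per chord with tone list and figure/gap flags."""
    path = Path(path)
    gap = set(range(stim.gap_onset, stim.gap_onset + stim.params.gap_chords))
    fig = set(int(k) for k in stim.figure_chords)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chord", "figure", "gap", "background_hz", "figure_hz"])
        for k, tones in enumerate(stim.chords):
            w.writerow([
                k, int(k in fig), int(k in gap),
                ";".join(f"{f:.2f}" for f in tones),
                ";".join(f"{f:.2f}" for f in stim.figure_freqs) if k in fig else "",
            ])
    return path
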