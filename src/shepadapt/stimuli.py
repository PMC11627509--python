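"""Shepard-tone stimuli: single tones, biased sequences, and spectrograms.

A Shepard tone is a complex tone made of equal-amplitude, octave-spaced
partials; its identity on the pitch circle is the pitch class (semitones
re a 440 Hz anchor, modulo 12).  Two sequence paradigms are generated:

* the *biased pair*: a bias sequence of 5 or 10 Shepard tones drawn from
  a 5-semitone range above ("up") or below ("down") the first test tone,
  a silent gap, then an ambiguous pair separated by half an octave;
* *biased tuning*: long sequences in which 5 of every 6 tones come from
  one of four bias regions and every 6th tone probes the whole octave on
  a 0.5-semitone grid.

Model-facing stimuli are time x circular-pitch-bin spectrograms at the
simulation sampling rate (default 20 Hz, i.e. 50 ms frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .circular import wrap_pc

ANCHOR_HZ = 440.0  # pitch class 0
DEFAULT_BAND = (30.0, 16000.0)  # audible band for synthesis, Hz

Role = Literal["lead_in", "bias", "probe", "test1", "test2"]


@dataclass(frozen=True)
class ShepardTone:
    """A single Shepard tone (pitch-class-labelled complex tone)."""

    pitch_class: float
    duration: float = 0.1  # s
    level: float = 70.0  # dB SPL
    ramp: float = 5.0  # ms, sinusoidal on/off gates
    phase_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pitch_class", float(wrap_pc(self.pitch_class)))
        if self.duration <= 0:
            raise ValueError("tone duration must be positive")
        if self.ramp < 0:
            raise ValueError("ramp must be nonnegative")
        if 2 * self.ramp / 1000.0 > self.duration:
            raise ValueError("ramps longer than the tone itself")


@dataclass(frozen=True)
class ToneEvent:
    onset: float  # s
    tone: ShepardTone
    role: Role


@dataclass(frozen=True)
class BiasMeta:
    center: float  # pitch class of the bias-range center
    range: float  # semitones covered by the bias
    direction: Literal["up", "down"]
    length: int  # number of bias tones
    gap: float  # s, silence between bias and test pair


@dataclass
class ToneSequence:
    """A timed, role-labelled sequence of Shepard tones."""

    events: list[ToneEvent]
    paradigm: Literal["biased_pair", "biased_tuning", "meg_probe"]
    bias_meta: BiasMeta | None = None
    seq_id: str = ""
    bias_id: str = ""  # identity of the bias-tone set (gap-independent)
    base_pc: float | None = None  # pitch class of test1 / region anchor
    randomization: int = 0
    region: tuple[float, float] | None = None

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def tones(self, role: Role | None = None) -> list[ToneEvent]:
        if role is None:
            return list(self.events)
        return [e for e in self.events if e.role == role]

    @property
    def duration(self) -> float:
        last = self.events[-1]
        return last.onset + last.tone.duration


def component_frequencies(pc: float, band: tuple[float, float]) -> np.ndarray:
    """Octave-spaced partials of pitch class ``pc`` inside ``band`` (Hz).

    All frequencies 440 * 2**(pc/12) * 2**k falling in the band, ascending.
    The set only depends on pc modulo 12.
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    f0 = ANCHOR_HZ * 2.0 ** (wrap_pc(pc) / 12.0)
    k_lo = int(np.ceil(np.log2(lo / f0) - 1e-12))
    k_hi = int(np.floor(np.log2(hi / f0) + 1e-12))
    return f0 * 2.0 ** np.arange(k_lo, k_hi + 1, dtype=float)


def synthesize_waveform(
    tone: ShepardTone,
    audio_rate: float = 44100.0,
    band: tuple[float, float] = DEFAULT_BAND,
    level_ref: float = 70.0,
) -> np.ndarray:
    """Render a Shepard tone as a mono sample vector.

    Equal-amplitude sinusoids at the octave-spaced component frequencies,
    phases drawn from ``tone.phase_seed``, gated with sinusoidal
    (half-cosine) on/off ramps, peak-normalized and scaled so that
    ``level == level_ref`` gives peak amplitude 1.
    """
    if audio_rate <= 2 * band[1]:
        raise ValueError("audio_rate violates the Nyquist bound for the band")
    freqs = component_frequencies(tone.pitch_class, band)
    rng = np.random.default_rng(tone.phase_seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    n = int(round(tone.duration * audio_rate))
    t = np.arange(n) / audio_rate
    wave = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    n_ramp = int(round(tone.ramp / 1000.0 * audio_rate))
    if n_ramp > 0:
        gate = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        wave[:n_ramp] *= gate
        wave[-n_ramp:] *= gate[::-1]
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak
    return wave * 10.0 ** ((tone.level - level_ref) / 20.0)


def sequence_waveform(seq: ToneSequence, audio_rate: float = 44100.0,
                      band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Render a whole sequence (tones summed into a silent carrier)."""
    n = int(np.ceil(seq.duration * audio_rate)) + 1
    out = np.zeros(n)
    for ev in seq.events:
        w = synthesize_waveform(ev.tone, audio_rate, band)
        i0 = int(round(ev.onset * audio_rate))
        out[i0:i0 + w.size] += w
    return out


def write_wav(path, seq: ToneSequence, audio_rate: float = 44100.0) -> None:
    wave = sequence_waveform(seq, audio_rate)
    scaled = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, int(audio_rate), (scaled * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Paradigm generators
# ---------------------------------------------------------------------------


@dataclass
class PairConfig:
    """Biased Shepard pair paradigm (ferret timing by default)."""

    base_pitch_classes: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    n_randomizations: int = 2
    bias_lengths: tuple[int, ...] = (5, 10)
    directions: tuple[str, ...] = ("up", "down")
    gaps: tuple[float, ...] = (0.05, 0.2, 0.5)
    bias_range: float = 5.0  # st covered by the bias
    bias_offset: float = 3.0  # st from test1 to the bias-range center
    pair_step: float = 6.0  # st between test1 and test2
    tone_duration: float = 0.1  # s
    soa: float = 0.15  # s, stimulus onset asynchrony


@dataclass
class TuningConfig:
    """Biased Shepard tuning paradigm."""

    regions: tuple[tuple[float, float], ...] = ((0, 5), (3, 8), (6, 11), (9, 14))
    sequence_length: int = 154
    lead_in: int = 15
    probe_grid_n: int = 24  # probe positions per octave (0.5 st grid)
    sequences_per_region: int = 5
    tone_duration: float = 0.1
    soa: float = 0.15


def _combo_seed(seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_biased_pair_set(cfg: PairConfig, seed: int) -> list[ToneSequence]:
    """Full factorial of biased-pair sequences.

    Bias pitch classes are drawn uniformly and continuously from
    center +/- range/2, strictly above (up) or below (down) the first
    test tone.  The same bias-tone draw is reused across the gap levels,
    so the number of distinct bias sequences is
    ``len(bases) * n_randomizations * len(lengths) * len(directions)``
    (32 by default, containing 240 distinct bias tones), while one
    ``ToneSequence`` is emitted per (bias sequence, gap) pair.
    """
    if cfg.bias_range >= 12.0:
        raise ValueError("bias range must be below one octave")
    sequences: list[ToneSequence] = []
    for ib, base in enumerate(cfg.base_pitch_classes):
        for ir in range(cfg.n_randomizations):
            for il, length in enumerate(cfg.bias_lengths):
                for idd, direction in enumerate(cfg.directions):
                    sgn = 1.0 if direction == "up" else -1.0
                    center = wrap_pc(base + sgn * cfg.bias_offset)
                    rng = np.random.default_rng(_combo_seed(seed, ib, ir, il, idd))
                    offsets = rng.uniform(cfg.bias_offset - cfg.bias_range / 2,
                                          cfg.bias_offset + cfg.bias_range / 2,
                                          size=length)
                    bias_pcs = wrap_pc(base + sgn * offsets)
                    bias_id = f"b{base:g}_r{ir}_L{length}_{direction}"
                    for gap in cfg.gaps:
                        events = []
                        for k, pc in enumerate(bias_pcs):
                            events.append(ToneEvent(
                                onset=k * cfg.soa,
                                tone=ShepardTone(pc, cfg.tone_duration,
                                                 phase_seed=_combo_seed(seed, ib, ir, il, idd, k)),
                                role="bias"))
                        t1_onset = (length - 1) * cfg.soa + cfg.tone_duration + gap
                        events.append(ToneEvent(
                            onset=t1_onset,
                            tone=ShepardTone(base, cfg.tone_duration,
                                             phase_seed=_combo_seed(seed, ib, ir, il, idd, 1001)),
                            role="test1"))
                        events.append(ToneEvent(
                            onset=t1_onset + cfg.soa,
                            tone=ShepardTone(wrap_pc(base + cfg.pair_step), cfg.tone_duration,
                                             phase_seed=_combo_seed(seed, ib, ir, il, idd, 1002)),
                            role="test2"))
                        sequences.append(ToneSequence(
                            events=events,
                            paradigm="biased_pair",
                            bias_meta=BiasMeta(center=float(center), range=cfg.bias_range,
                                               direction=direction, length=length, gap=gap),
                            seq_id=f"{bias_id}_g{gap:g}",
                            bias_id=bias_id,
                            base_pc=float(base),
                            randomization=ir,
                        ))
    return sequences


def generate_meg_probe_set(cfg: PairConfig, seed: int,
                           pauses: tuple[float, ...] = (0.5, 1.0, 2.0),
                           probe_offset: float = 3.0,
                           probe_duration: float = 0.03,
                           probe_soa: float = 0.25,
                           train_duration: float = 2.0) -> list[ToneSequence]:
    """MEG-timing variant of the biased pair.

    Slower presentation (0.125 s tones at 4 Hz), post-bias pauses of
    {0.5, 1, 2} s, and a 2 s train of brief probe tones (30 ms at a
    250 ms onset asynchrony, pitch class 3 st above or below the first
    pair tone, matching the bias side) inserted between the bias and
    the ambiguous pair.  The stimulus exists for completeness; no
    MEG-specific analysis is implemented downstream.
    """
    base_cfg = PairConfig(
        base_pitch_classes=cfg.base_pitch_classes,
        n_randomizations=cfg.n_randomizations,
        bias_lengths=cfg.bias_lengths,
        directions=cfg.directions,
        gaps=tuple(pauses),
        bias_range=cfg.bias_range,
        bias_offset=cfg.bias_offset,
        pair_step=cfg.pair_step,
        tone_duration=0.125,
        soa=0.25,
    )
    sequences = []
    n_probes = int(round(train_duration / probe_soa))
    for seq in generate_biased_pair_set(base_cfg, seed):
        bm = seq.bias_meta
        sgn = 1.0 if bm.direction == "up" else -1.0
        probe_pc = wrap_pc(seq.base_pc + sgn * probe_offset)
        bias_events = [e for e in seq.events if e.role == "bias"]
        bias_end = max(e.onset + e.tone.duration for e in bias_events)
        train_start = bias_end + bm.gap
        events = list(bias_events)
        for k in range(n_probes):
            events.append(ToneEvent(
                onset=train_start + k * probe_soa,
                tone=ShepardTone(probe_pc, probe_duration,
                                 phase_seed=_combo_seed(seed, 9000, k)),
                role="probe"))
        pair_start = train_start + train_duration + probe_soa
        for ev, role in zip([e for e in seq.events if e.role in ("test1", "test2")],
                            ("test1", "test2")):
            events.append(ToneEvent(
                onset=pair_start if role == "test1" else pair_start + base_cfg.soa,
                tone=ev.tone, role=role))
        sequences.append(ToneSequence(
            events=events, paradigm="meg_probe", bias_meta=bm,
            seq_id="meg_" + seq.seq_id, bias_id=seq.bias_id,
            base_pc=seq.base_pc, randomization=seq.randomization))
    return sequences


def generate_biased_tuning_set(cfg: TuningConfig, seed: int) -> list[ToneSequence]:
    """Biased-tuning sequences with balanced probe coverage.

    Each sequence opens with ``lead_in`` bias-role tones, then repeats
    groups of 5 bias tones + 1 probe tone on the ``probe_grid_n``-step
    octave grid, truncated/padded to ``sequence_length``.  Probe grid
    coverage is balanced across a region's sequence set: every grid
    position occurs either floor or ceil of (slots / grid) times.
    """
    grid = 12.0 * np.arange(cfg.probe_grid_n) / cfg.probe_grid_n
    probes_per_seq = (cfg.sequence_length - cfg.lead_in) // 6
    sequences: list[ToneSequence] = []
    for ireg, (lo, hi) in enumerate(cfg.regions):
        rng = np.random.default_rng(_combo_seed(seed, 7000, ireg))
        n_slots = probes_per_seq * cfg.sequences_per_region
        reps = int(np.ceil(n_slots / cfg.probe_grid_n))
        pool = np.tile(np.arange(cfg.probe_grid_n), reps)
        rng.shuffle(pool)
        pool = pool[:n_slots]
        for iseq in range(cfg.sequences_per_region):
            probe_idx = pool[iseq * probes_per_seq:(iseq + 1) * probes_per_seq]
            pcs: list[tuple[float, Role]] = []
            for k in range(cfg.lead_in):
                pcs.append((float(wrap_pc(rng.uniform(lo, hi))), "lead_in"))
            ip = 0
            while len(pcs) < cfg.sequence_length:
                for _ in range(5):
                    if len(pcs) >= cfg.sequence_length:
                        break
                    pcs.append((float(wrap_pc(rng.uniform(lo, hi))), "bias"))
                if len(pcs) < cfg.sequence_length and ip < probe_idx.size:
                    pcs.append((float(grid[probe_idx[ip]]), "probe"))
                    ip += 1
                elif ip >= probe_idx.size and len(pcs) < cfg.sequence_length:
                    pcs.append((float(wrap_pc(rng.uniform(lo, hi))), "bias"))
            events = [
                ToneEvent(onset=k * cfg.soa,
                          tone=ShepardTone(pc, cfg.tone_duration,
                                           phase_seed=_combo_seed(seed, 7000, ireg, iseq, k)),
                          role=role)
                for k, (pc, role) in enumerate(pcs)
            ]
            center = wrap_pc((lo + hi) / 2.0)
            sequences.append(ToneSequence(
                events=events,
                paradigm="biased_tuning",
                bias_meta=BiasMeta(center=float(center), range=float(hi - lo),
                                   direction="up", length=cfg.sequence_length, gap=0.0),
                seq_id=f"reg{ireg}_s{iseq}",
                bias_id=f"reg{ireg}_s{iseq}",
                base_pc=float(center),
                randomization=iseq,
                region=(float(lo), float(hi)),
            ))
    return sequences


# ---------------------------------------------------------------------------
# Spectrogram representation
# ---------------------------------------------------------------------------


@dataclass
class PitchClassSpectrogram:
    """Time x circular-pitch-bin stimulus representation S(t, phi).

    The pitch axis wraps: bin ``n_bins - 1`` is adjacent to bin 0.
    Frames are zero outside tone presentations.
    """

    frames: np.ndarray  # (n_frames, n_bins), nonnegative
    sample_rate: float  # Hz
    n_bins: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 12.0 * np.arange(self.n_bins) / self.n_bins

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def pitch_bin(pc: float, n_bins: int) -> int:
    """Nearest circular pitch bin for a pitch class."""
    return int(np.round(wrap_pc(pc) * n_bins / 12.0)) % n_bins


def to_spectrogram(seq: ToneSequence, sample_rate: float = 20.0,
                   n_bins: int = 24, total_duration: float | None = None) -> PitchClassSpectrogram:
    """Rasterize a tone sequence onto the model's pitch-class spectrogram.

    Each tone contributes amplitude 1 in its nearest circular pitch bin
    for every frame overlapping its on-time.
    """
    dur = total_duration if total_duration is not None else seq.duration
    n_frames = int(np.ceil(dur * sample_rate - 1e-6))
    frames = np.zeros((n_frames, n_bins))
    for ev in seq.events:
        f0 = int(np.floor(ev.onset * sample_rate + 1e-6))
        f1 = int(np.ceil((ev.onset + ev.tone.duration) * sample_rate - 1e-6))
        f1 = min(f1, n_frames)
        frames[f0:f1, pitch_bin(ev.tone.pitch_class, n_bins)] += 1.0
    return PitchClassSpectrogram(frames=frames, sample_rate=sample_rate, n_bins=n_bins)


def alignment_table(seq: ToneSequence, sample_rate: float = 20.0,
                    n_frames: int | None = None) -> pd.DataFrame:
    """Per-frame stimulus alignment for a rasterized sequence.

    Columns: frame, event_index (-1 in silence), role, pitch_class,
    position (index among same-role events), offset_bin (0 = onset
    frame of the event; counts on during silence after the last event).
    """
    if n_frames is None:
        n_frames = int(np.ceil(seq.duration * sample_rate - 1e-6))
    frame_event = np.full(n_frames, -1, dtype=int)
    for idx, ev in enumerate(seq.events):
        f0 = int(np.floor(ev.onset * sample_rate + 1e-6))
        f1 = min(int(np.ceil((ev.onset + ev.tone.duration) * sample_rate - 1e-6)), n_frames)
        frame_event[f0:f1] = idx
    role_pos: dict[str, int] = {}
    positions, roles, pcs = [], [], []
    for idx, ev in enumerate(seq.events):
        positions.append(role_pos.get(ev.role, 0))
        role_pos[ev.role] = positions[-1] + 1
        roles.append(ev.role)
        pcs.append(ev.tone.pitch_class)
    rows = []
    for f in range(n_frames):
        idx = frame_event[f]
        if idx >= 0:
            onset_frame = int(np.floor(seq.events[idx].onset * sample_rate + 1e-6))
            rows.append((f, idx, roles[idx], pcs[idx], positions[idx], f - onset_frame))
        else:
            # offset_bin relative to most recent event onset (or -1 before any)
            prev = [i for i in range(len(seq.events))
                    if seq.events[i].onset * sample_rate <= f + 1e-6]
            if prev:
                idxp = prev[-1]
                onset_frame = int(np.floor(seq.events[idxp].onset * sample_rate + 1e-6))
                rows.append((f, -1, "silence", np.nan, -1, f - onset_frame))
            else:
                rows.append((f, -1, "silence", np.nan, -1, -1))
    return pd.DataFrame(rows, columns=["frame", "event_index", "role", "pitch_class",
                                       "position", "offset_bin"])


def schedule_table(sequences: Sequence[ToneSequence]) -> pd.DataFrame:
    """Stimulus schedule as a tidy table (one row per tone event)."""
    rows = []
    for seq in sequences:
        bm = seq.bias_meta
        for k, ev in enumerate(seq.events):
            rows.append({
                "sequence_id": seq.seq_id,
                "event_index": k,
                "onset_s": ev.onset,
                "duration_s": ev.tone.duration,
                "pitch_class": ev.tone.pitch_class,
                "role": ev.role,
                "bias_center": bm.center if bm else np.nan,
                "bias_direction": bm.direction if bm else "",
                "bias_length": bm.length if bm else 0,
                "gap_s": bm.gap if bm else np.nan,
            })
    return pd.DataFrame(rows)
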