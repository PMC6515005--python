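"""Heart-sound detection and S1/S2 classification on the Shannon envelope.

Detection is rule-based: amplitude thresholding at 5% of the envelope
maximum, gap joining below 10% of the mean RR interval, split location at
the deepest interior envelope minimum, false-positive pruning on inter-sound
spacing (20% / 40% of mean RR), and finally R-peak-referenced temporal
classification (S1 window from 50 ms before the R-peak to 18% of the RR
interval after it; S2 from 18% RR up to the next beat's S1 window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelope import EnvelopeSignal, normalize_envelope, shannon_energy
from .filtering import (FilterSpec, Recording, align_signals, bandpass_ecg,
                        bandpass_pcg, ecg_group_delay)
from .rpeaks import RPeakSeries, RRStats, detect_r_peaks, rr_statistics

__all__ = [
    "SegmentationConstants",
    "CandidateSegment",
    "HeartSound",
    "SegmentationResult",
    "threshold_segments",
    "locate_components",
    "prune_false_positives",
    "classify_sounds",
    "segment_recording",
]


@dataclass
class SegmentationConstants:
    """Rule constants of the detection/classification stage.

    amp_threshold_frac : fraction of the global envelope maximum below
        which samples count as noise (0.05).
    join_frac : segments closer than this fraction of the mean RR interval
        are joined (0.10) so an under-threshold intercomponent split does
        not cut one sound in two.
    fp_pair_frac / fp_triple_frac : first components closer than 0.20 (any
        pair) or 0.40 (two consecutive pairs) of the mean RR mark false
        positives; the lowest-envelope one is dropped.
    s1_pre_ms / s1_rr_frac : the S1 acceptance window spans from 50 ms
        before the R-peak to 18% of the RR interval after it.
    """

    amp_threshold_frac: float = 0.05
    join_frac: float = 0.10
    fp_pair_frac: float = 0.20
    fp_triple_frac: float = 0.40
    s1_pre_ms: float = 50.0
    s1_rr_frac: float = 0.18

    def validate(self) -> None:
        for name in ("amp_threshold_frac", "join_frac", "fp_pair_frac",
                     "fp_triple_frac", "s1_rr_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class CandidateSegment:
    """A detected over-threshold envelope segment, half-open [start, end).

    ``split`` is the deepest interior envelope minimum; ``c1`` and ``c2``
    the envelope argmax before and after it.  Single-lobe segments with no
    interior minimum are flagged degenerate with ``split == c1 == c2``.
    """

    start: int
    end: int
    split: int
    c1: int
    c2: int
    degenerate: bool = False


S1_COMPONENTS = ("mitral", "tricuspid")
S2_COMPONENTS = ("aortic", "pulmonary")


@dataclass
class HeartSound:
    segment: CandidateSegment
    label: str  # "S1" | "S2"
    ref_rpeak: int
    component_labels: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if self.label not in ("S1", "S2"):
            raise ValueError("label must be 'S1' or 'S2'")
        self.component_labels = (
            S1_COMPONENTS if self.label == "S1" else S2_COMPONENTS
        )


def threshold_segments(env: EnvelopeSignal | np.ndarray, mean_rr: float,
                       constants: SegmentationConstants | None = None,
                       fs: float | None = None) -> list[tuple[int, int]]:
    """Over-threshold runs of the envelope, gap-joined.

    Returns half-open ``(start, end)`` runs where the envelope exceeds 5%
    of its global maximum; consecutive runs separated by less than 10% of
    ``mean_rr`` (ms) are merged.
    """
    if constants is None:
        constants = SegmentationConstants()
    if isinstance(env, EnvelopeSignal):
        values, fs = env.values, env.fs
    else:
        values = np.asarray(env, dtype=float)
        if fs is None:
            fs = 1000.0
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    peak = values.max(initial=0.0)
    if peak <= 0:
        return []
    above = values > constants.amp_threshold_frac * peak
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values))

    max_gap = constants.join_frac * mean_rr * fs / 1000.0
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _interior_minima(seg: np.ndarray) -> np.ndarray:
    """Indices of interior local minima, plateau-aware.

    A maximal run of equal values counts as one minimum when the values
    immediately before and after the run are both larger (the gap-joining
    step produces flat zero valleys, which a strictly-pointwise test would
    miss).  Each plateau is represented by its earliest index.
    """
    if len(seg) < 3:
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(seg) != 0)
    if len(change) == 0:
        return np.array([], dtype=int)
    run_starts = np.concatenate(([0], change + 1))
    run_vals = seg[run_starts]
    interior = np.arange(1, len(run_vals) - 1)
    is_min = (run_vals[interior] < run_vals[interior - 1]) & \
             (run_vals[interior] < run_vals[interior + 1])
    return run_starts[interior[is_min]]


def _interior_maxima(seg: np.ndarray) -> np.ndarray:
    return _interior_minima(-seg)


def locate_components(env: EnvelopeSignal | np.ndarray, start: int,
                      end: int, min_prominence: float = 0.0,
                      min_peak_sep: int = 1) -> CandidateSegment:
    """Locate the split and the two component peaks inside one segment.

    The split is the deepest (plateau-aware) local minimum between the two
    tallest envelope peaks of the segment, where the second peak must lie
    at least ``min_peak_sep`` samples from the first — structures closer
    than the envelope's integration window are not resolvable by
    construction, and noise ripples on the segment skirts must not be
    mistaken for components.  The two peaks are the component locations
    (equivalently, the envelope argmax on either side of the split, which
    on a clean envelope is the same thing).  Ties break to the earliest
    index.  A segment with fewer than two qualifying peaks,
    or whose valley is shallower than ``min_prominence`` below both peaks,
    collapses to a single-component (degenerate) sound.
    """
    values = env.values if isinstance(env, EnvelopeSignal) else np.asarray(env)
    if end - start < 3:
        raise ValueError("segment must span at least 3 samples")
    seg = values[start:end]

    def degenerate() -> CandidateSegment:
        peak = start + int(np.argmax(seg))
        return CandidateSegment(start=start, end=end, split=peak, c1=peak,
                                c2=peak, degenerate=True)

    peaks = _interior_maxima(seg)
    # The segment boundary samples can themselves be the lobe tops when the
    # envelope enters/leaves above threshold; treat them as candidates too.
    if len(seg) >= 2 and seg[0] > seg[1]:
        peaks = np.concatenate(([0], peaks))
    if len(seg) >= 2 and seg[-1] > seg[-2]:
        peaks = np.concatenate((peaks, [len(seg) - 1]))
    if len(peaks) < 2:
        return degenerate()
    p1 = peaks[int(np.argmax(seg[peaks]))]
    far = peaks[np.abs(peaks - p1) >= min_peak_sep]
    if len(far) == 0:
        return degenerate()
    p2 = far[int(np.argmax(seg[far]))]
    lo, hi = (p1, p2) if p1 < p2 else (p2, p1)
    valley = _interior_minima(seg[lo:hi + 1])
    if len(valley) == 0:
        return degenerate()
    vals = seg[lo + valley]
    split_rel = lo + valley[int(np.argmin(vals))]
    if min(seg[p1], seg[p2]) - seg[split_rel] < min_prominence:
        return degenerate()
    split = start + int(split_rel)
    c1 = start + int(lo)
    c2 = start + int(hi)
    return CandidateSegment(start=start, end=end, split=split, c1=c1, c2=c2)


def prune_false_positives(candidates: list[CandidateSegment],
                          env: EnvelopeSignal | np.ndarray, mean_rr: float,
                          constants: SegmentationConstants | None = None,
                          fs: float | None = None) -> list[CandidateSegment]:
    """Drop physiologically implausible candidates.

    Rule (a): of two first components closer than 20% of the mean RR, the
    one with the lower envelope is a false positive.  Rule (b): when two
    consecutive first-component gaps are both below 40% of the mean RR,
    the lowest-envelope first component of the triple is a false positive.
    Both rules run iteratively until the list is stable.
    """
    if constants is None:
        constants = SegmentationConstants()
    if isinstance(env, EnvelopeSignal):
        values, fs = env.values, env.fs
    else:
        values = np.asarray(env, dtype=float)
        if fs is None:
            fs = 1000.0
    out = sorted(candidates, key=lambda c: c.c1)
    pair_gap = constants.fp_pair_frac * mean_rr * fs / 1000.0
    triple_gap = constants.fp_triple_frac * mean_rr * fs / 1000.0

    changed = True
    while changed:
        changed = False
        for i in range(len(out) - 1):
            if out[i + 1].c1 - out[i].c1 < pair_gap:
                drop = i if values[out[i].c1] <= values[out[i + 1].c1] else i + 1
                del out[drop]
                changed = True
                break
        if changed:
            continue
        for i in range(len(out) - 2):
            trio = out[i:i + 3]
            g1 = trio[1].c1 - trio[0].c1
            g2 = trio[2].c1 - trio[1].c1
            if g1 < triple_gap and g2 < triple_gap:
                amps = [values[c.c1] for c in trio]
                del out[i + int(np.argmin(amps))]
                changed = True
                break
    return out


def classify_sounds(candidates: list[CandidateSegment], peaks: RPeakSeries,
                    rr: RRStats,
                    constants: SegmentationConstants | None = None,
                    env: EnvelopeSignal | np.ndarray | None = None
                    ) -> list[HeartSound]:
    """Label candidates as S1 or S2 relative to their reference R-peak.

    Each candidate is referred to the nearest preceding R-peak, or to the
    following one when its first component leads it by at most 50 ms.  A
    first component within ``[ref - 50 ms, ref + 0.18 RR]`` makes an S1
    (mitral, tricuspid); at or beyond ``ref + 0.18 RR``, with the whole
    sound (through its second component) ending before the next beat's S1
    window opens, an S2 (aortic, pulmonary).  Per cardiac cycle at most
    one S1 and one S2 survive (highest envelope first component wins);
    anything else is discarded.
    """
    if constants is None:
        constants = SegmentationConstants()
    if len(peaks) < 2:
        return []
    fs = peaks.fs
    idx = peaks.indices
    pre = constants.s1_pre_ms * fs / 1000.0
    values = None
    if env is not None:
        values = env.values if isinstance(env, EnvelopeSignal) else np.asarray(env)

    def rr_samples(k: int) -> float:
        if k < len(idx) - 1:
            return float(idx[k + 1] - idx[k])
        return rr.mean_rr * fs / 1000.0

    best: dict[tuple[int, str], tuple[float, HeartSound]] = {}
    for cand in candidates:
        c1 = cand.c1
        k = int(np.searchsorted(idx, c1, side="right")) - 1
        if k + 1 < len(idx) and idx[k + 1] - c1 <= pre:
            k = k + 1  # leads the next R-peak by <= 50 ms: that beat's S1
        if k < 0:
            continue
        ref = int(idx[k])
        rr_k = rr_samples(k)
        s1_hi = ref + constants.s1_rr_frac * rr_k
        next_window_start = (idx[k + 1] - pre if k + 1 < len(idx)
                             else ref + rr_k - pre)
        label = None
        if ref - pre <= c1 <= s1_hi:
            label = "S1"
        elif c1 >= s1_hi and cand.c2 < next_window_start:
            label = "S2"
        if label is None:
            continue
        amp = float(values[c1]) if values is not None else 0.0
        key = (k, label)
        if key not in best or amp > best[key][0]:
            best[key] = (amp, HeartSound(segment=cand, label=label, ref_rpeak=ref))
    sounds = [hs for _, hs in best.values()]
    sounds.sort(key=lambda h: h.segment.c1)
    return sounds


@dataclass
class SegmentationResult:
    """Output bundle of the full pipeline."""

    rpeaks: RPeakSeries
    sounds: list[HeartSound]
    envelope: EnvelopeSignal
    recording: Recording  # filtered, delay-compensated
    rr: RRStats | None

    def __iter__(self):
        return iter((self.rpeaks, self.sounds, self.envelope))


def segment_recording(rec: Recording, spec: FilterSpec | None = None,
                      constants: SegmentationConstants | None = None,
                      norm_window: float = 1.0,
                      se_window_n: int = 20) -> SegmentationResult:
    """Run the full ECG-referenced segmentation pipeline on a raw recording.

    Stages: ECG FIR band-pass -> PCG zero-phase band-pass -> delay
    compensation -> R-peak detection -> Shannon-energy envelope with moving
    normalisation -> amplitude thresholding and gap joining -> component
    location -> false-positive pruning -> S1/S2 classification.
    """
    if spec is None:
        spec = FilterSpec()
    if constants is None:
        constants = SegmentationConstants()
    constants.validate()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as exc:
            raise ValueError(f"[{name}] {exc}") from exc

    ecg_f = stage("bandpass_ecg", bandpass_ecg, rec.ecg, spec, rec.fs)
    pcg_f = stage("bandpass_pcg", bandpass_pcg, rec.pcg, spec, rec.fs)
    aligned = stage("align_signals", align_signals, ecg_f, pcg_f,
                    ecg_group_delay(spec), rec.fs)
    peaks = stage("detect_r_peaks", detect_r_peaks, aligned.ecg, rec.fs)

    raw_se = stage("shannon_energy", shannon_energy, aligned.pcg, se_window_n)
    env = stage("normalize_envelope", normalize_envelope, raw_se, rec.fs,
                norm_window, se_window_n)

    if len(peaks) < 2:
        return SegmentationResult(rpeaks=peaks, sounds=[], envelope=env,
                                  recording=aligned, rr=None)
    rr = rr_statistics(peaks)
    runs = stage("threshold_segments", threshold_segments, env, rr.mean_rr,
                 constants)
    # A valley shallower than the amplitude threshold's own noise scale
    # (5% of the envelope maximum) does not separate two components, and
    # peaks closer than the integration window are smoothing ripples of a
    # single lobe rather than two components.
    min_prom = constants.amp_threshold_frac * float(env.values.max(initial=0.0))
    candidates = [locate_components(env, s, e, min_prom, se_window_n)
                  for s, e in runs if e - s >= 3]
    pruned = stage("prune_false_positives", prune_false_positives, candidates,
                   env, rr.mean_rr, constants)
    sounds = stage("classify_sounds", classify_sounds, pruned, peaks, rr,
                   constants, env)
    return SegmentationResult(rpeaks=peaks, sounds=sounds, envelope=env,
                              recording=aligned, rr=rr)
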