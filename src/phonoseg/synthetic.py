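"""Synthetic paired ECG/PCG generator with exact ground truth.

No public dataset accompanies the method, so validation runs on simulated
records that emulate its acquisition setting: 1-kHz simultaneous ECG/PCG,
heart rates of 55-90 bpm, and heart sounds built as pairs of short
Gaussian-windowed tone bursts (mitral/tricuspid for S1, aortic/pulmonary
for S2) at programmable delays from each R-peak.  Optional systolic
murmurs (200-600 Hz band-limited noise) and premature ventricular
contractions (wide low-frequency ECG deflection with absent heart sounds)
reproduce the main confounders the detection rules must reject.

Component timing defaults, per-subject delay/variability values, heart
rates and SNR levels of the 24-subject reference cohort are tabulated in
``SUBJECT_TABLE``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .filtering import FilterSpec, Recording, _pcg_sos

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectParams",
    "SUBJECT_TABLE",
    "generate_recording",
    "generate_cohort",
    "noise_std_for_snr",
]

# Acquisition front-end bandwidth (3-dB low-pass corner, Hz): broadband
# noise is shaped by this before entering the record.
ACQUISITION_BANDWIDTH_HZ = 262.0


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generator parameters of the reference cohort.

    Delays are means over a 10-min recording, in ms from the R-peak;
    ``*_std`` is the within-subject beat-to-beat variability.  S1/S2 are
    parameterised by their first component (mitral/aortic) and the split,
    so that the component order is preserved under per-beat jitter.
    """

    subject_id: str
    heart_rate: float  # bpm
    snr_db: float
    s1m: float
    s1m_std: float
    s1_split: float
    s1_split_std: float
    s2a: float
    s2a_std: float
    s2_split: float
    s2_split_std: float


SUBJECT_TABLE: tuple[SubjectParams, ...] = tuple(
    SubjectParams(*row)
    for row in [
        ("subj_01", 66, 33.7, 45.0, 3.2, 19.3, 5.3, 360.2, 4.3, 22.4, 12.8),
        ("subj_02", 82, 13.9, 20.7, 5.8, 51.7, 11.9, 328.0, 38.4, 18.3, 20.4),
        ("subj_03", 80, 16.1, 33.3, 8.9, 30.6, 17.4, 337.8, 9.2, 10.3, 11.3),
        ("subj_04", 66, 20.7, 66.7, 19.6, 56.5, 17.1, 429.7, 6.7, 20.4, 14.9),
        ("subj_05", 68, 28.3, 36.7, 8.4, 13.6, 6.0, 353.3, 33.4, 15.0, 16.7),
        ("subj_06", 63, 18.7, 41.5, 5.4, 32.7, 9.9, 398.8, 5.4, 49.0, 11.6),
        ("subj_07", 63, 27.2, 49.9, 6.1, 19.6, 10.2, 372.0, 4.3, 35.8, 14.2),
        ("subj_08", 55, 28.8, 45.8, 5.9, 16.3, 12.2, 392.3, 7.1, 20.8, 13.3),
        ("subj_09", 78, 15.0, 17.9, 6.8, 54.1, 9.7, 342.8, 8.8, 43.6, 13.4),
        ("subj_10", 56, 18.3, 41.5, 6.3, 24.3, 16.3, 371.1, 60.4, 19.3, 16.0),
        ("subj_11", 56, 30.2, 39.2, 4.8, 21.1, 16.4, 379.7, 9.6, 11.9, 5.8),
        ("subj_12", 63, 24.4, 36.9, 14.7, 40.6, 12.5, 391.6, 7.5, 60.3, 26.6),
        ("subj_13", 84, 14.7, 39.2, 14.7, 21.3, 12.9, 361.7, 16.6, 31.9, 18.2),
        ("subj_14", 56, 27.7, 53.1, 5.1, 23.5, 12.9, 394.9, 11.2, 28.1, 16.9),
        ("subj_15", 65, 16.2, 32.4, 5.4, 24.7, 22.5, 351.1, 10.0, 41.6, 12.4),
        ("subj_16", 61, 14.2, 58.8, 15.2, 51.7, 23.4, 407.3, 27.2, 26.1, 22.4),
        ("subj_17", 67, 20.7, 23.8, 14.3, 63.6, 19.7, 360.8, 19.6, 23.9, 19.7),
        ("subj_18", 87, 21.9, 58.6, 15.1, 35.4, 12.8, 345.8, 10.2, 24.3, 13.1),
        ("subj_19", 86, 19.0, 43.6, 11.6, 25.1, 26.5, 340.7, 39.7, 19.6, 25.0),
        ("subj_20", 62, 25.4, 51.0, 18.8, 34.0, 8.6, 407.6, 8.1, 30.2, 13.0),
        ("subj_21", 65, 12.5, 61.2, 14.1, 37.3, 18.4, 395.1, 21.0, 29.1, 21.8),
        ("subj_22", 56, 24.2, 59.5, 12.8, 30.8, 12.8, 382.1, 9.7, 21.2, 15.0),
        ("subj_23", 76, 14.4, 42.1, 13.2, 26.5, 14.6, 352.1, 9.0, 35.6, 38.6),
        ("subj_24", 66, 27.5, 54.0, 11.1, 17.4, 8.6, 355.0, 8.4, 34.4, 15.2),
    ]
)


@dataclass
class SimConfig:
    """Parameters of one synthetic paired ECG/PCG recording.

    Component timing is parameterised as (first-component delay, split),
    with defaults equal to the reference-cohort means: mitral 43.9 ms,
    S1 split 32.1 ms, aortic 371.3 ms, S2 split 28.1 ms from the R-peak.
    Per-beat jitter applies to the first-component delay and to the split
    independently (split clamped at ``min_split_ms`` so the second
    component never precedes the first).  ``burst_freq`` sits mid-band of
    the 20-100 Hz PCG filter; ``burst_duration`` approximates the typical
    20-60 ms duration of a heart-sound component.

    Noise: broadband Gaussian noise shaped by the acquisition bandwidth is
    added to the PCG; its standard deviation is either given explicitly
    (``noise_std``, relative to the mitral burst amplitude) or derived
    from ``target_snr_db`` by inverting the ensemble SNR definition (see
    :func:`noise_std_for_snr`).
    """

    duration: float = 60.0  # s
    fs: float = 1000.0
    heart_rate: float = 60.0  # bpm
    rr_jitter: float = 25.0  # ms std of the RR interval

    mitral_delay: float = 43.9  # ms from R
    s1_split: float = 32.1
    aortic_delay: float = 371.3
    s2_split: float = 28.1
    s1_jitter: float = 10.0  # ms std, shifts both S1 components
    s1_split_jitter: float = 13.0
    s2_jitter: float = 10.0
    s2_split_jitter: float = 15.0
    min_split_ms: float = 2.0

    burst_freq: float = 50.0  # Hz
    burst_duration: float = 40.0  # ms (~ +-2.5 envelope sigmas)
    amplitudes: tuple[float, float, float, float] = (1.0, 0.85, 0.95, 0.75)
    # Heart-sound intensity varies beat to beat (respiration, preload);
    # lognormal sigma of the per-beat scale and of each component's own
    # scale.  Without this the loudest component would sit exactly at the
    # envelope's amplitude-normalisation ceiling on every beat, a
    # degenerate coincidence real records do not show.
    amp_jitter: float = 0.2
    comp_amp_jitter: float = 0.05

    noise_std: float | None = None
    target_snr_db: float = 21.4  # cohort-mean SNR of the reference study
    ecg_noise_std: float = 0.01  # relative to the R-wave amplitude

    murmur: bool = False
    murmur_amplitude: float = 0.3
    murmur_band: tuple[float, float] = (200.0, 600.0)

    pvc_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.heart_rate <= 0 or self.duration <= 0 or self.fs <= 0:
            raise ValueError("heart_rate, duration and fs must be positive")
        if self.s1_split <= 0 or self.s2_split <= 0:
            raise ValueError("splits must be positive (second component "
                             "follows the first)")
        rr_ms = 60000.0 / self.heart_rate
        last = self.aortic_delay + self.s2_split + self.burst_duration + 50.0
        if last >= rr_ms:
            raise ValueError(
                f"infeasible geometry: the pulmonary burst ends at "
                f"~{last:.0f} ms after R, beyond the {rr_ms:.0f}-ms RR interval"
            )

    @property
    def tricuspid_delay(self) -> float:
        return self.mitral_delay + self.s1_split

    @property
    def pulmonary_delay(self) -> float:
        return self.aortic_delay + self.s2_split

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


COMPONENT_NAMES = ("mitral", "tricuspid", "aortic", "pulmonary")


@dataclass
class GroundTruth:
    """True beat and component times of a synthetic recording.

    ``components[name]`` holds one absolute time (ms from record start)
    per beat; PVC beats carry NaN (they produce no heart sounds).
    """

    true_rpeaks: np.ndarray  # sample indices
    components: dict[str, np.ndarray]  # ms, one entry per beat
    pvc_beats: np.ndarray  # beat ordinals
    fs: float = 1000.0

    @property
    def n_beats(self) -> int:
        return len(self.true_rpeaks)

    def normal_beats(self) -> np.ndarray:
        mask = np.ones(self.n_beats, dtype=bool)
        mask[np.asarray(self.pvc_beats, dtype=int)] = False
        return np.flatnonzero(mask)

    def component_times_ms(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-sound (first, second) component times over normal beats."""
        keep = self.normal_beats()
        return {
            "S1": (self.components["mitral"][keep],
                   self.components["tricuspid"][keep]),
            "S2": (self.components["aortic"][keep],
                   self.components["pulmonary"][keep]),
        }

    def to_json(self, path) -> None:
        payload = {
            "fs": self.fs,
            "true_rpeaks": self.true_rpeaks.tolist(),
            "pvc_beats": np.asarray(self.pvc_beats).tolist(),
            "components": {k: v.tolist() for k, v in self.components.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_rpeaks=np.asarray(d["true_rpeaks"], dtype=int),
            components={k: np.asarray(v, dtype=float)
                        for k, v in d["components"].items()},
            pvc_beats=np.asarray(d["pvc_beats"], dtype=int),
            fs=float(d["fs"]),
        )


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _add_ecg_beat(ecg: np.ndarray, t_ms: np.ndarray, r_ms: float) -> None:
    # Piecewise-Gaussian P-QRS-T; only the R location needs to be faithful.
    for amp, off, sig in ((0.15, -160.0, 25.0), (-0.15, -25.0, 8.0),
                          (1.0, 0.0, 11.0), (-0.25, 28.0, 9.0),
                          (0.35, 300.0, 55.0)):
        lo = np.searchsorted(t_ms, r_ms + off - 5 * sig)
        hi = np.searchsorted(t_ms, r_ms + off + 5 * sig)
        ecg[lo:hi] += amp * _gauss(t_ms[lo:hi], r_ms + off, sig)


def _add_pvc(ecg: np.ndarray, t_ms: np.ndarray, r_ms: float) -> None:
    # Broad low-frequency biphasic wave: its energy sits below the 10-Hz
    # ECG high-pass, so the detector never sees it.
    sig = 40.0
    lo = np.searchsorted(t_ms, r_ms - 5 * sig)
    hi = np.searchsorted(t_ms, r_ms + 5 * sig)
    tt = t_ms[lo:hi]
    ecg[lo:hi] += -0.6 * (tt - r_ms) / sig * _gauss(tt, r_ms, sig)


def _burst_sigma_ms(cfg: SimConfig) -> float:
    # The stated duration covers ~ +-2.5 sigma of the Gaussian envelope.
    return cfg.burst_duration / 5.0


def _add_burst(pcg: np.ndarray, t_ms: np.ndarray, center_ms: float,
               r_ms: float, amp: float, cfg: SimConfig) -> None:
    sig = _burst_sigma_ms(cfg)
    lo = np.searchsorted(t_ms, center_ms - 5 * sig)
    hi = np.searchsorted(t_ms, center_ms + 5 * sig)
    tt = t_ms[lo:hi]
    # Carrier phase locked to the R-peak: the beat-synchronous waveform is
    # reproducible across beats, as it is in real recordings, so the
    # ensemble-average SNR stays meaningful under timing jitter.
    carrier = np.cos(2 * np.pi * cfg.burst_freq * (tt - r_ms) / 1000.0)
    pcg[lo:hi] += amp * _gauss(tt, center_ms, sig) * carrier


def _acq_noise_sos(fs: float) -> np.ndarray:
    return signal.butter(4, ACQUISITION_BANDWIDTH_HZ, btype="lowpass",
                         fs=fs, output="sos")


def _draw_beats(cfg: SimConfig, rng: np.random.Generator):
    """Beat grid and per-beat component times (ms)."""
    rr_ms = 60000.0 / cfg.heart_rate
    # The last beat's sounds must survive the FIR delay-compensation trim
    # (250 ms at 1 kHz) with allowance for per-beat timing jitter.
    fir_trim_ms = 250.0
    jitter_allow = 4.0 * (cfg.s2_jitter + cfg.s2_split_jitter)
    margin_end = (cfg.pulmonary_delay + cfg.burst_duration + 100.0
                  + fir_trim_ms + jitter_allow)
    r_times = []
    t = 500.0  # leave room for the FIR transient at the record head
    dur_ms = cfg.duration * 1000.0
    while t + margin_end < dur_ms:
        r_times.append(t)
        t += max(rr_ms + rng.normal(0.0, cfg.rr_jitter), 350.0)
    r_times = np.asarray(r_times)
    n = len(r_times)
    if n == 0:
        raise ValueError("record too short to place a single beat")

    m = r_times + cfg.mitral_delay + rng.normal(0.0, cfg.s1_jitter, n)
    sp1 = np.maximum(cfg.s1_split + rng.normal(0.0, cfg.s1_split_jitter, n),
                     cfg.min_split_ms)
    a = r_times + cfg.aortic_delay + rng.normal(0.0, cfg.s2_jitter, n)
    sp2 = np.maximum(cfg.s2_split + rng.normal(0.0, cfg.s2_split_jitter, n),
                     cfg.min_split_ms)
    comps = {"mitral": m, "tricuspid": m + sp1, "aortic": a,
             "pulmonary": a + sp2}
    return r_times, comps


def _expected_mean_pcg_cycle(cfg: SimConfig) -> np.ndarray:
    """Deterministic expectation of the R-aligned filtered mean waveform.

    Component-time jitter convolves each Gaussian burst envelope with the
    jitter distribution (the R-locked carrier is unaffected); the result
    is passed through the zero-phase PCG band-pass.
    """
    fs = cfg.fs
    rr_ms = 60000.0 / cfg.heart_rate
    n = int(round(rr_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    sig_b = _burst_sigma_ms(cfg)
    jit = {
        "mitral": cfg.s1_jitter,
        "tricuspid": np.hypot(cfg.s1_jitter, cfg.s1_split_jitter),
        "aortic": cfg.s2_jitter,
        "pulmonary": np.hypot(cfg.s2_jitter, cfg.s2_split_jitter),
    }
    delays = {
        "mitral": cfg.mitral_delay,
        "tricuspid": cfg.tricuspid_delay,
        "aortic": cfg.aortic_delay,
        "pulmonary": cfg.pulmonary_delay,
    }
    wave = np.zeros(n)
    carrier = np.cos(2 * np.pi * cfg.burst_freq * t / 1000.0)
    for name, amp in zip(COMPONENT_NAMES, cfg.amplitudes):
        s_eff = float(np.hypot(sig_b, jit[name]))
        wave += amp * (sig_b / s_eff) * _gauss(t, delays[name], s_eff) * carrier
    sos = _pcg_sos(FilterSpec(), fs)
    return signal.sosfiltfilt(sos, wave)


def _noise_power_gain(fs: float) -> float:
    """Std gain of the PCG band-pass on acquisition-band-limited noise."""
    f = np.linspace(0.0, fs / 2.0, 4096)
    _, h_acq = signal.sosfreqz(_acq_noise_sos(fs), worN=f, fs=fs)
    _, h_pcg = signal.sosfreqz(_pcg_sos(FilterSpec(), fs), worN=f, fs=fs)
    num = np.trapezoid(np.abs(h_acq) ** 2 * np.abs(h_pcg) ** 4, f)
    den = np.trapezoid(np.abs(h_acq) ** 2, f)
    return float(np.sqrt(num / den))


def noise_std_for_snr(cfg: SimConfig, snr_db: float) -> float:
    """Raw-noise std (pre-band-pass) that yields the target ensemble SNR.

    Inverts ``SNR = 20 log10(AS / (4 sigma_N))``: ``AS`` comes from the
    deterministic expected mean filtered waveform, ``sigma_N`` from the
    target, and the PCG band-pass noise-std gain maps the in-band noise
    level back to the generator scale.
    """
    a_s = float(np.ptp(_expected_mean_pcg_cycle(cfg)))
    sigma_filtered = a_s / (4.0 * 10.0 ** (snr_db / 20.0))
    return sigma_filtered / _noise_power_gain(cfg.fs)


def generate_recording(cfg: SimConfig | None = None,
                       seed: int | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one paired ECG/PCG record with exact ground truth.

    Fully reproducible: the same config and seed give bit-identical
    output.  ``seed`` overrides ``cfg.seed`` when given.
    """
    if cfg is None:
        cfg = SimConfig()
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    t_ms = np.arange(n) * 1000.0 / fs

    r_times, comps = _draw_beats(cfg, rng)
    nb = len(r_times)
    pvc = np.sort(rng.choice(np.arange(1, nb - 1), size=min(cfg.pvc_count,
                                                            max(nb - 2, 0)),
                             replace=False)) if cfg.pvc_count > 0 else \
        np.array([], dtype=int)
    is_pvc = np.zeros(nb, dtype=bool)
    is_pvc[pvc] = True

    ecg = np.zeros(n)
    pcg = np.zeros(n)
    for b in range(nb):
        if is_pvc[b]:
            _add_pvc(ecg, t_ms, r_times[b])
            continue
        _add_ecg_beat(ecg, t_ms, r_times[b])
        beat_scale = float(np.exp(rng.normal(0.0, cfg.amp_jitter)))
        for name, amp in zip(COMPONENT_NAMES, cfg.amplitudes):
            scale = beat_scale * float(np.exp(rng.normal(0.0,
                                                         cfg.comp_amp_jitter)))
            _add_burst(pcg, t_ms, comps[name][b], r_times[b], amp * scale,
                       cfg)
        if cfg.murmur:
            # Systolic murmur: band-limited noise between S1 and S2.
            lo_ms = comps["tricuspid"][b] + 60.0
            hi_ms = comps["aortic"][b] - 40.0
            if hi_ms - lo_ms > 50.0:
                i0, i1 = (np.searchsorted(t_ms, lo_ms),
                          np.searchsorted(t_ms, hi_ms))
                noise = rng.standard_normal(i1 - i0)
                # Murmur band may exceed Nyquist at 1 kHz; clamp the top.
                band = (cfg.murmur_band[0],
                        min(cfg.murmur_band[1], 0.98 * fs / 2.0))
                sos_m = signal.butter(4, band, btype="bandpass",
                                      fs=fs, output="sos")
                burst = signal.sosfilt(sos_m, noise)
                sd = burst.std()
                if sd > 0:
                    taper = signal.windows.tukey(i1 - i0, 0.3)
                    pcg[i0:i1] += cfg.murmur_amplitude * taper * burst / sd

    noise_std = (cfg.noise_std if cfg.noise_std is not None
                 else noise_std_for_snr(cfg, cfg.target_snr_db))
    if noise_std > 0:
        raw = rng.standard_normal(n)
        shaped = signal.sosfilt(_acq_noise_sos(fs), raw)
        pcg += noise_std * shaped / shaped.std()
    if cfg.ecg_noise_std > 0:
        ecg += cfg.ecg_noise_std * rng.standard_normal(n)

    truth = GroundTruth(
        true_rpeaks=np.round(r_times * fs / 1000.0).astype(int),
        components={k: np.where(is_pvc, np.nan, v)
                    for k, v in comps.items()},
        pvc_beats=pvc,
        fs=fs,
    )
    return Recording(ecg=ecg, pcg=pcg, fs=fs), truth


def subject_config(params: SubjectParams, base: SimConfig | None = None,
                   min_snr_db: float = 13.0) -> SimConfig:
    """SimConfig for one cohort subject (SNR floored at ``min_snr_db``)."""
    base = base if base is not None else SimConfig()
    return base.replace(
        heart_rate=params.heart_rate,
        target_snr_db=max(params.snr_db, min_snr_db),
        noise_std=None,
        mitral_delay=params.s1m,
        s1_split=params.s1_split,
        aortic_delay=params.s2a,
        s2_split=params.s2_split,
        s1_jitter=params.s1m_std,
        s1_split_jitter=params.s1_split_std,
        s2_jitter=params.s2a_std,
        s2_split_jitter=params.s2_split_std,
    )


def generate_cohort(n: int | None = None, base_cfg: SimConfig | None = None,
                    delay_table: tuple[SubjectParams, ...] = SUBJECT_TABLE,
                    seed: int = 0):
    """Generate ``n`` records with per-subject parameters from the table.

    Per-record seeds derive deterministically from the master seed.  When
    ``n`` exceeds the table, subjects are recycled with a warning.  Yields
    ``(SubjectParams, Recording, GroundTruth)`` lazily so that 10-min
    cohorts need not be held in memory at once.
    """
    if n is None:
        n = len(delay_table)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(delay_table):
        import warnings

        warnings.warn(f"requested {n} records from a {len(delay_table)}-row "
                      "table; recycling subjects", stacklevel=2)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    for i in range(n):
        params = delay_table[i % len(delay_table)]
        cfg = subject_config(params, base_cfg)
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        rec, truth = generate_recording(cfg, seed=sub_seed)
        yield params, rec, truth
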