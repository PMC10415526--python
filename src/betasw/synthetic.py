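"""Synthetic sensorimotor cohorts with known lagged coupling structure.

The generator emulates the data entering the connectivity stage: per-subject
current-density time series for 26 Brodmann-area ROIs (13 areas x 2
hemispheres), band-limited to beta (13-30 Hz), with configurable lagged
coupling between ROIs, plus a subject table (FSS-7, sex, clinical
covariates) shaped like a two-group stroke cohort (16 low-fatigue /
13 high-fatigue, 18 male / 11 female).

Signals are built as zero-phase FIR band-filtered white noise (one
independent base oscillation per ROI); a coupling edge adds a delayed,
scaled copy of the source ROI's base oscillation to the target ROI, which
creates genuine lagged coherence confined to the band.  An optional shared
zero-lag component emulates volume-conduction-like instantaneous mixing,
which lagged coherence must ignore.

The group effect is planted as *topology*: a hub region with elevated
lagged coupling to every other region of its network, all at a common lag.
Because the spokes then share the hub's signal with zero relative lag,
their pairwise dependence is instantaneous and contributes nothing to
lagged coherence — the connectivity matrix acquires a clean star of strong
edges.  Under the weight-multiset-preserving surrogate null this raises
normalized clustering (the hub's triangles have high geometric-mean
intensity) without lengthening normalized paths, so the network's
small-world index rises.  Hubs are planted in the sensory networks of the
high-fatigue group and in the motor networks of the low-fatigue group,
producing the crossover of interest (sensory Sw up, motor Sw down in high
fatigue) without shifting overall connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve, firwin, resample_poly
from scipy.stats import truncnorm

from .connectivity import RoiTimeSeries
from .networks import (DEFAULT_NETWORKS, DEFAULT_ROI_LABELS,
                       NetworkDefinition)
from .preprocess import Recording
from .subjects import SubjectRecord, classify_fatigue

__all__ = [
    "CouplingEdge",
    "CouplingSpec",
    "CohortSpec",
    "CohortDataset",
    "ArtifactSpec",
    "generate_roi_timeseries",
    "generate_cohort",
    "project_to_scalp",
    "default_coupling_spec",
    "STANDARD_64_LABELS",
]

# BrainProducts-style 64-channel 10-20 cap (FCz is the online reference).
STANDARD_64_LABELS: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
)


@dataclass(frozen=True)
class CouplingEdge:
    """Directed lagged coupling: target += gain * delay(source, lag_ms)."""

    source: int
    target: int
    gain: float
    lag_ms: float


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth dependence structure for one simulated subject."""

    n_rois: int = 26
    edges: tuple[CouplingEdge, ...] = ()
    band: tuple[float, float] = (13.0, 30.0)
    noise_sd: float = 0.3
    instantaneous_mix: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("need at least one ROI")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid band {self.band}")
        for e in self.edges:
            if not 0.0 <= e.gain <= 1.0:
                raise ValueError(f"coupling gain {e.gain} outside [0, 1]")
            if e.lag_ms <= 0:
                raise ValueError("lags must be strictly positive")
            for k in (e.source, e.target):
                if not 0 <= k < self.n_rois:
                    raise ValueError(f"ROI index {k} out of range")


def _bandlimited_noise(shape: tuple[int, ...], band: tuple[float, float],
                       rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance white noise filtered to the band (zero-phase FIR)."""
    numtaps = int(np.ceil(3.3 * rate_hz / 1.0)) | 1  # ~1 Hz transition
    h = firwin(numtaps, list(band), pass_zero=False, fs=rate_hz,
               window="hamming")
    x = rng.standard_normal(shape)
    y = fftconvolve(x, h.reshape((1,) * (len(shape) - 1) + (-1,)),
                    mode="same", axes=-1)
    sd = y.std(axis=-1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def generate_roi_timeseries(spec: CouplingSpec, duration_s: float = 420.0,
                            rate_hz: float = 250.0,
                            seed: int | np.random.SeedSequence = 0,
                            labels: Optional[tuple[str, ...]] = None
                            ) -> RoiTimeSeries:
    """Simulate one subject's ROI current-density series.

    Each ROI is an independent band-limited base oscillation, plus delayed
    scaled copies of coupled sources' base oscillations, plus white noise,
    plus (optionally) a shared instantaneous component.  Deterministic given
    the seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz <= 2 * spec.band[1]:
        raise ValueError(
            f"rate {rate_hz} Hz below Nyquist for band upper edge "
            f"{spec.band[1]} Hz"
        )
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    base = _bandlimited_noise((spec.n_rois, n), spec.band, rate_hz, rng)
    data = base.copy()
    for e in spec.edges:
        lag = int(round(e.lag_ms / 1000.0 * rate_hz))
        if lag >= n:
            raise ValueError(f"lag {e.lag_ms} ms exceeds series length")
        lag = max(lag, 1)
        data[e.target, lag:] += e.gain * base[e.source, :-lag]
    if spec.instantaneous_mix > 0:
        shared = _bandlimited_noise((1, n), spec.band, rate_hz, rng)
        data += spec.instantaneous_mix * shared
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal((spec.n_rois, n))
    if labels is None:
        if spec.n_rois == len(DEFAULT_ROI_LABELS):
            labels = DEFAULT_ROI_LABELS
        else:
            labels = tuple(f"ROI{k}" for k in range(spec.n_rois))
    return RoiTimeSeries(data, rate_hz, labels)


# ---------------------------------------------------------------------------
# cohort-level defaults
# ---------------------------------------------------------------------------

_ROI_INDEX = {lab: k for k, lab in enumerate(DEFAULT_ROI_LABELS)}

#: Frozen default effect magnitudes (see docs/methods.md).
BASE_RING_GAIN = 0.35
HUB_GAIN = 0.5
HUB_LAG_MS = 20.0


def _network_indices(net: NetworkDefinition) -> list[int]:
    return [_ROI_INDEX[lab] for lab in net.roi_labels]


def _ring_edges(idx: list[int], gain: float) -> list[CouplingEdge]:
    m = len(idx)
    return [CouplingEdge(idx[i], idx[(i + 1) % m], gain, 15.0 + 2.0 * i)
            for i in range(m)]


def _hub_edges(idx: list[int], gain: float) -> list[CouplingEdge]:
    # common lag: spoke-spoke shared components stay instantaneous, so the
    # lagged-coherence matrix is a star centred on the hub
    hub = idx[0]
    return [CouplingEdge(hub, k, gain, HUB_LAG_MS) for k in idx[1:]]


def default_coupling_spec(group: Optional[str] = None,
                          hub_gain: float = HUB_GAIN,
                          base_gain: float = BASE_RING_GAIN,
                          noise_sd: float = 0.3,
                          instantaneous_mix: float = 0.0) -> CouplingSpec:
    """Study-condition coupling structure for one group.

    Every network carries a weak lagged ring (shared baseline connectivity).
    ``group='high'`` adds a coupling hub to both sensory networks;
    ``group='low'`` adds one to both motor networks; ``group=None`` yields
    the baseline-only null structure (no group difference).
    """
    edges: list[CouplingEdge] = []
    for net in DEFAULT_NETWORKS:
        idx = _network_indices(net)
        edges.extend(_ring_edges(idx, base_gain))
        if group == "high" and net.name == "sensory":
            edges.extend(_hub_edges(idx, hub_gain))
        if group == "low" and net.name == "motor":
            edges.extend(_hub_edges(idx, hub_gain))
    return CouplingSpec(n_rois=len(DEFAULT_ROI_LABELS), edges=tuple(edges),
                        noise_sd=noise_sd, instantaneous_mix=instantaneous_mix)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout mirroring the study: 16 low / 13 high fatigue.

    ``fss_params`` maps group -> (mean, sd) of a truncated normal: the high
    group on (4, 7], the low group on [1, 4], so labels are always
    consistent with the FSS-7 > 4 rule.  ``group_effect=True`` plants the
    default sensory-up / motor-down hub difference; ``False`` gives both
    groups the identical baseline structure (null cohort).
    """

    n_low: int = 16
    n_high: int = 13
    sex_counts: dict = field(default_factory=lambda: {
        "low": {"male": 13, "female": 3},
        "high": {"male": 5, "female": 8},
    })
    fss_params: dict = field(default_factory=lambda: {
        "low": (2.1, 0.8), "high": (5.6, 0.6),
    })
    duration_s: float = 420.0
    rate_hz: float = 250.0
    seed: int = 0
    group_effect: bool = True
    hub_gain: float = HUB_GAIN
    noise_sd: float = 0.3
    coupling_overrides: Optional[dict] = None  # group -> CouplingSpec

    def __post_init__(self) -> None:
        if self.n_low < 2 or self.n_high < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.duration_s * self.rate_hz < 2 * 2.0 * self.rate_hz:
            raise ValueError("recording must span at least 2 epochs")
        if self.fss_params["high"][0] <= 4.0 or self.fss_params["low"][0] > 4.0:
            raise ValueError(
                "degenerate fss_params: group means must fall on their own "
                "side of the FSS-7 > 4 boundary"
            )
        for g in ("low", "high"):
            n = self.n_low if g == "low" else self.n_high
            if sum(self.sex_counts[g].values()) != n:
                raise ValueError(f"sex counts for group {g!r} do not sum to {n}")

    @property
    def n_subjects(self) -> int:
        return self.n_low + self.n_high


@dataclass
class CohortDataset:
    subjects: list[SubjectRecord]
    roi_series: dict  # subject id -> RoiTimeSeries
    provenance: dict


def _truncnorm(lo: float, hi: float, mean: float, sd: float,
               size: int, rng: np.random.Generator) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def _draw_subject(sid: str, group: str, sex: str, spec: CohortSpec,
                  rng: np.random.Generator) -> SubjectRecord:
    mean, sd = spec.fss_params[group]
    lo, hi = ((4.05, 7.0) if group == "high" else (1.0, 4.0))
    fss = round(float(_truncnorm(lo, hi, mean, sd, 1, rng)[0]), 2)
    anx_mean = 7.0 if group == "high" else 5.0
    dep_mean = 6.5 if group == "high" else 4.0
    return SubjectRecord(
        id=sid, fss7=fss, fatigue_group=classify_fatigue(fss),
        sex=sex,
        age=float(np.clip(rng.normal(62.0, 7.0), 30.0, 85.0).round(1)),
        grip_pct=float(np.clip(rng.normal(95.0, 10.0), 60.0, 130.0).round(1)),
        nhpt_pct=float(np.clip(rng.normal(90.0, 12.0), 60.0, 130.0).round(1)),
        hads_anx=float(np.clip(rng.normal(anx_mean, 3.0), 0.0, 21.0).round(0)),
        hads_dep=float(np.clip(rng.normal(dep_mean, 2.2), 0.0, 11.0).round(0)),
        hemisphere_affected="left" if rng.random() < 0.55 else "right",
        stroke_type="ischaemic" if rng.random() < 26 / 29 else "hemorrhagic",
        time_post_stroke=float(np.exp(rng.normal(np.log(6.0), 0.4)).round(1)),
        vascular_territory=(None if rng.random() < 5 / 29 else
                            rng.choice(["MCA", "PCA", "Brainstem/Cerebellum"],
                                       p=[0.67, 0.08, 0.25])),
    )


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate a full cohort: subject table plus per-subject ROI series.

    Group membership, sex composition and FSS-7 scores follow the spec;
    each subject's ROI series is generated with their group's coupling
    structure.  Bit-identical given the same spec and seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    meta_ss, *subject_ss = ss.spawn(spec.n_subjects + 1)
    meta_rng = np.random.default_rng(meta_ss)

    roles = ([("low", s) for s, c in spec.sex_counts["low"].items()
              for _ in range(c)] +
             [("high", s) for s, c in spec.sex_counts["high"].items()
              for _ in range(c)])
    order = meta_rng.permutation(len(roles))

    if spec.coupling_overrides is not None:
        coupling = dict(spec.coupling_overrides)
    elif spec.group_effect:
        coupling = {g: default_coupling_spec(g, hub_gain=spec.hub_gain,
                                             noise_sd=spec.noise_sd)
                    for g in ("low", "high")}
    else:
        null = default_coupling_spec(None, noise_sd=spec.noise_sd)
        coupling = {"low": null, "high": null}

    subjects, series = [], {}
    for k, pos in enumerate(order):
        group, sex = roles[pos]
        sid = f"S{k + 1:02d}"
        rng = np.random.default_rng(subject_ss[k])
        subjects.append(_draw_subject(sid, group, sex, spec, rng))
        series[sid] = generate_roi_timeseries(
            coupling[group], spec.duration_s, spec.rate_hz,
            seed=subject_ss[k].spawn(1)[0])
    return CohortDataset(subjects=subjects, roi_series=series,
                         provenance={"seed": spec.seed,
                                     "n_low": spec.n_low,
                                     "n_high": spec.n_high,
                                     "group_effect": spec.group_effect,
                                     "hub_gain": spec.hub_gain,
                                     "duration_s": spec.duration_s,
                                     "rate_hz": spec.rate_hz})


# ---------------------------------------------------------------------------
# scalp projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactSpec:
    """Injected artifacts with ground-truth timing.

    Amplitudes are in multiples of the clean recording's across-channel SD.
    """

    blink_times_s: tuple[float, ...] = ()
    blink_amplitude_sd: float = 10.0
    blink_duration_s: float = 0.4
    spike_times_s: tuple[float, ...] = ()
    spike_amplitude_sd: float = 10.0
    spike_duration_s: float = 0.1


def _frontal_profile(labels: tuple[str, ...]) -> np.ndarray:
    w = np.full(len(labels), 0.05)
    matched = False
    for i, lab in enumerate(labels):
        if lab.startswith(("Fp", "AF")):
            w[i] = 1.0
            matched = True
        elif lab.startswith(("FT", "FC")):
            w[i] = 0.3
        elif lab.startswith(("F", "Iz")):
            w[i] = 0.6
    if not matched:  # generic labels: treat the leading channels as frontal
        q = max(1, len(labels) // 4)
        w[:q] = 1.0
        w[q:2 * q] = 0.3
    return w


def project_to_scalp(roi: RoiTimeSeries, n_channels: int = 64,
                     artifact_spec: Optional[ArtifactSpec] = None,
                     seed: int | np.random.SeedSequence = 0,
                     rate_hz: float = 1000.0,
                     sensor_noise_sd: float = 0.5
                     ) -> tuple[Recording, dict]:
    """Mix ROI series to scalp channels with a random full-rank forward map.

    The ROI series are upsampled to ``rate_hz`` (default 1 kHz), mixed
    through a random Gaussian matrix (not a physical head model), scaled to
    microvolt-like amplitudes, and optionally contaminated with blink-like
    frontal transients and high-amplitude spikes at known times.  Returns
    the recording and a ground-truth artifact log (times and the indices of
    the 2-s epochs they fall in).
    """
    if n_channels < roi.n_rois:
        raise ValueError("need at least as many channels as ROIs")
    if rate_hz < roi.rate_hz or (rate_hz / roi.rate_hz) % 1:
        raise ValueError("scalp rate must be an integer multiple of ROI rate")
    rng = np.random.default_rng(seed)
    up = int(rate_hz / roi.rate_hz)
    x = resample_poly(roi.data, up, 1, axis=1, padtype="line") if up > 1 \
        else roi.data
    M = rng.standard_normal((n_channels, roi.n_rois)) / np.sqrt(roi.n_rois)
    if np.linalg.matrix_rank(M) < roi.n_rois:  # astronomically unlikely
        M += 0.01 * np.eye(n_channels, roi.n_rois)
    data = 20.0 * (M @ x)
    if sensor_noise_sd > 0:
        data = data + sensor_noise_sd * rng.standard_normal(data.shape)
    labels = (STANDARD_64_LABELS if n_channels == 64
              else tuple(f"CH{k:02d}" for k in range(n_channels)))

    spec = artifact_spec or ArtifactSpec()
    n = data.shape[1]
    sd = data.std()
    log = {"blink_times_s": list(spec.blink_times_s),
           "spike_times_s": list(spec.spike_times_s),
           "epochs_affected": set()}

    def _mark(t0: float, dur: float) -> None:
        e0 = int(t0 // 2.0)
        e1 = int((t0 + dur) // 2.0)
        log["epochs_affected"].update(range(e0, e1 + 1))

    frontal = _frontal_profile(labels)
    for t in spec.blink_times_s:
        i0 = int(round(t * rate_hz))
        L = int(round(spec.blink_duration_s * rate_hz))
        if i0 + L > n:
            raise ValueError(f"blink at {t} s extends past the recording")
        pulse = np.hanning(L) * spec.blink_amplitude_sd * sd
        data[:, i0:i0 + L] += frontal[:, None] * pulse[None, :]
        _mark(t, spec.blink_duration_s)
    for t in spec.spike_times_s:
        i0 = int(round(t * rate_hz))
        L = int(round(spec.spike_duration_s * rate_hz))
        if i0 + L > n:
            raise ValueError(f"spike at {t} s extends past the recording")
        data[:, i0:i0 + L] += spec.spike_amplitude_sd * sd
        _mark(t, spec.spike_duration_s)
    log["epochs_affected"] = sorted(log["epochs_affected"])
    return Recording(data, rate_hz, labels, reference_label="FCz"), log
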