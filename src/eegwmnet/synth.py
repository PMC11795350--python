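"""Synthetic cohorts, task sequences and phase-coupled EEG epochs.

This module generates everything the downstream pipeline consumes, so the
whole analysis chain is testable without any recorded data: a cohort of
subjects spanning ages 20-81 with cognitive/behavioural scores, visual
short-term-memory-binding (VSTMB) trial sequences, and multichannel epochs
built from per-band oscillators whose phase coupling can be made
age-dependent.  The oscillator model is deliberately simple: per-band
sinusoids with slowly drifting random phase plus 1/f noise, with coupling
implemented as copy-with-lag on a fraction ``g`` of epochs.  That gives
analytically predictable weighted-phase-lag-index limits (g=0 -> 0,
g=1 -> 1), which is what makes the estimator testable.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Montage and constants
# --------------------------------------------------------------------------

#: The 30-channel 10-20 montage used throughout (order fixed).
MONTAGE_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

CONDITIONS: tuple[str, str] = ("shape", "binding")

SRATE: int = 256          # Hz
EPOCH_LEN_MS: int = 1000  # one-second test-locked epochs
SAMPLES_PER_EPOCH: int = SRATE * EPOCH_LEN_MS // 1000

AGE_MIN_DEFAULT: float = 20.0
AGE_MAX_DEFAULT: float = 81.0

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Carrier frequency (Hz) of each band's oscillator component.
BAND_CARRIERS: dict[str, float] = {
    "delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 38.0,
}

#: Oscillation amplitude per band, microvolts (1/f-like amplitude profile).
BAND_AMPLITUDES: dict[str, float] = {
    "delta": 4.0, "theta": 3.0, "alpha": 5.0, "beta": 2.0, "gamma": 1.2,
}

DOMAINS: tuple[str, ...] = (
    "episodic", "visual", "attention", "executive", "language", "visuospatial",
)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Ordered 10-20 electrode labels; label -> 0-based index is a bijection."""

    labels: tuple[str, ...] = MONTAGE_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 30 or len(set(self.labels)) != 30:
            raise ValueError("montage must contain exactly 30 unique labels")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def __len__(self) -> int:
        return len(self.labels)


DEFAULT_MONTAGE = ElectrodeMontage()

# --------------------------------------------------------------------------
# Subject records and cognition curves
# --------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    education: int
    mmse: float
    bdi: float
    domain_scores: dict[str, float]
    accuracy: dict[str, float]  # condition -> % correct
    rt: dict[str, float]        # condition -> ms

    def __post_init__(self) -> None:
        if set(self.domain_scores) != set(DOMAINS):
            raise ValueError("domain_scores must cover the six cognitive domains")
        for cond, acc in self.accuracy.items():
            if not 0.0 <= acc <= 100.0:
                raise ValueError(f"accuracy[{cond}] outside [0, 100]")


def _relu(x: float) -> float:
    return x if x > 0.0 else 0.0


def cognition_means(age: float) -> dict[str, float]:
    """Ground-truth mean outcome curves at a given age.

    Piecewise-linear-with-hinge curves chosen to mirror the qualitative
    aging literature the pipeline is meant to detect: task accuracy high and
    declining after ~50, language peaking around 45, visuospatial ability
    dropping sharply after 70, reaction time slowing late in life.  The
    parameters here are the generator's ground truth; recovery tests compare
    against these exact values.
    """
    a = float(age)
    return {
        "mmse": min(30.0, 29.8 - 0.020 * (a - 20.0)),
        "bdi": 4.0 + 0.050 * (a - 20.0),
        "episodic": 0.8 - 0.020 * (a - 20.0) - 0.030 * _relu(a - 50.0),
        "visual": 0.8 - 0.015 * (a - 20.0) - 0.040 * _relu(a - 60.0),
        "attention": 0.7 - 0.025 * (a - 20.0) - 0.020 * _relu(a - 50.0),
        "executive": 0.6 - 0.005 * (a - 20.0) - 0.035 * _relu(a - 50.0),
        "language": 0.2 + 0.030 * min(a - 20.0, 25.0) - 0.025 * _relu(a - 45.0),
        "visuospatial": 0.6 - 0.005 * (a - 20.0) - 0.060 * _relu(a - 70.0),
        "accuracy_shape": 94.0 - 0.080 * (a - 20.0) - 0.450 * _relu(a - 50.0),
        "accuracy_binding": 88.0 - 0.180 * (a - 20.0) - 0.200 * _relu(a - 55.0),
        "rt_shape": 600.0 + 2.0 * (a - 20.0) + 8.0 * _relu(a - 65.0),
        "rt_binding": 700.0 + 2.5 * (a - 20.0) + 10.0 * _relu(a - 70.0),
    }


#: Gaussian noise s.d. applied around each mean curve (units of the outcome).
COGNITION_NOISE_SD: dict[str, float] = {
    "mmse": 0.5, "bdi": 3.0,
    "episodic": 0.4, "visual": 0.4, "attention": 0.4,
    "executive": 0.4, "language": 0.4, "visuospatial": 0.4,
    "accuracy_shape": 4.0, "accuracy_binding": 5.0,
    "rt_shape": 60.0, "rt_binding": 80.0,
}


def simulate_cognition(
    age: float,
    seed: int | np.random.Generator,
    noise_scale: float = 1.0,
    age_range: tuple[float, float] = (AGE_MIN_DEFAULT, AGE_MAX_DEFAULT),
) -> tuple[float, float, dict[str, float], dict[str, float], dict[str, float]]:
    """Draw (mmse, bdi, domain_scores, accuracy, rt) for one subject.

    ``noise_scale`` multiplies every outcome's noise s.d.; 0 returns the
    mean curves exactly.  MMSE is clipped to [27, 30] and BDI to [0, 17]
    because the cohort emulates *included* subjects (the study's exclusion
    rule removes MMSE < 27 or BDI > 17).
    """
    lo, hi = age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range [{lo}, {hi}]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means = cognition_means(age)

    def draw(key: str) -> float:
        return means[key] + noise_scale * COGNITION_NOISE_SD[key] * rng.standard_normal()

    mmse = float(np.clip(draw("mmse"), 27.0, 30.0))
    bdi = float(np.clip(draw("bdi"), 0.0, 17.0))
    domains = {d: float(draw(d)) for d in DOMAINS}
    accuracy = {
        "shape": float(np.clip(draw("accuracy_shape"), 0.0, 100.0)),
        "binding": float(np.clip(draw("accuracy_binding"), 0.0, 100.0)),
    }
    rt = {
        "shape": float(max(200.0, draw("rt_shape"))),
        "binding": float(max(200.0, draw("rt_binding"))),
    }
    return mmse, bdi, domains, accuracy, rt


def simulate_cohort(
    n_subjects: int = 39,
    age_min: float = AGE_MIN_DEFAULT,
    age_max: float = AGE_MAX_DEFAULT,
    seed: int | None = None,
    noise_scale: float = 1.0,
) -> list[SubjectRecord]:
    """Simulate an included cohort with ages stratified-uniform over the range.

    The age axis is split into ``n_subjects`` equal strata with one uniform
    draw per stratum, so even a 39-subject cohort covers 20-81 without gaps.
    Deterministic for a fixed seed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if not age_min < age_max:
        raise ValueError("age_min must be strictly less than age_max")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    edges = np.linspace(age_min, age_max, n_subjects + 1)
    ages = rng.uniform(edges[:-1], edges[1:])
    records = []
    for i, age in enumerate(ages):
        sex = "F" if rng.random() < 0.5 else "M"
        education = int(rng.integers(8, 21))
        mmse, bdi, domains, acc, rt = simulate_cognition(
            float(age), rng, noise_scale=noise_scale, age_range=(age_min, age_max)
        )
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                age=float(age),
                sex=sex,
                education=education,
                mmse=mmse,
                bdi=bdi,
                domain_scores=domains,
                accuracy=acc,
                rt=rt,
            )
        )
    return records


# --------------------------------------------------------------------------
# Trial sequences
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    condition: str
    probe_type: str  # "same" | "different"
    study_duration_ms: int = 1000
    delay_ms: int = 1200


@dataclass
class TrialSequence:
    trials: list[Trial]

    def __post_init__(self) -> None:
        counts = self.counts
        if len(self.trials) != 96 or any(counts[c] != 48 for c in CONDITIONS):
            raise ValueError("a session holds 96 stimuli, 48 per condition")

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            out[t.condition] += 1
        return out


N_TRIALS_TOTAL = 96
N_TRIALS_PER_CONDITION = 48
_BLOCK_LEN = 12  # 8 alternating blocks of 12 trials


def simulate_trials(seed: int) -> TrialSequence:
    """One VSTMB session: 96 trials, 48 per condition, P(same) = 0.5.

    Conditions alternate blockwise (blocks of 12); which condition leads is
    randomized per seed, emulating counterbalancing across participants.
    """
    rng = np.random.default_rng(seed)
    first = int(rng.integers(0, 2))
    order = [CONDITIONS[(first + b) % 2] for b in range(N_TRIALS_TOTAL // _BLOCK_LEN)]
    trials = []
    for cond in order:
        for _ in range(_BLOCK_LEN):
            probe = "same" if rng.random() < 0.5 else "different"
            trials.append(Trial(condition=cond, probe_type=probe))
    return TrialSequence(trials=trials)


# --------------------------------------------------------------------------
# Epoch arrays
# --------------------------------------------------------------------------


@dataclass
class EpochArray:
    """Stack of fixed-length multichannel voltage epochs (microvolts)."""

    subject_id: str
    condition: str
    data: np.ndarray  # (n_epochs, 30, 256) float64, microvolts
    srate: int = SRATE
    epoch_len_ms: int = EPOCH_LEN_MS
    montage: ElectrodeMontage = field(default_factory=ElectrodeMontage)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = self.srate * self.epoch_len_ms // 1000
        if self.data.ndim != 3 or self.data.shape[1] != len(self.montage):
            raise ValueError(
                f"data must be (epochs, {len(self.montage)}, {expected}); got {self.data.shape}"
            )
        if self.data.shape[2] != expected:
            raise ValueError(
                f"samples per epoch must be {expected}; got {self.data.shape[2]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


# --------------------------------------------------------------------------
# Coupling profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeResponse:
    """Named age-response curve for a band's coupling strength g(age) in [0,1].

    kinds:
      constant    -- params: g
      linear      -- params: g_young (value at age 20), g_old (value at age 81)
      changepoint -- params: g_before, g_after, age0, ramp_years (linear ramp
                     from g_before at age0 to g_after at age0 + ramp_years)
    """

    kind: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "changepoint"):
            raise ValueError(f"unknown age-response kind {self.kind!r}")

    def strength(self, age: float) -> float:
        p = self.params
        if self.kind == "constant":
            g = p["g"]
        elif self.kind == "linear":
            frac = (age - AGE_MIN_DEFAULT) / (AGE_MAX_DEFAULT - AGE_MIN_DEFAULT)
            g = p["g_young"] + (p["g_old"] - p["g_young"]) * frac
        else:  # changepoint
            ramp = p.get("ramp_years", 20.0)
            if age <= p["age0"]:
                g = p["g_before"]
            else:
                frac = min(1.0, (age - p["age0"]) / ramp)
                g = p["g_before"] + (p["g_after"] - p["g_before"]) * frac
        return float(np.clip(g, 0.0, 1.0))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}


@dataclass(frozen=True)
class BandCoupling:
    """Coupled channel pairs, their phase lag and age-dependent strength."""

    pairs: tuple[tuple[str, str], ...]
    phase_lag: float  # radians, must avoid 0 and pi for detectable wPLI
    strength: AgeResponse

    def __post_init__(self) -> None:
        d = abs(self.phase_lag) % (2 * math.pi)
        if d < 1e-9 or abs(d - math.pi) < 1e-9:
            raise ValueError("phase lag must differ from 0 and pi")

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "phase_lag": self.phase_lag,
            "strength": self.strength.to_dict(),
        }


@dataclass(frozen=True)
class NoiseSpec:
    """Background 1/f^exponent noise; snr is oscillation-RMS / noise-RMS."""

    exponent: float = 1.0
    snr: float = 1.5


@dataclass(frozen=True)
class CouplingProfile:
    bands: dict[str, BandCoupling] = field(default_factory=dict)
    noise: NoiseSpec = NoiseSpec()

    def validate(self, montage: ElectrodeMontage) -> None:
        for band, bc in self.bands.items():
            if band not in BAND_ORDER:
                raise ValueError(f"unknown band {band!r}")
            for src, dst in bc.pairs:
                montage.index(src)
                montage.index(dst)

    def to_dict(self) -> dict:
        return {
            "bands": {b: c.to_dict() for b, c in self.bands.items()},
            "noise": {"exponent": self.noise.exponent, "snr": self.noise.snr},
        }


def profile_from_dict(d: dict) -> CouplingProfile:
    bands = {
        b: BandCoupling(
            pairs=tuple(tuple(p) for p in c["pairs"]),
            phase_lag=float(c["phase_lag"]),
            strength=AgeResponse(
                kind=c["strength"]["kind"],
                params={k: float(v) for k, v in c["strength"]["params"].items()},
            ),
        )
        for b, c in d["bands"].items()
    }
    noise = NoiseSpec(
        exponent=float(d["noise"]["exponent"]), snr=float(d["noise"]["snr"])
    )
    return CouplingProfile(bands=bands, noise=noise)


#: Default study-condition profile: posterior alpha coupling declining with
#: age (the effect the analysis is designed to detect), age-stable coupling
#: in the other bands.
DEFAULT_PROFILE = CouplingProfile(
    bands={
        "alpha": BandCoupling(
            pairs=(("O1", "O2"), ("P3", "P4"), ("O1", "P3"), ("O2", "P4"), ("Pz", "Oz")),
            phase_lag=math.pi / 4,
            strength=AgeResponse("linear", {"g_young": 0.8, "g_old": 0.25}),
        ),
        "theta": BandCoupling(
            pairs=(("Fz", "Cz"), ("F3", "F4"), ("FCz", "Cz")),
            phase_lag=math.pi / 4,
            strength=AgeResponse("constant", {"g": 0.5}),
        ),
        "delta": BandCoupling(
            pairs=(("Fp1", "Fp2"),),
            phase_lag=math.pi / 3,
            strength=AgeResponse("constant", {"g": 0.4}),
        ),
        "beta": BandCoupling(
            pairs=(("C3", "C4"),),
            phase_lag=math.pi / 4,
            strength=AgeResponse("constant", {"g": 0.4}),
        ),
        "gamma": BandCoupling(
            pairs=(("O1", "Oz"),),
            phase_lag=math.pi / 4,
            strength=AgeResponse("constant", {"g": 0.3}),
        ),
    },
)

#: Profile with no deterministic coupling anywhere (null condition).
NULL_PROFILE = CouplingProfile(bands={})

PROFILES: dict[str, CouplingProfile] = {
    "default": DEFAULT_PROFILE,
    "null": NULL_PROFILE,
}

# Epoch-count model per condition: truncated normal calibrated to the
# artifact-free epoch numbers typical of this paradigm (mean 38, sd 6, >= 20).
EPOCH_COUNT_MEAN = 38.0
EPOCH_COUNT_SD = 6.0
EPOCH_COUNT_MIN = 20


def draw_epoch_count(rng: np.random.Generator) -> int:
    while True:
        n = int(round(rng.normal(EPOCH_COUNT_MEAN, EPOCH_COUNT_SD)))
        if n >= EPOCH_COUNT_MIN:
            return n


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, exponent: float
) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (
        rng.standard_normal(shape + (freqs.size,))
        + 1j * rng.standard_normal(shape + (freqs.size,))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def simulate_epochs(
    subject: SubjectRecord,
    condition: str,
    profile: CouplingProfile,
    n_epochs: int,
    seed: int,
    montage: ElectrodeMontage = DEFAULT_MONTAGE,
) -> EpochArray:
    """Generate phase-coupled multichannel epochs for one subject/condition.

    Each channel is a sum over the five bands of a narrowband oscillator
    (carrier at the band centre, slowly drifting random phase) plus 1/f
    noise.  For every coupled pair in band b the target channel's band-b
    phase track is replaced, on a fraction g_b(age) of epochs, by the source
    track shifted by the profile's lag (phase-resetting coupling);
    on the remaining epochs the channels are independent.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if n_epochs < 8:
        raise ValueError("need at least 8 epochs for spectral estimation")
    profile.validate(montage)
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    n_s = SAMPLES_PER_EPOCH
    t = np.arange(n_s) / SRATE

    data = np.zeros((n_epochs, n_ch, n_s))
    osc_power = np.zeros((n_epochs, n_ch, 1))
    for band in BAND_ORDER:
        f_c = BAND_CARRIERS[band]
        amp = BAND_AMPLITUDES[band]
        phi0 = rng.uniform(0.0, 2.0 * np.pi, size=(n_epochs, n_ch, 1))
        # slow random-walk phase drift keeps the oscillation narrowband
        drift = np.cumsum(rng.normal(0.0, 0.03, size=(n_epochs, n_ch, n_s)), axis=-1)
        phase = 2.0 * np.pi * f_c * t[None, None, :] + phi0 + drift
        bc = profile.bands.get(band)
        if bc is not None:
            g = bc.strength.strength(subject.age)
            for src, dst in bc.pairs:
                i, j = montage.index(src), montage.index(dst)
                coupled = rng.random(n_epochs) < g
                phase[coupled, j, :] = phase[coupled, i, :] + bc.phase_lag
        comp = amp * np.cos(phase)
        data += comp
        osc_power += np.mean(comp**2, axis=-1, keepdims=True)

    noise = _one_over_f_noise(rng, (n_epochs, n_ch), n_s, profile.noise.exponent)
    noise_rms = np.sqrt(osc_power) / profile.noise.snr
    data += noise * noise_rms
    return EpochArray(
        subject_id=subject.subject_id, condition=condition, data=data, montage=montage
    )


# --------------------------------------------------------------------------
# Artifact injection (fixtures for the rejection criteria)
# --------------------------------------------------------------------------

ARTIFACT_KINDS = ("amplitude", "step", "flatline")


def inject_artifacts(
    epochs: EpochArray,
    kind: str,
    epoch_indices: Sequence[int],
    magnitude: float,
    seed: int,
) -> EpochArray:
    """Contaminate selected epochs with one artifact type; others untouched.

    amplitude -- add a +-``magnitude`` uV deflection (smooth bump, one channel)
    step      -- insert a ``magnitude`` uV jump between adjacent samples
    flatline  -- rescale a 100-ms window so its peak-to-peak < ``magnitude`` uV
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    n_e, n_ch, n_s = epochs.data.shape
    for idx in epoch_indices:
        if not 0 <= idx < n_e:
            raise IndexError(f"epoch index {idx} out of range [0, {n_e})")
    rng = np.random.default_rng(seed)
    data = epochs.data.copy()
    win = int(round(0.100 * epochs.srate))  # 100-ms flatline window
    for idx in epoch_indices:
        ch = int(rng.integers(0, n_ch))
        if kind == "amplitude":
            center = int(rng.integers(n_s // 4, 3 * n_s // 4))
            # deflect away from zero so the peak reaches +-magnitude
            sign = 1.0 if data[idx, ch, center] >= 0 else -1.0
            bump = np.exp(-0.5 * ((np.arange(n_s) - center) / 12.0) ** 2)
            data[idx, ch, :] += sign * magnitude * bump
        elif kind == "step":
            split = int(rng.integers(n_s // 4, 3 * n_s // 4))
            data[idx, ch, split:] += magnitude
        else:  # flatline
            start = int(rng.integers(0, n_s - win + 1))
            seg = data[idx, ch, start : start + win]
            ptp = float(seg.max() - seg.min())
            target = 0.5 * magnitude  # comfortably below the criterion
            scale = target / ptp if ptp > 0 else 0.0
            data[idx, ch, start : start + win] = seg.mean() + (seg - seg.mean()) * scale
    return EpochArray(
        subject_id=epochs.subject_id,
        condition=epochs.condition,
        data=data,
        srate=epochs.srate,
        epoch_len_ms=epochs.epoch_len_ms,
        montage=epochs.montage,
    )


# --------------------------------------------------------------------------
# External interfaces: cohort CSV and EDF + sidecar
# --------------------------------------------------------------------------

COHORT_COLUMNS = (
    ["subject_id", "age", "sex", "education", "mmse", "bdi"]
    + list(DOMAINS)
    + [f"accuracy_{c}" for c in CONDITIONS]
    + [f"rt_{c}" for c in CONDITIONS]
)


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for r in records:
            w.writerow(
                [r.subject_id, f"{r.age:.3f}", r.sex, r.education,
                 f"{r.mmse:.3f}", f"{r.bdi:.3f}"]
                + [f"{r.domain_scores[d]:.6f}" for d in DOMAINS]
                + [f"{r.accuracy[c]:.4f}" for c in CONDITIONS]
                + [f"{r.rt[c]:.2f}" for c in CONDITIONS]
            )


def read_cohort_csv(path) -> list[SubjectRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    education=int(row["education"]),
                    mmse=float(row["mmse"]),
                    bdi=float(row["bdi"]),
                    domain_scores={d: float(row[d]) for d in DOMAINS},
                    accuracy={c: float(row[f"accuracy_{c}"]) for c in CONDITIONS},
                    rt={c: float(row[f"rt_{c}"]) for c in CONDITIONS},
                )
            )
    return records


def write_epochs_edf(
    epochs: EpochArray,
    path,
    subject: SubjectRecord | None = None,
    profile: CouplingProfile | None = None,
) -> None:
    """Write epochs as one EDF file plus a JSON sidecar (<path>.json)."""
    from . import _edf

    _edf.write_edf(
        path,
        epochs.data,
        channel_labels=epochs.montage.labels,
        srate=epochs.srate,
        physical_dim="uV",
    )
    sidecar = {
        "subject_id": epochs.subject_id,
        "condition": epochs.condition,
        "n_epochs": int(epochs.n_epochs),
        "srate": int(epochs.srate),
        "epoch_len_ms": int(epochs.epoch_len_ms),
    }
    if subject is not None:
        sidecar["subject"] = {
            "age": subject.age, "sex": subject.sex, "education": subject.education,
            "mmse": subject.mmse, "bdi": subject.bdi,
        }
    if profile is not None:
        sidecar["coupling_profile"] = profile.to_dict()
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_epochs_edf(path, subject_id: str = "", condition: str = "") -> EpochArray:
    """Read an EDF written by :func:`write_epochs_edf` back into an EpochArray."""
    from . import _edf

    data, labels, srate = _edf.read_edf(path)
    sidecar_path = str(path) + ".json"
    try:
        with open(sidecar_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        subject_id = subject_id or meta.get("subject_id", "")
        condition = condition or meta.get("condition", "shape")
    except FileNotFoundError:
        condition = condition or "shape"
    return EpochArray(
        subject_id=subject_id,
        condition=condition,
        data=data,
        srate=int(srate),
        montage=ElectrodeMontage(labels=tuple(labels)),
    )
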