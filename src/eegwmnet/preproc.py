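"""Epoch segmentation and semi-automatic artifact rejection.

Four rejection criteria are applied per epoch, per channel:

(a) absolute amplitude above 70 uV at any sample,
(b) voltage step above 50 uV/ms between adjacent samples (the per-sample
    limit is scaled by the sampling interval: at 256 Hz one sample spans
    ~3.906 ms, so the per-sample limit is 50 x 3.906 uV),
(c) max - min range above 50 uV within any sliding 200-ms window,
(d) max - min range below 0.5 uV within any sliding 100-ms window
    (dead/flat signal).

An epoch is rejected if ANY channel violates ANY criterion; surviving
epochs pass through unmodified and in order.  Everything is logged: the
original procedure involved human review, this implementation is fully
automatic and auditable instead.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .synth import DEFAULT_MONTAGE, ElectrodeMontage, EpochArray

logger = logging.getLogger(__name__)

CRITERIA = ("amplitude", "step", "diff200", "lowact100")


@dataclass(frozen=True)
class RejectionCriteria:
    max_abs_amplitude: float = 70.0   # uV
    max_step: float = 50.0            # uV per ms
    max_diff_200ms: float = 50.0      # uV
    min_activity_100ms: float = 0.5   # uV

    def __post_init__(self) -> None:
        for name in ("max_abs_amplitude", "max_step", "max_diff_200ms", "min_activity_100ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class EpochVerdict:
    kept: bool
    violations: list[tuple[str, str]]  # (channel label, criterion)


@dataclass
class RejectionLog:
    verdicts: list[EpochVerdict] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return sum(v.kept for v in self.verdicts)

    @property
    def n_rejected(self) -> int:
        return len(self.verdicts) - self.n_kept

    @property
    def summary(self) -> dict[str, int]:
        """Number of epochs on which each criterion fired at least once."""
        out = {c: 0 for c in CRITERIA}
        for v in self.verdicts:
            for c in {crit for _, crit in v.violations}:
                out[c] += 1
        return out


def segment_epochs(
    continuous: np.ndarray,
    event_samples: Sequence[int],
    epoch_len_ms: int = 1000,
    srate: int = 256,
    montage: ElectrodeMontage = DEFAULT_MONTAGE,
    subject_id: str = "",
    condition: str = "shape",
) -> EpochArray:
    """Cut test-locked epochs [event, event + epoch length) from a recording.

    Events whose epoch would run past the end of the recording are skipped
    with a logged warning rather than raising.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous must be (channels, samples)")
    n_samp = continuous.shape[1]
    epoch_len = srate * epoch_len_ms // 1000
    epochs = []
    for ev in event_samples:
        if ev < 0 or ev + epoch_len > n_samp:
            logger.warning(
                "event at sample %d skipped: epoch [%d, %d) outside recording of %d samples",
                ev, ev, ev + epoch_len, n_samp,
            )
            continue
        epochs.append(continuous[:, ev : ev + epoch_len])
    data = (
        np.stack(epochs, axis=0)
        if epochs
        else np.empty((0, continuous.shape[0], epoch_len))
    )
    return EpochArray(
        subject_id=subject_id,
        condition=condition,
        data=data,
        srate=srate,
        epoch_len_ms=epoch_len_ms,
        montage=montage,
    )


def _window_range_max(data: np.ndarray, win: int) -> np.ndarray:
    """Per (epoch, channel): max over all full sliding windows of (max - min)."""
    # centred running max/min; only positions whose window lies fully inside
    # the epoch are valid
    mx = maximum_filter1d(data, size=win, axis=-1, mode="nearest")
    mn = minimum_filter1d(data, size=win, axis=-1, mode="nearest")
    left = win // 2
    right = data.shape[-1] - (win - 1 - left)
    rng = (mx - mn)[..., left:right]
    return rng.max(axis=-1)


def _window_range_min(data: np.ndarray, win: int) -> np.ndarray:
    mx = maximum_filter1d(data, size=win, axis=-1, mode="nearest")
    mn = minimum_filter1d(data, size=win, axis=-1, mode="nearest")
    left = win // 2
    right = data.shape[-1] - (win - 1 - left)
    rng = (mx - mn)[..., left:right]
    return rng.min(axis=-1)


def reject_epochs(
    epochs: EpochArray,
    criteria: RejectionCriteria = RejectionCriteria(),
) -> tuple[EpochArray, RejectionLog]:
    """Apply the four criteria; return surviving epochs and a full log.

    Raises if no epoch survives (downstream spectra would be undefined).
    """
    data = epochs.data
    n_e = data.shape[0]
    srate = epochs.srate
    ms_per_sample = 1000.0 / srate
    win200 = int(round(0.200 * srate))
    win100 = int(round(0.100 * srate))

    if n_e == 0:
        raise ValueError(
            f"no epochs to reject for {epochs.subject_id}/{epochs.condition}"
        )

    # (n_epochs, n_channels) boolean per criterion
    viol = {
        "amplitude": np.abs(data).max(axis=-1) > criteria.max_abs_amplitude,
        "step": np.abs(np.diff(data, axis=-1)).max(axis=-1)
        > criteria.max_step * ms_per_sample,
        "diff200": _window_range_max(data, win200) > criteria.max_diff_200ms,
        "lowact100": _window_range_min(data, win100) < criteria.min_activity_100ms,
    }

    labels = epochs.montage.labels
    verdicts = []
    keep_mask = np.ones(n_e, dtype=bool)
    for e in range(n_e):
        vlist = [
            (labels[ch], crit)
            for crit in CRITERIA
            for ch in np.nonzero(viol[crit][e])[0]
        ]
        kept = not vlist
        keep_mask[e] = kept
        verdicts.append(EpochVerdict(kept=kept, violations=vlist))
    log = RejectionLog(verdicts=verdicts)

    if not keep_mask.any():
        raise ValueError(
            f"all {n_e} epochs rejected for subject "
            f"{epochs.subject_id!r}, condition {epochs.condition!r}"
        )
    logger.info(
        "%s/%s: kept %d of %d epochs (%s)",
        epochs.subject_id, epochs.condition, log.n_kept, n_e, log.summary,
    )
    kept_epochs = EpochArray(
        subject_id=epochs.subject_id,
        condition=epochs.condition,
        data=data[keep_mask],
        srate=srate,
        epoch_len_ms=epochs.epoch_len_ms,
        montage=epochs.montage,
    )
    return kept_epochs, log


def write_rejection_csv(path, rows: Sequence[tuple[str, str, int, bool, str]]) -> None:
    """Write a rejection report: (subject, condition, epoch, kept, criteria)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "condition", "epoch", "kept", "criteria_fired"])
        for row in rows:
            w.writerow(row)


def log_to_rows(
    subject_id: str, condition: str, log: RejectionLog
) -> list[tuple[str, str, int, bool, str]]:
    rows = []
    for e, v in enumerate(log.verdicts):
        crits = ";".join(sorted({c for _, c in v.violations}))
        rows.append((subject_id, condition, e, v.kept, crits))
    return rows
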