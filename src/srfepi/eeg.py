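"""Seizure detection and metrics on EEG amplitude-envelope recordings.

An electrographic seizure is a high-amplitude discharge: envelope strictly
above ``threshold_ratio`` x baseline (default 2x) lasting strictly more than
``min_duration`` seconds (default 5 s).  Baseline is the median of the
unmasked envelope, which is robust as long as discharges occupy a minority of
the recording.  Sub-threshold gaps shorter than ``merge_gap`` seconds are
bridged before the duration test so one discharge is not fragmented.  Events
starting at or after 24 h post-injection are spontaneous (epileptogenesis
proper); earlier events belong to the induced status-epilepticus phase.

Racine behavioral scores (ordinal 1-5) are consumed as annotations scored from
video; they are attached to summaries, not computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

SPONTANEOUS_ONSET_S = 24 * 3600.0


@dataclass
class EnvelopeRecording:
    animal_id: str
    group: str  # CTR or KO
    sample_interval: float  # seconds per envelope sample
    envelope: np.ndarray
    artifact_mask: np.ndarray | None = None  # True = excluded
    injection_time: float = 0.0

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.envelope.size, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.size != self.envelope.size:
            raise ValueError("artifact mask length != envelope length")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if (self.envelope < 0).any():
            raise ValueError("envelope amplitudes must be nonnegative")


@dataclass
class SeizureEvent:
    start: float  # seconds from injection
    end: float
    duration: float
    peak_ratio: float
    spontaneous: bool
    racine_score: int | None = None


@dataclass
class SeizureSummary:
    animal_id: str
    group: str
    n_seizures: int
    latency_first_spontaneous_h: float | None
    frequency_per_day: float
    mean_duration_s: float | None
    mean_score: float | None


def estimate_baseline(rec: EnvelopeRecording) -> float:
    """Median of the unmasked envelope samples."""
    unmasked = rec.envelope[~rec.artifact_mask]
    if unmasked.size == 0:
        raise ValueError("all samples are masked; baseline undefined")
    return float(np.median(unmasked))


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if flags.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], flags.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_seizures(
    rec: EnvelopeRecording,
    baseline: float | None = None,
    threshold_ratio: float = 2.0,
    min_duration: float = 5.0,
    merge_gap: float = 1.0,
) -> list[SeizureEvent]:
    """Detect discharges: envelope > ratio*baseline for > min_duration seconds.

    Both inequalities are strict.  Runs separated by unmasked sub-threshold
    gaps shorter than ``merge_gap`` seconds are merged before the duration
    test.  Masked samples never start, end, or extend an event.
    """
    if baseline is None:
        baseline = estimate_baseline(rec)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    dt = rec.sample_interval
    above = (rec.envelope > threshold_ratio * baseline) & ~rec.artifact_mask
    runs = _runs(above)
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged:
            pstart, pstop = merged[-1]
            gap = slice(pstop, start)
            gap_clean = not rec.artifact_mask[gap].any()
            if gap_clean and (start - pstop) * dt < merge_gap:
                merged[-1] = (pstart, stop)
                continue
        merged.append((start, stop))
    events = []
    for start, stop in merged:
        duration = (stop - start) * dt
        if duration <= min_duration:
            continue
        t0 = start * dt - rec.injection_time
        events.append(
            SeizureEvent(
                start=t0,
                end=stop * dt - rec.injection_time,
                duration=duration,
                peak_ratio=float(rec.envelope[start:stop].max() / baseline),
                spontaneous=t0 >= SPONTANEOUS_ONSET_S,
            )
        )
    return events


def summarize_animal(
    events: Sequence[SeizureEvent],
    recording_days: float,
    animal_id: str = "",
    group: str = "",
    scores: Sequence[int] | None = None,
) -> SeizureSummary:
    """Per-animal seizure metrics over the spontaneous phase.

    Frequency is the number of spontaneous seizures divided by recording days;
    latency is hours from injection to the first spontaneous event (None if
    none occurred); scores, when given, are behavioral Racine annotations
    aligned with the event list.
    """
    if recording_days <= 0:
        raise ValueError("recording_days must be positive")
    if scores is not None:
        if len(scores) != len(events):
            raise ValueError("one score per event required")
        for ev, sc in zip(events, scores):
            if sc is not None and not 1 <= sc <= 5:
                raise ValueError(f"Racine score {sc} outside 1..5")
            ev.racine_score = sc
    spont = [e for e in events if e.spontaneous]
    latency = min((e.start for e in spont), default=None)
    durations = [e.duration for e in spont]
    score_vals = [e.racine_score for e in spont if e.racine_score is not None]
    return SeizureSummary(
        animal_id=animal_id,
        group=group,
        n_seizures=len(spont),
        latency_first_spontaneous_h=None if latency is None else latency / 3600.0,
        frequency_per_day=len(spont) / recording_days,
        mean_duration_s=float(np.mean(durations)) if durations else None,
        mean_score=float(np.mean(score_vals)) if score_vals else None,
    )


def compare_groups(
    summaries: Iterable[SeizureSummary],
    metric: str,
    test: str = "mann_whitney",
) -> dict:
    """Two-sided CTR vs KO comparison of a summary metric.

    ``test`` is "t" (Student's t, pooled variance) or "mann_whitney" (exact
    when combined n <= 20 and tie-free, normal approximation with tie
    correction otherwise).  Degenerate all-equal samples give p = 1.
    """
    attr = {
        "latency": "latency_first_spontaneous_h",
        "frequency": "frequency_per_day",
        "duration": "mean_duration_s",
        "score": "mean_score",
    }.get(metric, metric)
    groups: dict[str, list[float]] = {"CTR": [], "KO": []}
    for s in summaries:
        v = getattr(s, attr)
        if v is not None:
            groups[s.group].append(float(v))
    x, y = groups["CTR"], groups["KO"]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 animals per group")
    if len(set(x + y)) == 1:
        return {"metric": metric, "test": test, "statistic": float("nan"), "p_value": 1.0}
    if test == "t":
        res = sps.ttest_ind(x, y, equal_var=True)
    elif test == "mann_whitney":
        n = len(x) + len(y)
        has_ties = len(set(x + y)) < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "metric": metric,
        "test": test,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_ctr": len(x),
        "n_ko": len(y),
    }


# ---------------------------------------------------------------------------
# IO: CSV envelope series + JSON header per animal
# ---------------------------------------------------------------------------


def write_recording(rec: EnvelopeRecording, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"envelope": rec.envelope, "artifact": rec.artifact_mask.astype(int)}
    ).to_csv(directory / f"{rec.animal_id}.csv", index=False)
    header = {
        "animal_id": rec.animal_id,
        "group": rec.group,
        "sample_interval_s": rec.sample_interval,
        "injection_time": rec.injection_time,
        "units": "arbitrary amplitude",
    }
    (directory / f"{rec.animal_id}.json").write_text(json.dumps(header, indent=2))


def read_recording(directory: str | Path, animal_id: str) -> EnvelopeRecording:
    directory = Path(directory)
    header = json.loads((directory / f"{animal_id}.json").read_text())
    df = pd.read_csv(directory / f"{animal_id}.csv")
    return EnvelopeRecording(
        animal_id=header["animal_id"],
        group=header["group"],
        sample_interval=float(header["sample_interval_s"]),
        envelope=df["envelope"].to_numpy(),
        artifact_mask=df["artifact"].to_numpy().astype(bool),
        injection_time=float(header.get("injection_time", 0.0)),
    )
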