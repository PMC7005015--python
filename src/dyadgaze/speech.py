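"""Coding of speaking and listening periods from speech annotations.

Annotations are event streams per participant x task x speaker role:
``speech_on`` (first audible speech), ``speech_off`` (speaker stopped),
``interruption`` (partner interrupted), and ``resume_second_sentence``
(start of the second sentence after the speaker resumed — an explicit
annotation token, mirroring manual coding, never inferred from audio).

Coding rules:

* a period runs from ``speech_on`` to ``speech_off``;
* total coded speech is cropped at 30 s per task so every participant
  contributes a comparable amount of data;
* an interruption ends coding at the instant just preceding it — if at
  least 20 s were coded the period stands and coding ends; if less, that
  first segment is discarded as insufficient and a single second segment
  is coded from the ``resume_second_sentence`` event (gaze is typically
  averted right at speech onset, hence the second sentence);
* no third segment is ever coded.

Speaking periods come from the participant's own speech events; listening
periods are coded symmetrically from the partner's.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .errors import AnnotationError

__all__ = ["SpeechPeriod", "code_speech_periods", "periods_to_frame"]

#: annotation roles mapped to the gaze condition of the wearer
ROLE_TO_STATE = {"participant": "speaking", "partner": "listening"}

EVENT_TYPES = {"speech_on", "speech_off", "interruption",
               "resume_second_sentence"}


@dataclass(frozen=True)
class SpeechPeriod:
    participant: str
    task: str
    role: str  # "speaking" | "listening"
    t_start: float  # ms
    t_end: float    # ms
    segment_index: int  # 1 or 2

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _code_one_speaker(events: pd.DataFrame, participant: str, task: str,
                      role: str, config: AnalysisConfig) -> list[SpeechPeriod]:
    """State machine over one speaker's time-ordered events."""
    crop_ms = config.speech_crop_s * 1000.0
    min_ms = config.interruption_min_s * 1000.0
    segments: list[tuple[float, float, int]] = []
    open_t: float | None = None
    awaiting_resume = False
    seg_index = 1
    done = False
    last_t = float("-inf")
    for row in events.itertuples(index=False):
        ev, t = row.event, float(row.t_ms)
        if ev not in EVENT_TYPES:
            raise AnnotationError(
                f"unknown event {ev!r} at t={t} ({participant}/{task})")
        if t < last_t:
            raise AnnotationError(
                f"events out of order at t={t} ({participant}/{task})")
        last_t = t
        if done:
            break
        if ev == "speech_on":
            if open_t is not None:
                raise AnnotationError(
                    f"speech_on at t={t} while speech already open "
                    f"({participant}/{task})")
            if not awaiting_resume:  # resumption is governed by its token
                open_t = t
        elif ev == "speech_off":
            if open_t is not None:
                segments.append((open_t, t, seg_index))
                open_t = None
                done = True
        elif ev == "interruption":
            if open_t is None:
                continue
            if t - open_t >= min_ms:
                # enough data coded before the interruption: period ends
                # at the instant just preceding it
                segments.append((open_t, t, seg_index))
                open_t = None
                done = True
            elif seg_index == 1:
                # insufficient first segment: discard, await the second
                # sentence after resumption
                open_t = None
                awaiting_resume = True
            else:
                # second segment interrupted early: keep what was coded;
                # no third segment is ever used
                segments.append((open_t, t, seg_index))
                open_t = None
                done = True
        elif ev == "resume_second_sentence":
            if awaiting_resume:
                open_t = t
                awaiting_resume = False
                seg_index = 2
    if open_t is not None:
        raise AnnotationError(
            f"speech_on at t={open_t} never closed ({participant}/{task})")

    # crop cumulative coded speech at the per-task cap
    periods: list[SpeechPeriod] = []
    coded = 0.0
    for t0, t1, idx in segments:
        if coded >= crop_ms:
            break
        t1 = min(t1, t0 + (crop_ms - coded))
        if t1 > t0:
            periods.append(SpeechPeriod(participant, task, role, t0, t1, idx))
            coded += t1 - t0
    return periods


def code_speech_periods(annotations: pd.DataFrame,
                        config: AnalysisConfig | None = None,
                        ) -> list[SpeechPeriod]:
    """Code speaking and listening periods from a speech event table.

    ``annotations`` has columns ``participant``, ``task``, ``event``,
    ``role`` (``participant``/``partner``, the speaker), ``t_ms``.
    Returns time-ordered periods; the wearer's own speech codes as
    ``speaking``, the partner's as ``listening``.
    """
    config = config or AnalysisConfig()
    if len(annotations) == 0:
        return []
    periods: list[SpeechPeriod] = []
    for (pid, task, speaker), group in annotations.groupby(
            ["participant", "task", "role"], sort=True):
        if speaker not in ROLE_TO_STATE:
            raise AnnotationError(f"unknown speaker role {speaker!r}")
        group = group.sort_values("t_ms", kind="stable")
        periods.extend(_code_one_speaker(
            group, pid, task, ROLE_TO_STATE[speaker], config))
    periods.sort(key=lambda p: (p.participant, p.task, p.role, p.t_start))
    return periods


def periods_to_frame(periods: list[SpeechPeriod]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"participant": p.participant, "task": p.task, "role": p.role,
          "t_start_ms": p.t_start, "t_end_ms": p.t_end,
          "segment_index": p.segment_index} for p in periods],
        columns=["participant", "task", "role", "t_start_ms", "t_end_ms",
                 "segment_index"])
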