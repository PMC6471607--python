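"""Rule-based recognition of valid five-time chair rise sequences.

A valid test is five sit-to-stand transitions, each directly followed —
optionally via a bounded static hold — by a stand-to-sit transition; the
trailing fifth descent is optional because the test clock stops at the end
of the fifth rise.  Any DYNAMIC or OTHER activity inside a candidate, a
static hold longer than ``max_hold_s``, or a gap in the track aborts the
candidate.  Matching is greedy left-to-right, so back-to-back tests in one
track are each detected once and never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError
from .io import (
    SIT,
    SIT_STAND,
    STAND,
    STAND_SIT,
    LabelTrack,
    Segment,
)

#: maximum admissible gap between consecutive segments inside a candidate (s)
_GAP_TOL = 0.01


@dataclass(frozen=True)
class DetectedTest:
    """One validated 5CRT occurrence.

    ``start`` is the onset of the first rise and ``end`` the end of the
    fifth rise (where the test clock stops).  ``descents`` holds 4 segments,
    or 5 when the subject's final sit-down directly followed the fifth rise.
    ``segments`` lists every consumed segment (rises, descents and the
    static holds between them) in time order.
    """

    start: float
    end: float
    rises: tuple[Segment, ...]
    descents: tuple[Segment, ...]
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.rises) != 5:
            raise ValidationError("a detected test must contain exactly 5 rises")
        if len(self.descents) not in (4, 5):
            raise ValidationError("a detected test must contain 4 or 5 descents")
        if self.segments[0].label != SIT_STAND:
            raise ValidationError("a detected test must begin with a rise")
        if abs(self.start - self.rises[0].start) > 1e-9:
            raise ValidationError("start must equal the first rise onset")
        if abs(self.end - self.rises[4].end) > 1e-9:
            raise ValidationError("end must equal the fifth rise end")
        events = [s for s in self.segments if s.label in (SIT_STAND, STAND_SIT)]
        expected = [SIT_STAND, STAND_SIT] * 5
        if [s.label for s in events] != expected[:len(events)]:
            raise ValidationError("rises and descents must alternate")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end - 1e-9:
                raise ValidationError("test segments must be time-ordered")

    @property
    def duration_s(self) -> float:
        return self.end - self.start

    @property
    def has_final_descent(self) -> bool:
        return len(self.descents) == 5


def _match_candidate(segs: list[Segment], i: int, max_hold_s: float
                     ) -> tuple[DetectedTest, int] | None:
    """Try to match a full test starting at segment ``i`` (a SIT_STAND).

    Returns (test, index of first segment after the match) or None.
    """
    rises: list[Segment] = []
    descents: list[Segment] = []
    consumed: list[Segment] = []
    j = i

    def take(expect_label: str, bounded: bool = False) -> Segment | None:
        nonlocal j
        if j >= len(segs):
            return None
        s = segs[j]
        if consumed and s.start > consumed[-1].end + _GAP_TOL:
            return None                      # unlabelled gap inside the test
        if s.label != expect_label:
            return None
        if bounded and s.duration > max_hold_s:
            return None
        consumed.append(s)
        j += 1
        return s

    for cycle in range(5):
        rise = take(SIT_STAND)
        if rise is None:
            return None
        rises.append(rise)
        last = cycle == 4
        # optional bounded STAND hold, then the descent
        saved = j
        hold = take(STAND, bounded=True)
        descent = take(STAND_SIT)
        if descent is None:
            if last:
                # fifth descent is optional: roll back any lone hold
                if hold is not None:
                    consumed.pop()
                    j = saved
                break
            return None
        descents.append(descent)
        if not last:
            take(SIT, bounded=True)          # optional bounded SIT hold
    test = DetectedTest(
        start=rises[0].start, end=rises[4].end,
        rises=tuple(rises), descents=tuple(descents),
        segments=tuple(consumed))
    return test, j


def detect_5crt(track: LabelTrack, max_hold_s: float = 30.0) -> list[DetectedTest]:
    """Scan a label track for valid five-rise test sequences.

    Greedy earliest-start matching: the scan anchors a candidate at each
    SIT_STAND segment, validates the grammar, and on success resumes after
    the consumed segments, so detected tests never overlap.  Returns the
    (possibly empty) list of tests left to right.
    """
    segs = list(track.segments)
    tests: list[DetectedTest] = []
    i = 0
    while i < len(segs):
        if segs[i].label != SIT_STAND:
            i += 1
            continue
        match = _match_candidate(segs, i, max_hold_s)
        if match is None:
            i += 1
        else:
            test, nxt = match
            tests.append(test)
            i = nxt
    return tests
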