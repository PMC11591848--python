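"""Partial-credit scoring of CBT sessions.

A trial earns one *item credit* for every block recalled in its correct
serial position; a trial is *fully correct* only if the response equals the
target exactly (same blocks, same order, same length).  A session's score is

    FinalResult = L - 1 + avLevelScore / L

where ``L`` is the highest (last) level administered — including a failed
terminal level — and ``avLevelScore`` is the mean item credit over the
trials at that level.  The score therefore lies in ``[L - 1, L]``: a
participant who fails level ``s + 1`` with zero credit scores exactly
``s``, and partial recall at the terminal level adds up to one point.

Worked example: a participant terminating at level 3 with item credits
(2, 2, 1) has avLevelScore (2 + 2 + 1)/3 = 1.67 and
FinalResult 3 - 1 + 1.67/3 = 2.56 (report-time rounding, half-up, 2 dp).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .task_engine import ResponseSequence, SessionConfig, SessionTranscript, TargetSequence

__all__ = [
    "TrialResult",
    "LevelResult",
    "SessionResult",
    "score_trial",
    "level_average",
    "final_result",
    "score_session",
    "classify_performance",
    "round_half_up",
]


@dataclass(frozen=True)
class TrialResult:
    target: TargetSequence
    response: ResponseSequence
    item_credits: int
    fully_correct: bool


@dataclass(frozen=True)
class LevelResult:
    level: int
    trials: tuple[TrialResult, ...]
    passed: bool


@dataclass(frozen=True)
class SessionResult:
    """Scored session: highest level L, avLevelScore, and FinalResult."""

    highest_level: int
    av_level_score: float
    final_score: float
    per_level: tuple[LevelResult, ...]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report-time rounding: round half away from zero toward +inf (half-up)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def score_trial(target: TargetSequence, response: ResponseSequence) -> TrialResult:
    """Credit one item per position recalled in correct order and location.

    Credits are counted over the overlap of the two sequences only: extra
    clicks beyond the target length earn nothing (and void full
    correctness), and there is no credit for a correct block in the wrong
    position.
    """
    credits = sum(
        1 for t, r in zip(target.block_ids, response.block_ids) if t == r
    )
    fully = response.block_ids == target.block_ids
    return TrialResult(
        target=target, response=response, item_credits=credits, fully_correct=fully
    )


def level_average(trials: list[TrialResult] | tuple[TrialResult, ...]) -> float:
    """Mean item credit over the trials of one level (unrounded)."""
    if not trials:
        raise ValueError("cannot average an empty trial list")
    levels = {t.target.level for t in trials}
    if len(levels) != 1:
        raise ValueError(f"trials span multiple levels: {sorted(levels)}")
    return sum(t.item_credits for t in trials) / len(trials)


def final_result(L: int, av_level_score: float) -> float:
    """The session score ``L - 1 + avLevelScore / L``."""
    if L < 1:
        raise ValueError("highest level must be >= 1")
    if not (0.0 <= av_level_score <= L):
        raise ValueError(
            f"avLevelScore must lie in [0, {L}], got {av_level_score}"
        )
    return L - 1 + av_level_score / L


def score_session(
    transcript: SessionTranscript,
    config: SessionConfig | None = None,
    divisor: str = "trials",
) -> SessionResult:
    """Score a full session transcript.

    L is the last level administered: the failed level if the session
    terminated there, or the maximum level if it was passed.  The
    ``divisor`` of the terminal-level average is the number of trials at
    that level (default, matching the worked arithmetic above); the
    alternative reading ``"level"`` divides the total credit by the
    sequence length instead — the two coincide when both equal three.
    """
    if config is None:
        config = transcript.config
    if not transcript.levels:
        raise ValueError("transcript contains no administered levels")
    if divisor not in ("trials", "level"):
        raise ValueError("divisor must be 'trials' or 'level'")

    per_level: list[LevelResult] = []
    for lv in transcript.levels:
        trial_results = tuple(score_trial(t, r) for t, r in lv.trials)
        n_ok = sum(tr.fully_correct for tr in trial_results)
        per_level.append(
            LevelResult(
                level=lv.level,
                trials=trial_results,
                passed=n_ok >= config.pass_min_correct,
            )
        )

    terminal = per_level[-1]
    L = terminal.level
    total = sum(tr.item_credits for tr in terminal.trials)
    if divisor == "trials":
        av = total / len(terminal.trials)
    else:
        av = total / L
    return SessionResult(
        highest_level=L,
        av_level_score=av,
        final_score=final_result(L, av),
        per_level=tuple(per_level),
    )


def classify_performance(final_score: float, threshold: float = 7.0) -> str:
    """Binary good/poor performance split at a configurable score threshold.

    The study's figures bin scores at 7 points; "good" means
    ``final_score >= threshold``.
    """
    return "good" if final_score >= threshold else "poor"
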