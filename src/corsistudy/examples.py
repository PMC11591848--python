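"""Scripted respondents and reference transcripts.

These are deterministic session drivers used throughout the test-suite,
the documentation and the acceptance checks: a perfect echo respondent, a
hard-threshold (deterministic span) respondent, and a builder for the
canonical worked-example session that terminates at level 3 with item
credits (2, 2, 1).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .task_engine import (
    BoardLayout,
    ResponseSequence,
    SessionConfig,
    SessionTranscript,
    TargetSequence,
    default_board,
    run_session,
)

__all__ = [
    "echo_respondent",
    "empty_respondent",
    "deterministic_span_respondent",
    "corrupt_response",
    "worked_example_transcript",
]


def echo_respondent(target: TargetSequence) -> ResponseSequence:
    """Perfect recall: always reproduces the target exactly."""
    return ResponseSequence(target.block_ids)


def empty_respondent(target: TargetSequence) -> ResponseSequence:
    """Total failure: never clicks any block."""
    return ResponseSequence(())


def deterministic_span_respondent(span: int):
    """A respondent that echoes targets of length <= span, else answers empty.

    Such a respondent passes every level up to ``span``, fails level
    ``span + 1`` with zero credit, and therefore scores exactly ``span``.
    """

    def respond(target: TargetSequence) -> ResponseSequence:
        if target.level <= span:
            return ResponseSequence(target.block_ids)
        return ResponseSequence(())

    return respond


def corrupt_response(
    target: TargetSequence, wrong_positions: set[int], board: BoardLayout
) -> ResponseSequence:
    """Copy the target, replacing the given positions with wrong blocks.

    Replacement blocks are chosen (deterministically, lowest id first) so
    that they are wrong at their own position and do not collide with any
    other response position; the result has exactly
    ``len(target) - len(wrong_positions)`` item credits.
    """
    resp = list(target.block_ids)
    used = set(resp)
    for i in sorted(wrong_positions):
        candidates = [
            b
            for b in board.block_ids
            if b != target.block_ids[i] and b not in used
        ]
        if not candidates:
            raise ValueError("board too small to corrupt this position")
        resp[i] = candidates[0]
        used.add(resp[i])
    return ResponseSequence(tuple(resp))


def _worked_example_responder(board: BoardLayout) -> Iterator:
    """Yields per-trial corruption plans for the worked example."""
    # level 2: echo all three trials (passes); level 3: credits 2, 2, 1.
    plans = [set(), set(), set(), {2}, {2}, {0, 1}]
    for plan in plans:
        yield plan


def worked_example_transcript(
    config: SessionConfig | None = None,
    board: BoardLayout | None = None,
    seed: int = 0,
) -> SessionTranscript:
    """Administer the canonical worked-example session.

    The respondent echoes every level-2 trial, then at level 3 recalls two
    blocks correctly on two attempts and one block on the third — never the
    full sequence — so the session terminates at level 3 with avLevelScore
    (2 + 2 + 1)/3 and FinalResult 3 - 1 + 1.67/3 ≈ 2.56.
    """
    config = config or SessionConfig(rng_seed=seed)
    board = board or default_board()
    plans = _worked_example_responder(board)

    def respond(target: TargetSequence) -> ResponseSequence:
        plan = next(plans)
        if not plan:
            return ResponseSequence(target.block_ids)
        return corrupt_response(target, plan, board)

    rng = np.random.default_rng(seed)
    return run_session(respond, config, board, rng)
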