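"""Administration engine for a computerized Corsi block-tapping test (CBT).

The CBT presents sequences of highlighted blocks on a board that the
participant reproduces in order.  Sequence length starts at two blocks and
grows by one every three trials; the session advances to the next length
only if at least one of the three trials is reproduced perfectly, and stops
at the first failed level (or after the longest administrable sequence).

The engine is callback-driven: a *respondent* is any callable mapping a
:class:`TargetSequence` to a :class:`ResponseSequence`.  Timing parameters
(highlight duration, inter-block interval, preparation delay) are recorded
as session metadata but the engine never sleeps — it simulates the
procedure, it does not present stimuli.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Block",
    "BoardLayout",
    "SessionConfig",
    "TargetSequence",
    "ResponseSequence",
    "LevelTrials",
    "SessionTranscript",
    "default_board",
    "generate_sequence",
    "run_session",
]


@dataclass(frozen=True)
class Block:
    """One tappable block: a 1-based id and its centre position in cm."""

    id: int
    x_cm: float
    y_cm: float


@dataclass(frozen=True)
class BoardLayout:
    """Geometry of the test display.

    The canonical board (see :func:`default_board`) shows ten blocks of
    equal size scattered over a 20 x 15 cm window; smaller boards are
    permitted for exhaustive distributional checks.  Coordinates use a
    top-left origin with x rightward and y downward.
    """

    blocks: tuple[Block, ...]
    window_w_cm: float = 20.0
    window_h_cm: float = 15.0
    block_size_cm: float = 2.0

    def __post_init__(self) -> None:
        n = len(self.blocks)
        if n < 2:
            raise ValueError("a board needs at least 2 blocks")
        ids = [b.id for b in self.blocks]
        if sorted(ids) != list(range(1, n + 1)):
            raise ValueError(f"block ids must be contiguous 1..{n}, got {ids}")
        half = self.block_size_cm / 2.0
        for b in self.blocks:
            if not (half <= b.x_cm <= self.window_w_cm - half) or not (
                half <= b.y_cm <= self.window_h_cm - half
            ):
                raise ValueError(f"block {b.id} extends outside the window")
        for a, b in itertools.combinations(self.blocks, 2):
            if (
                abs(a.x_cm - b.x_cm) < self.block_size_cm
                and abs(a.y_cm - b.y_cm) < self.block_size_cm
            ):
                raise ValueError(f"blocks {a.id} and {b.id} overlap")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_ids(self) -> tuple[int, ...]:
        return tuple(b.id for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "window_w_cm": self.window_w_cm,
            "window_h_cm": self.window_h_cm,
            "block_size_cm": self.block_size_cm,
            "blocks": [
                {"id": b.id, "x_cm": b.x_cm, "y_cm": b.y_cm} for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoardLayout":
        return cls(
            blocks=tuple(Block(b["id"], b["x_cm"], b["y_cm"]) for b in d["blocks"]),
            window_w_cm=d["window_w_cm"],
            window_h_cm=d["window_h_cm"],
            block_size_cm=d["block_size_cm"],
        )


_DEFAULT_POSITIONS = (
    (3.0, 2.5),
    (8.0, 1.8),
    (13.5, 2.2),
    (17.5, 4.5),
    (5.5, 5.8),
    (10.5, 6.4),
    (15.5, 8.7),
    (3.5, 9.6),
    (8.5, 11.2),
    (13.5, 12.4),
)


def default_board() -> BoardLayout:
    """The shipped 10-block layout in a 20 x 15 cm window.

    Exact block positions are an arbitrary (irregular, non-overlapping)
    arrangement; the procedure depends only on block identity, not
    geometry.
    """
    return BoardLayout(
        blocks=tuple(
            Block(i + 1, x, y) for i, (x, y) in enumerate(_DEFAULT_POSITIONS)
        )
    )


@dataclass(frozen=True)
class SessionConfig:
    """Administration parameters.

    Defaults follow the standard procedure: sequences start at two blocks,
    three trials per level, advancement on at least one perfect trial,
    1 s highlight with 0.5 s inter-block interval and a 5 s preparation
    delay before each trial.
    """

    start_length: int = 2
    trials_per_level: int = 3
    pass_min_correct: int = 1
    max_level: int = 10
    highlight_s: float = 1.0
    inter_block_s: float = 0.5
    prep_delay_s: float = 5.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.start_length < 1:
            raise ValueError("start_length must be >= 1")
        if not (1 <= self.pass_min_correct <= self.trials_per_level):
            raise ValueError("need 1 <= pass_min_correct <= trials_per_level")
        if self.max_level < self.start_length:
            raise ValueError("max_level must be >= start_length")

    def to_dict(self) -> dict:
        return {
            "start_length": self.start_length,
            "trials_per_level": self.trials_per_level,
            "pass_min_correct": self.pass_min_correct,
            "max_level": self.max_level,
            "highlight_s": self.highlight_s,
            "inter_block_s": self.inter_block_s,
            "prep_delay_s": self.prep_delay_s,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        return cls(**d)


@dataclass(frozen=True)
class TargetSequence:
    """An ordered sequence of distinct block ids of length ``level``."""

    level: int
    block_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.block_ids) != self.level:
            raise ValueError("sequence length must equal level")
        if len(set(self.block_ids)) != len(self.block_ids):
            raise ValueError("target sequences never repeat a block")

    def __len__(self) -> int:
        return self.level


@dataclass(frozen=True)
class ResponseSequence:
    """The blocks clicked by the respondent, in order (may be empty)."""

    block_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.block_ids)


@dataclass(frozen=True)
class LevelTrials:
    level: int
    trials: tuple[tuple[TargetSequence, ResponseSequence], ...]


@dataclass(frozen=True)
class SessionTranscript:
    """Complete record of one administered session."""

    config: SessionConfig
    levels: tuple[LevelTrials, ...]
    termination: str  # "failed_level" | "reached_max"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "termination": self.termination,
            "levels": [
                {
                    "level": lv.level,
                    "trials": [
                        {"target": list(t.block_ids), "response": list(r.block_ids)}
                        for t, r in lv.trials
                    ],
                }
                for lv in self.levels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionTranscript":
        return cls(
            config=SessionConfig.from_dict(d["config"]),
            seed=d.get("seed"),
            termination=d["termination"],
            levels=tuple(
                LevelTrials(
                    level=lv["level"],
                    trials=tuple(
                        (
                            TargetSequence(len(t["target"]), tuple(t["target"])),
                            ResponseSequence(tuple(t["response"])),
                        )
                        for t in lv["trials"]
                    ),
                )
                for lv in d["levels"]
            ),
        )


def generate_sequence(
    level: int, board: BoardLayout, rng: np.random.Generator
) -> TargetSequence:
    """Draw a uniformly random ordered selection of ``level`` distinct blocks.

    Sampling is without replacement, so at full board length the sequence
    is a uniform random permutation of the board.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if level > board.n_blocks:
        raise ValueError(
            f"cannot present a {level}-block sequence on a "
            f"{board.n_blocks}-block board"
        )
    ids = rng.choice(board.block_ids, size=level, replace=False)
    return TargetSequence(level=level, block_ids=tuple(int(i) for i in ids))


def _validate_response(resp: ResponseSequence, board: BoardLayout) -> None:
    valid = set(board.block_ids)
    bad = [i for i in resp.block_ids if i not in valid]
    if bad:
        raise ValueError(f"response contains unknown block ids: {bad}")


def run_session(
    respond: Callable[[TargetSequence], ResponseSequence],
    config: SessionConfig,
    board: BoardLayout | None = None,
    rng: np.random.Generator | None = None,
) -> SessionTranscript:
    """Administer one full CBT session.

    At each level all ``trials_per_level`` trials are presented; the session
    advances iff at least ``pass_min_correct`` of them are reproduced
    perfectly (exact order and length).  The first failed level terminates
    the session; a session that passes ``max_level`` terminates with
    reason ``"reached_max"``.
    """
    from . import scoring  # deferred: scoring depends on this module's types

    board = board if board is not None else default_board()
    if config.max_level > board.n_blocks:
        raise ValueError("max_level cannot exceed the number of blocks")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    levels: list[LevelTrials] = []
    termination = "reached_max"
    for level in range(config.start_length, config.max_level + 1):
        trials = []
        n_correct = 0
        for _ in range(config.trials_per_level):
            target = generate_sequence(level, board, rng)
            response = respond(target)
            if not isinstance(response, ResponseSequence):
                response = ResponseSequence(tuple(response))
            _validate_response(response, board)
            trials.append((target, response))
            if scoring.score_trial(target, response).fully_correct:
                n_correct += 1
        levels.append(LevelTrials(level=level, trials=tuple(trials)))
        if n_correct < config.pass_min_correct:
            termination = "failed_level"
            break
    return SessionTranscript(
        config=config,
        levels=tuple(levels),
        termination=termination,
        seed=config.rng_seed,
    )
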