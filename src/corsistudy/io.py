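"""File formats and run configuration.

Formats
-------
participants CSV
    ``id, group, sex, age, years_reading, self_assessment`` — lowercase
    string codings, "." decimal, UTF-8, one provenance comment line.
sessions JSON-lines
    First line a ``{"_meta": ...}`` object, then one session per line:
    ``{"participant_id": ..., "config": ..., "levels": [...], ...}``.
scores CSV
    ``participant_id, highest_level, av_level_score, final_score,
    performance_label``.
report JSON
    The dictionary produced by :func:`corsistudy.stats.run_full_analysis`.

Every writer embeds provenance (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import AgeDistribution, CohortSpec, StudyDataset
from .scoring import classify_performance, score_session
from .stats import AnalysisOptions
from .task_engine import SessionConfig, SessionTranscript

__all__ = [
    "RunConfig",
    "config_hash",
    "provenance_line",
    "load_run_config",
    "write_participants_csv",
    "read_participants_csv",
    "write_scores_csv",
    "read_scores_csv",
    "write_sessions_jsonl",
    "read_sessions_jsonl",
    "score_sessions_file",
    "write_report_json",
    "read_report_json",
    "participants_frame",
    "scores_frame",
    "join_scores_participants",
]

PARTICIPANT_COLUMNS = ["id", "group", "sex", "age", "years_reading", "self_assessment"]
SCORE_COLUMNS = [
    "participant_id",
    "highest_level",
    "av_level_score",
    "final_score",
    "performance_label",
]


def config_hash(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def provenance_line(seed, cfg_hash: str) -> str:
    return f"# corsistudy {__version__} seed={seed} config={cfg_hash}"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulate/analyze/power run."""

    session: SessionConfig = SessionConfig()
    cohort: CohortSpec = CohortSpec()
    analysis: AnalysisOptions = AnalysisOptions()
    out_dir: str = "results"
    seed: int | None = None
    verbosity: str = "info"

    def hash(self) -> str:
        return config_hash(
            {
                "session": self.session.to_dict(),
                "cohort": self.cohort.to_dict(),
                "analysis": vars(self.analysis),
                "seed": self.seed,
            }
        )


def load_run_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file; missing keys take defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    session = SessionConfig(**raw.get("session", {}))
    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("age_musicians", "age_non_musicians"):
        if key in cohort_raw:
            cohort_raw[key] = AgeDistribution(**cohort_raw[key])
    cohort = CohortSpec(**cohort_raw)
    analysis = AnalysisOptions(**raw.get("analysis", {}))
    return RunConfig(
        session=session,
        cohort=cohort,
        analysis=analysis,
        out_dir=raw.get("out_dir", "results"),
        seed=raw.get("seed"),
        verbosity=raw.get("verbosity", "info"),
    )


# ---------------------------------------------------------------------------
# frames


def participants_frame(dataset: StudyDataset) -> pd.DataFrame:
    return dataset.data[PARTICIPANT_COLUMNS].copy()


def scores_frame(dataset: StudyDataset, threshold: float = 7.0) -> pd.DataFrame:
    d = dataset.data
    return pd.DataFrame(
        {
            "participant_id": d["id"],
            "highest_level": d["highest_level"],
            "av_level_score": d["av_level_score"],
            "final_score": d["final_score"],
            "performance_label": [
                classify_performance(s, threshold) for s in d["final_score"]
            ],
        }
    )


# ---------------------------------------------------------------------------
# CSV


def _write_csv(df: pd.DataFrame, path: str | Path, seed, cfg_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed, cfg_hash) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_participants_csv(
    df: pd.DataFrame, path: str | Path, seed=None, cfg_hash: str = ""
) -> None:
    _write_csv(df[PARTICIPANT_COLUMNS], path, seed, cfg_hash)


def read_participants_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, PARTICIPANT_COLUMNS)


def write_scores_csv(
    df: pd.DataFrame, path: str | Path, seed=None, cfg_hash: str = ""
) -> None:
    _write_csv(df[SCORE_COLUMNS], path, seed, cfg_hash)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# sessions JSON-lines


def write_sessions_jsonl(
    sessions: list[tuple[str, SessionTranscript]],
    path: str | Path,
    seed=None,
    cfg_hash: str = "",
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        meta = {
            "_meta": {
                "package_version": __version__,
                "seed": seed,
                "config": cfg_hash,
                "n_sessions": len(sessions),
            }
        }
        fh.write(json.dumps(meta) + "\n")
        for pid, transcript in sessions:
            rec = {"participant_id": pid, **transcript.to_dict()}
            fh.write(json.dumps(rec) + "\n")


def read_sessions_jsonl(
    path: str | Path,
) -> tuple[dict, list[tuple[str, SessionTranscript]]]:
    """Parse a sessions file; malformed lines raise with their line number."""
    meta: dict = {}
    sessions: list[tuple[str, SessionTranscript]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as err:
                raise ValueError(f"{path}:{lineno}: invalid JSON ({err})") from err
            if "_meta" in rec:
                meta = rec["_meta"]
                continue
            try:
                pid = rec["participant_id"]
                transcript = SessionTranscript.from_dict(rec)
            except (KeyError, TypeError, ValueError) as err:
                raise ValueError(
                    f"{path}:{lineno}: malformed session record ({err})"
                ) from err
            sessions.append((pid, transcript))
    return meta, sessions


def score_sessions_file(
    path: str | Path, threshold: float = 7.0
) -> pd.DataFrame:
    """Score every session in a JSON-lines file into a scores table."""
    _, sessions = read_sessions_jsonl(path)
    rows = []
    for pid, transcript in sessions:
        result = score_session(transcript)
        rows.append(
            {
                "participant_id": pid,
                "highest_level": result.highest_level,
                "av_level_score": result.av_level_score,
                "final_score": result.final_score,
                "performance_label": classify_performance(
                    result.final_score, threshold
                ),
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# report JSON


def write_report_json(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = dict(report)
    report.setdefault("provenance", {})
    report["provenance"] = {
        "package_version": __version__,
        **report["provenance"],
    }
    path.write_text(json.dumps(report, indent=2, default=float) + "\n")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def join_scores_participants(
    scores: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join scores to participants on id, erroring on unmatched ids."""
    merged = participants.merge(
        scores, left_on="id", right_on="participant_id", how="outer", indicator=True
    )
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        ids = sorted(
            set(unmatched["id"].dropna()) | set(unmatched["participant_id"].dropna())
        )
        raise ValueError(f"unmatched participant ids: {ids}")
    merged = merged.drop(columns=["_merge", "participant_id"])
    return merged
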