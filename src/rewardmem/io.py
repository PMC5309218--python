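"""CSV I/O contracts tying the pipeline stages together.

All interchange is headered UTF-8 CSV with period decimal separators; delays
are the literal strings "20min"/"24h".  Writes are atomic (temp file then
rename) and refuse to overwrite existing files unless asked.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd

from .design import SessionDesign

DESIGN_COLUMNS = [
    "session_id", "delay", "trial_index", "character_id", "level",
    "pair_id", "feedback",
]
TRIALS_COLUMNS = DESIGN_COLUMNS + [
    "participant_id", "V_before", "delta", "p_encoding", "test_correct",
    "confidence",
]
FITS_COLUMNS = [
    "participant_id", "session_id", "delay", "model",
    "c0", "c_delta", "c_absdelta", "c_v", "alpha",
    "lle", "k", "aic", "grid_step_scale", "grid_step_alpha",
]
TRAITS_COLUMNS = ["participant_id", "SR", "SP"]


class OutputExists(FileExistsError):
    pass


def atomic_write_csv(frame: pd.DataFrame, path: str | Path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise OutputExists(f"{path} exists; pass overwrite=True (or --overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json(obj, path: str | Path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise OutputExists(f"{path} exists; pass overwrite=True (or --overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2, default=str)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def write_design_csv(design: SessionDesign, path, overwrite: bool = False) -> None:
    atomic_write_csv(design.to_frame()[DESIGN_COLUMNS], path, overwrite)


def read_design_csv(path) -> SessionDesign:
    frame = pd.read_csv(path)
    _require_columns(frame, DESIGN_COLUMNS, f"design CSV {path}")
    return SessionDesign.from_frame(frame)


def write_trials_csv(trials: pd.DataFrame, path, overwrite: bool = False) -> None:
    cols = [c for c in TRIALS_COLUMNS if c in trials.columns]
    atomic_write_csv(trials[cols], path, overwrite)


def read_trials_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(
        frame,
        DESIGN_COLUMNS + ["participant_id", "test_correct"],
        f"trials CSV {path}",
    )
    bad = frame.index[~frame["feedback"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"trials CSV {path}: non-binary feedback at line(s) "
            f"{[int(i) + 2 for i in bad[:10]]}"
        )
    frame["correct"] = frame["test_correct"]
    return frame


def designs_from_trials(trials: pd.DataFrame) -> Dict[str, SessionDesign]:
    """Reconstruct each participant's SessionDesign from a trials table."""
    return {
        str(pid): SessionDesign.from_frame(grp[DESIGN_COLUMNS])
        for pid, grp in trials.groupby("participant_id")
    }


def write_fits_csv(fits: pd.DataFrame, path, overwrite: bool = False) -> None:
    cols = [c for c in FITS_COLUMNS if c in fits.columns]
    extra = [c for c in fits.columns if c not in cols and c in ("grid_lle", "n_trials")]
    atomic_write_csv(fits[cols + extra], path, overwrite)


def read_fits_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, ["participant_id", "model", "lle", "k", "aic"],
                     f"fits CSV {path}")
    return frame


def write_traits_csv(records, path, overwrite: bool = False) -> None:
    rows: List[dict] = []
    for r in records:
        if r.traits is not None:
            rows.append(
                {"participant_id": r.participant_id,
                 "SR": r.traits.sr, "SP": r.traits.sp}
            )
    atomic_write_csv(pd.DataFrame(rows, columns=TRAITS_COLUMNS), path, overwrite)


def read_traits_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, TRAITS_COLUMNS, f"traits CSV {path}")
    return frame
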