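"""Associative-memory task schedules with predetermined probabilistic feedback.

A session presents six cartoon characters, two per reward-anticipation level
(high / medium / low).  Each character appears in a contiguous block of ten
trials, one novel object pair per trial; the participant guesses the
character's preferred object and receives positive or negative feedback.
Feedback is predetermined and independent of the choice: high-anticipation
characters receive positive feedback on 8/10 trials, medium on 5/10, low on
2/10.  Only the block order and the positions of the positive feedbacks
within each block are randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

LEVELS: Tuple[str, ...] = ("high", "medium", "low")
DELAYS: Tuple[str, ...] = ("20min", "24h")

#: predetermined positive-feedback counts out of 10 trials
DEFAULT_POSITIVES: Mapping[str, int] = {"high": 8, "medium": 5, "low": 2}


@dataclass(frozen=True)
class DesignConfig:
    """Counts defining one encoding session (defaults give the 60-trial task)."""

    characters_per_level: Mapping[str, int] = field(
        default_factory=lambda: {lvl: 2 for lvl in LEVELS}
    )
    positives_per_level: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVES)
    )
    trials_per_character: int = 10
    session_id: str = "S1"
    delay: str = "20min"
    character_prefix: str = "char"
    pair_prefix: str = "pair"

    def validate(self) -> None:
        for lvl in LEVELS:
            n = self.characters_per_level.get(lvl, 0)
            if n <= 0:
                raise ValueError(f"character count for level {lvl!r} must be positive")
            npos = self.positives_per_level.get(lvl)
            if npos is None or not (0 <= npos <= self.trials_per_character):
                raise ValueError(
                    f"positive-feedback count for level {lvl!r} must lie in "
                    f"[0, {self.trials_per_character}]"
                )
        if self.delay not in DELAYS:
            raise ValueError(f"delay must be one of {DELAYS}")


@dataclass(frozen=True)
class CharacterSpec:
    character_id: str
    level: str
    n_positive: int


@dataclass(frozen=True)
class TrialSlot:
    trial_index: int  # 1-based within the session
    character_id: str
    pair_id: str
    feedback: int  # 1 = positive, 0 = negative


@dataclass(frozen=True)
class SessionDesign:
    """A fixed encoding schedule: characters and their predetermined feedback."""

    session_id: str
    delay: str
    characters: Tuple[CharacterSpec, ...]
    trials: Tuple[TrialSlot, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def character(self, character_id: str) -> CharacterSpec:
        for c in self.characters:
            if c.character_id == character_id:
                return c
        raise KeyError(character_id)

    def feedback_for(self, character_id: str) -> np.ndarray:
        """Feedback sequence (session order) for one character's block."""
        return np.array(
            [t.feedback for t in self.trials if t.character_id == character_id],
            dtype=int,
        )

    def levels(self) -> Dict[str, str]:
        return {c.character_id: c.level for c in self.characters}

    def validate(self) -> None:
        counts: Dict[str, int] = {}
        pos: Dict[str, int] = {}
        pair_ids = set()
        last_char = None
        seen_chars = set()
        for i, t in enumerate(self.trials, start=1):
            if t.trial_index != i:
                raise ValueError("trial_index must be contiguous and 1-based")
            if t.pair_id in pair_ids:
                raise ValueError(f"pair_id {t.pair_id!r} repeated")
            pair_ids.add(t.pair_id)
            if t.character_id != last_char:
                if t.character_id in seen_chars:
                    raise ValueError("character blocks must be contiguous")
                seen_chars.add(t.character_id)
                last_char = t.character_id
            counts[t.character_id] = counts.get(t.character_id, 0) + 1
            pos[t.character_id] = pos.get(t.character_id, 0) + t.feedback
        for c in self.characters:
            if pos.get(c.character_id, 0) != c.n_positive:
                raise ValueError(
                    f"character {c.character_id!r} has {pos.get(c.character_id, 0)} "
                    f"positive feedbacks, expected {c.n_positive}"
                )
        if set(counts) != {c.character_id for c in self.characters}:
            raise ValueError("trials and characters disagree")

    def to_frame(self) -> pd.DataFrame:
        levels = self.levels()
        return pd.DataFrame(
            {
                "session_id": self.session_id,
                "delay": self.delay,
                "trial_index": [t.trial_index for t in self.trials],
                "character_id": [t.character_id for t in self.trials],
                "level": [levels[t.character_id] for t in self.trials],
                "pair_id": [t.pair_id for t in self.trials],
                "feedback": [t.feedback for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SessionDesign":
        frame = frame.sort_values("trial_index")
        chars = []
        for cid, grp in frame.groupby("character_id", sort=False):
            chars.append(
                CharacterSpec(
                    character_id=str(cid),
                    level=str(grp["level"].iloc[0]),
                    n_positive=int(grp["feedback"].sum()),
                )
            )
        trials = tuple(
            TrialSlot(
                trial_index=int(r.trial_index),
                character_id=str(r.character_id),
                pair_id=str(r.pair_id),
                feedback=int(r.feedback),
            )
            for r in frame.itertuples()
        )
        design = cls(
            session_id=str(frame["session_id"].iloc[0]),
            delay=str(frame["delay"].iloc[0]),
            characters=tuple(sorted(chars, key=lambda c: c.character_id)),
            trials=trials,
        )
        design.validate()
        return design


def generate_session_design(
    seed: int, config: DesignConfig | None = None
) -> SessionDesign:
    """Generate one randomized session satisfying the design invariants.

    Character block order and the positions of positive feedback within each
    block are uniform random permutations driven only by ``seed``; the same
    seed and config always yield the identical design.
    """
    config = config or DesignConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    characters = []
    idx = 1
    for lvl in LEVELS:
        for _ in range(config.characters_per_level[lvl]):
            characters.append(
                CharacterSpec(
                    character_id=f"{config.character_prefix}{idx:02d}",
                    level=lvl,
                    n_positive=config.positives_per_level[lvl],
                )
            )
            idx += 1
    order = rng.permutation(len(characters))

    trials = []
    trial_index = 1
    for ci in order:
        char = characters[ci]
        n = config.trials_per_character
        feedback = np.zeros(n, dtype=int)
        feedback[rng.permutation(n)[: char.n_positive]] = 1
        for fb in feedback:
            trials.append(
                TrialSlot(
                    trial_index=trial_index,
                    character_id=char.character_id,
                    pair_id=f"{config.pair_prefix}{trial_index:03d}",
                    feedback=int(fb),
                )
            )
            trial_index += 1

    design = SessionDesign(
        session_id=config.session_id,
        delay=config.delay,
        characters=tuple(characters),
        trials=tuple(trials),
    )
    design.validate()
    return design
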