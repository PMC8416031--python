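"""Canonical sleep-stage codes.

The five AASM stages in fixed order Wake, N1, N2, N3, REM, mapped to integer
indices 0-4. This ordering is used everywhere: hypnogram vectors, CRF state
indices, confusion-matrix rows/columns and class-weight vectors.
"""

from __future__ import annotations

import numpy as np

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
N_STAGES: int = 5

_STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}

# R&K tokens and common aliases seen in scoring exports (Sleep-EDF uses
# "Sleep stage 1" ... "Sleep stage R"); S3/S4 merge into AASM N3.
_ALIASES = {
    "WAKE": "W",
    "S1": "N1",
    "S2": "N2",
    "S3": "N3",
    "S4": "N3",
    "R": "REM",
    "REM": "REM",
    "SLEEP STAGE W": "W",
    "SLEEP STAGE 1": "N1",
    "SLEEP STAGE 2": "N2",
    "SLEEP STAGE 3": "N3",
    "SLEEP STAGE 4": "N3",
    "SLEEP STAGE R": "REM",
}


def stage_to_index(label: str, *, rk_merge: bool = True) -> int:
    """Map a stage token to its canonical index 0-4.

    Parameters
    ----------
    label : str
        Stage token: W/N1/N2/N3/REM, or an R&K / Sleep-EDF alias.
    rk_merge : bool
        Accept R&K tokens S1-S4 (S3 and S4 both map to N3). When False only
        the five canonical labels are accepted.
    """
    token = label.strip().upper()
    if token in _STAGE_TO_INDEX:
        return _STAGE_TO_INDEX[token]
    if rk_merge and token in _ALIASES:
        return _STAGE_TO_INDEX[_ALIASES[token]]
    raise ValueError(
        f"unknown sleep-stage token {label!r}; expected one of {STAGES}"
        + (" or an R&K alias (S1-S4, R)" if rk_merge else "")
    )


def index_to_stage(index: int) -> str:
    if not 0 <= int(index) < N_STAGES:
        raise ValueError(f"stage index {index} out of range 0-{N_STAGES - 1}")
    return STAGES[int(index)]


def stages_to_indices(labels, *, rk_merge: bool = True) -> np.ndarray:
    """Vectorize :func:`stage_to_index` over an iterable of tokens."""
    return np.array([stage_to_index(s, rk_merge=rk_merge) for s in labels], dtype=np.int64)


def indices_to_stages(indices) -> list[str]:
    return [index_to_stage(i) for i in np.asarray(indices).ravel()]
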