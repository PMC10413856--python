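"""Outcome labeling of downhill trajectories and transition-state bisection.

A downhill trajectory is an unbiased path started near the putative
transition state.  Its outcome is summarized by a scalar score — by default
the equal-weight sum of the unbinding CV's pair distances — averaged over a
terminal window of frames: IN (re-binding) if the terminal mean is at or
below ``s_in``, OUT (unbinding) if at or above ``s_out``, else UNDECIDED.
Candidate starting structures along the path are scored by their IN
fraction over repeated shots, and the transition-state candidate is the one
closest to a 1:1 IN:OUT split (committor ~ 0.5).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core import Trajectory
from .cv import UnbindingCV, interatomic_distances
from .errors import ConfigurationError, SelectionError


class OutcomeLabel(str, enum.Enum):
    IN = "IN"
    OUT = "OUT"
    UNDECIDED = "UNDECIDED"

    def __str__(self):
        return self.value


@dataclass(frozen=True)
class LabelingRule:
    """Linear-combination score with IN/OUT thresholds.

    ``weights=None`` means equal weights over the CV's pair distances, i.e.
    the score is the plain distance sum.  The terminal mean averages the
    last ``terminal_fraction`` of frames (robust to recrossings);
    ``mode="first_crossing"`` instead labels by whichever threshold the
    score crosses first.
    """

    s_in: float
    s_out: float
    weights: tuple[float, ...] | None = None
    terminal_fraction: float = 0.1
    mode: str = "terminal_mean"

    def __post_init__(self):
        if not self.s_in < self.s_out:
            raise ConfigurationError(
                f"need s_in < s_out (got {self.s_in} >= {self.s_out})"
            )
        if not 0 < self.terminal_fraction <= 1:
            raise ConfigurationError("terminal_fraction must be in (0, 1]")
        if self.mode not in ("terminal_mean", "first_crossing"):
            raise ConfigurationError(f"unknown labeling mode {self.mode!r}")


def score_series(
    traj: Trajectory, rule: LabelingRule, cv: UnbindingCV
) -> np.ndarray:
    """Per-frame weighted distance score."""
    d = interatomic_distances(traj, cv.pairs)
    if rule.weights is None:
        return d.sum(axis=1)
    w = np.asarray(rule.weights, float)
    if len(w) != cv.n_pairs:
        raise ConfigurationError(
            f"{len(w)} weights for a {cv.n_pairs}-pair CV"
        )
    return d @ w


def label_score_series(scores: np.ndarray, rule: LabelingRule) -> OutcomeLabel:
    """Label a precomputed score series (used for scalar toy paths too)."""
    scores = np.asarray(scores, float)
    if rule.mode == "first_crossing":
        hit_in = np.flatnonzero(scores <= rule.s_in)
        hit_out = np.flatnonzero(scores >= rule.s_out)
        if hit_in.size and (not hit_out.size or hit_in[0] < hit_out[0]):
            return OutcomeLabel.IN
        if hit_out.size:
            return OutcomeLabel.OUT
        return OutcomeLabel.UNDECIDED
    n_tail = max(1, int(round(rule.terminal_fraction * len(scores))))
    tail_mean = scores[-n_tail:].mean()
    if tail_mean <= rule.s_in:
        return OutcomeLabel.IN
    if tail_mean >= rule.s_out:
        return OutcomeLabel.OUT
    return OutcomeLabel.UNDECIDED


def label_downhill(
    traj: Trajectory, rule: LabelingRule, cv: UnbindingCV
) -> OutcomeLabel:
    """IN/OUT/UNDECIDED outcome of one downhill trajectory."""
    if traj.n_frames < 1:
        raise ConfigurationError("empty trajectory")
    return label_score_series(score_series(traj, rule, cv), rule)


@dataclass
class CandidateWindow:
    """One candidate starting structure with its downhill shot outcomes."""

    window_id: int
    labels: list[OutcomeLabel]
    shots: list = field(default_factory=list)  # optional trajectory handles

    @property
    def n_in(self) -> int:
        return sum(1 for l in self.labels if l == OutcomeLabel.IN)

    @property
    def n_out(self) -> int:
        return sum(1 for l in self.labels if l == OutcomeLabel.OUT)

    @property
    def n_decided(self) -> int:
        return self.n_in + self.n_out

    @property
    def in_fraction(self) -> float:
        """#IN / (#IN + #OUT); UNDECIDED shots are excluded."""
        if self.n_decided == 0:
            raise SelectionError(
                f"window {self.window_id} has no decided shots"
            )
        return self.n_in / self.n_decided


def committor_profile(windows: list[CandidateWindow]) -> pd.DataFrame:
    """Path-ordered IN fractions with Wilson 95% intervals per window.

    Windows with zero decided shots are excluded with a warning.
    """
    rows = []
    for w in sorted(windows, key=lambda w: w.window_id):
        if w.n_decided == 0:
            warnings.warn(
                f"window {w.window_id} has no decided shots; excluded",
                stacklevel=2,
            )
            continue
        lo, hi = proportion_confint(
            w.n_in, w.n_decided, alpha=0.05, method="wilson"
        )
        rows.append(
            {
                "window_id": w.window_id,
                "n_in": w.n_in,
                "n_out": w.n_out,
                "in_fraction": w.in_fraction,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["window_id", "n_in", "n_out", "in_fraction", "ci_low", "ci_high"],
    )


def select_ts_candidate(windows: list[CandidateWindow]) -> int:
    """The window id whose IN fraction is closest to 0.5 (the 1:1 split).

    Ties are broken toward the smaller window id (earlier along the path).
    """
    decided = [w for w in windows if w.n_decided > 0]
    if not decided:
        raise SelectionError("no window has any decided downhill shots")
    decided.sort(key=lambda w: (abs(w.in_fraction - 0.5), w.window_id))
    return decided[0].window_id
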