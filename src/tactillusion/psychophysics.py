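"""Same-different psychophysics under the differencing decision rule.

The discrimination experiments use a same-different procedure: on each
trial the observer explores an ordered pair of stimuli and reports whether
their compliances were the same or different.  Sensitivity is summarized by
d' under the differencing model: the observer forms one noisy internal
observation per interval (unit variance, means separated by d' when the
stimuli differ), takes the difference D of the two observations
(variance 2), and responds "different" when |D| exceeds a criterion k.
Hence

    F = 2 * Phi(-k / sqrt(2))
    H = Phi((d' - k) / sqrt(2)) + Phi((-d' - k) / sqrt(2))

for the false-alarm rate F (different-responses on same-pairs) and hit
rate H (different-responses on different-pairs).  ``dprime_differencing``
inverts these two equations numerically; ``simulate_observer`` samples the
forward model and is used both for validation and to generate synthetic
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "StimulusPair",
    "TrialRecord",
    "SensitivityResult",
    "enumerate_pairs",
    "percent_correct",
    "rates_from_trials",
    "dprime_differencing",
    "dprime_from_trials",
    "simulate_observer",
    "condition_report",
    "CORRECT_THRESHOLD_PC",
]

#: percent-correct detection threshold conventionally used for the
#: same-different procedure
CORRECT_THRESHOLD_PC = 75.0


@dataclass(frozen=True)
class StimulusPair:
    """An ordered pair of stimulus ids (equal ids form a same-pair)."""

    first: str
    second: str

    @property
    def is_same(self) -> bool:
        return self.first == self.second

    def label(self) -> str:
        return f"{self.first}|{self.second}"


@dataclass(frozen=True)
class TrialRecord:
    pair: StimulusPair
    condition: str
    response: str  # "same" | "different"
    correct: bool

    @staticmethod
    def from_response(pair: StimulusPair, condition: str, response: str) -> "TrialRecord":
        if response not in ("same", "different"):
            raise ValueError(f"response must be 'same' or 'different', got {response!r}")
        correct = (response == "different") != pair.is_same
        return TrialRecord(pair=pair, condition=condition, response=response, correct=correct)


@dataclass(frozen=True)
class SensitivityResult:
    hit_rate: float
    false_alarm_rate: float
    dprime: float
    criterion: float
    n_different: int = 0
    n_same: int = 0


def enumerate_pairs(stimuli: Sequence[str]) -> list[StimulusPair]:
    """All ordered pairs of ``stimuli`` (sampling with replacement).

    Three stimuli yield the nine ordered pairs used in the discrimination
    design, of which three are same-pairs.  Deterministic row-major order.
    """
    ids = list(stimuli)
    if not ids:
        raise ValueError("enumerate_pairs requires at least one stimulus")
    return [StimulusPair(a, b) for a in ids for b in ids]


def percent_correct(trials: Iterable[TrialRecord], condition: str | None = None) -> tuple[float, bool]:
    """Percent correct (0-100) and whether it reaches the 75% threshold.

    Restricts to ``condition`` when given.
    """
    selected = [t for t in trials if condition is None or t.condition == condition]
    if not selected:
        raise ValueError("no trials in the requested condition")
    pc = 100.0 * float(np.mean([t.correct for t in selected]))
    return pc, pc >= CORRECT_THRESHOLD_PC


def _corrected_rate(k: int, n: int) -> float:
    """Proportion k/n with the 1/(2N) correction for extreme rates."""
    if n <= 0:
        raise ValueError("rate requires at least one trial")
    if k == 0:
        return 1.0 / (2.0 * n)
    if k == n:
        return 1.0 - 1.0 / (2.0 * n)
    return k / n


def rates_from_trials(trials: Iterable[TrialRecord]) -> tuple[float, float, int, int]:
    """(H, F, n_different, n_same) with extreme-rate correction.

    H is the proportion of "different" responses on different-pairs, F the
    proportion on same-pairs; rates of exactly 0 or 1 are replaced by
    1/(2N) and 1 - 1/(2N).
    """
    trials = list(trials)
    diff_trials = [t for t in trials if not t.pair.is_same]
    same_trials = [t for t in trials if t.pair.is_same]
    if not diff_trials or not same_trials:
        raise ValueError("need both same-pairs and different-pairs to estimate rates")
    hits = sum(t.response == "different" for t in diff_trials)
    fas = sum(t.response == "different" for t in same_trials)
    H = _corrected_rate(hits, len(diff_trials))
    F = _corrected_rate(fas, len(same_trials))
    return H, F, len(diff_trials), len(same_trials)


def forward_differencing(dprime: float, criterion: float) -> tuple[float, float]:
    """(H, F) predicted by the differencing model at (d', k)."""
    s = np.sqrt(2.0)
    F = 2.0 * norm.cdf(-criterion / s)
    H = norm.cdf((dprime - criterion) / s) + norm.cdf((-dprime - criterion) / s)
    return float(H), float(F)


def dprime_differencing(H: float, F: float) -> SensitivityResult:
    """Invert the same-different differencing model for (d', k).

    The criterion follows from F alone, ``k = -sqrt(2) * Phi^-1(F / 2)``;
    d' is then the root of ``H(d', k) - H`` which is strictly increasing in
    d'.  Returns d' = 0 whenever H <= F (performance at or below chance).

    Raises
    ------
    ValueError
        If H or F lies outside the open interval (0, 1).
    """
    if not (0.0 < H < 1.0) or not (0.0 < F < 1.0):
        raise ValueError("H and F must lie strictly inside (0, 1); apply the "
                         "extreme-rate correction first")
    s = np.sqrt(2.0)
    k = float(-s * norm.ppf(F / 2.0))
    if H <= F:
        return SensitivityResult(H, F, 0.0, k)

    def gap(d: float) -> float:
        return forward_differencing(d, k)[0] - H

    hi = 1.0
    while gap(hi) < 0 and hi < 60.0:
        hi *= 2.0
    d = brentq(gap, 0.0, hi, xtol=1e-10)
    return SensitivityResult(H, F, float(d), k)


def dprime_from_trials(trials: Iterable[TrialRecord]) -> SensitivityResult:
    """Pooled-count d' for a set of trials (corrected rates, then inversion)."""
    H, F, nd, ns = rates_from_trials(trials)
    res = dprime_differencing(H, F)
    return SensitivityResult(res.hit_rate, res.false_alarm_rate, res.dprime,
                             res.criterion, n_different=nd, n_same=ns)


def simulate_observer(
    dprime: float,
    criterion: float,
    pairs: Sequence[StimulusPair],
    n_trials: int = 1,
    seed: int | None = None,
    condition: str = "simulated",
) -> list[TrialRecord]:
    """Sample same-different responses from the differencing observer.

    Each presentation of a pair draws two unit-variance internal
    observations whose means are separated by ``dprime`` when the stimuli
    differ; the observer responds "different" when the absolute difference
    of the observations exceeds ``criterion`` (the same k inverted by
    :func:`dprime_differencing`).  Every pair in ``pairs`` is presented
    ``n_trials`` times.

    Raises
    ------
    ValueError
        If ``dprime`` is negative or ``n_trials`` < 1.
    """
    if dprime < 0:
        raise ValueError("dprime must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for _ in range(n_trials):
        for pair in pairs:
            x1 = rng.normal(0.0, 1.0)
            mean2 = 0.0 if pair.is_same else dprime
            x2 = rng.normal(mean2, 1.0)
            response = "different" if abs(x2 - x1) > criterion else "same"
            records.append(TrialRecord.from_response(pair, condition, response))
    return records


def condition_report(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Per-condition and per-pair summary table.

    One row per (condition, pair) with percent correct, plus one pooled row
    per condition (pair = "all") carrying H, F, pooled-count d' and the
    unweighted mean of per-pair d' values (each stimulus pair scored
    against the condition's same-pairs).  Conditions lacking same-pairs or
    different-pairs have NaN sensitivity entries.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("condition_report requires at least one trial")
    rows = []
    conditions = sorted({t.condition for t in trials})
    for cond in conditions:
        cond_trials = [t for t in trials if t.condition == cond]
        pair_labels = sorted({t.pair.label() for t in cond_trials})
        per_pair_d = []
        same_trials = [t for t in cond_trials if t.pair.is_same]
        for label in pair_labels:
            sub = [t for t in cond_trials if t.pair.label() == label]
            pc = 100.0 * float(np.mean([t.correct for t in sub]))
            rows.append({"condition": cond, "pair": label, "n_trials": len(sub),
                         "percent_correct": pc, "hit_rate": np.nan,
                         "false_alarm_rate": np.nan, "dprime": np.nan,
                         "mean_pair_dprime": np.nan, "threshold_reached": pc >= CORRECT_THRESHOLD_PC})
            if not sub[0].pair.is_same and same_trials:
                H, F, *_ = rates_from_trials(sub + same_trials)
                per_pair_d.append(dprime_differencing(H, F).dprime)
        pc_all, flag = percent_correct(cond_trials)
        try:
            pooled = dprime_from_trials(cond_trials)
            H, F, d = pooled.hit_rate, pooled.false_alarm_rate, pooled.dprime
        except ValueError:
            H = F = d = np.nan
        rows.append({"condition": cond, "pair": "all", "n_trials": len(cond_trials),
                     "percent_correct": pc_all, "hit_rate": H, "false_alarm_rate": F,
                     "dprime": d,
                     "mean_pair_dprime": float(np.mean(per_pair_d)) if per_pair_d else np.nan,
                     "threshold_reached": flag})
    return pd.DataFrame(rows)
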