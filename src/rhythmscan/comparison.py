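"""Cross-condition / cross-genotype comparison of rhythm-call sets.

Produces the summary structures used to contrast circadiomes: shared /
lost / gained gene sets with failure-reason attribution for the lost
set, phase cross-tabulations and histograms, circular phase-shift
summaries, and mean-expression-change profiles binned by phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# symmetric log2 bin edges; outer bins open
LOG2_CHANGE_EDGES = (-np.inf, -4, -2, -1, -0.5, -0.25, 0.25, 0.5, 1, 2, 4, np.inf)


@dataclass(frozen=True)
class CircadiomeComparison:
    set_A_only: list[str]
    set_B_only: list[str]
    set_both: list[str]
    failure_breakdown: dict[str, float]
    phase_crosstab: pd.DataFrame
    phase_shift_median_h: float

    def summary(self) -> str:
        n_a = len(self.set_A_only) + len(self.set_both)
        n_b = len(self.set_B_only) + len(self.set_both)
        lines = [
            f"rhythmic in A: {n_a}",
            f"rhythmic in B: {n_b}",
            f"rhythmic in both: {len(self.set_both)}"
            + (f" ({100 * len(self.set_both) / n_a:.0f}% of A)" if n_a else ""),
            f"lost in B: {len(self.set_A_only)}",
            f"gained in B: {len(self.set_B_only)}",
            f"median phase shift (B - A): {self.phase_shift_median_h:+.1f} h",
        ]
        if self.failure_breakdown:
            frac = ", ".join(
                f"{k}: {100 * v:.0f}%" for k, v in sorted(self.failure_breakdown.items())
            )
            lines.append(f"failure reasons among lost genes: {frac}")
        return "\n".join(lines)


def circular_phase_shift(phase_a: float, phase_b: float, period: float = 24.0) -> float:
    """Minimal signed circular difference phase_b - phase_a.

    Result lies in (-period/2, period/2]; the antipodal boundary maps
    to +period/2.
    """
    d = (phase_b - phase_a) % period
    if d > period / 2.0:
        d -= period
    return float(d)


def circular_median_shift(shifts: np.ndarray, period: float = 24.0) -> float:
    """Circular median: the observed shift minimizing total circular distance.

    Ties break to the smallest value.  Returns NaN for an empty input.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size == 0:
        return float("nan")
    d = np.abs(shifts[:, None] - shifts[None, :]) % period
    d = np.minimum(d, period - d)
    totals = d.sum(axis=1)
    candidates = shifts[totals == totals.min()]
    return float(candidates.min())


def phase_histogram(calls: pd.DataFrame, period: float = 24.0,
                    phase_step: float = 1.0) -> np.ndarray:
    """Counts of rhythmic genes per phase bin; sums to n rhythmic."""
    n_bins = int(round(period / phase_step))
    phases = calls.loc[calls["rhythmic"], "phase"].to_numpy(dtype=float)
    idx = np.round(phases / phase_step).astype(int) % n_bins
    return np.bincount(idx, minlength=n_bins)


def phase_crosstab(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                   shared: list[str], period: float = 24.0,
                   phase_step: float = 1.0) -> pd.DataFrame:
    """Phase-in-A x phase-in-B count matrix over the shared rhythmic set."""
    n_bins = int(round(period / phase_step))
    labels = np.arange(n_bins) * phase_step
    mat = np.zeros((n_bins, n_bins), dtype=int)
    if shared:
        pa = calls_a.loc[shared, "phase"].to_numpy(dtype=float)
        pb = calls_b.loc[shared, "phase"].to_numpy(dtype=float)
        ia = np.round(pa / phase_step).astype(int) % n_bins
        ib = np.round(pb / phase_step).astype(int) % n_bins
        np.add.at(mat, (ia, ib), 1)
    return pd.DataFrame(mat, index=labels, columns=labels)


def compare_rhythm_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                        period: float = 24.0,
                        phase_step: float = 1.0) -> CircadiomeComparison:
    """Partition the rhythmic universe and attribute losses.

    ``failure_breakdown`` gives, for genes rhythmic in A but not in B,
    the fraction attributed to each failure reason of the B calls.
    """
    if not set(calls_a.index) & set(calls_b.index):
        raise ValueError("call sets share no probes")
    shared_universe = calls_a.index.intersection(calls_b.index)
    a = calls_a.loc[shared_universe]
    b = calls_b.loc[shared_universe]
    rhythmic_a = set(a.index[a["rhythmic"]])
    rhythmic_b = set(b.index[b["rhythmic"]])

    order = {p: i for i, p in enumerate(shared_universe)}
    def _sorted(s: set) -> list[str]:
        return sorted(s, key=order.__getitem__)

    set_both = _sorted(rhythmic_a & rhythmic_b)
    set_a_only = _sorted(rhythmic_a - rhythmic_b)
    set_b_only = _sorted(rhythmic_b - rhythmic_a)

    breakdown: dict[str, float] = {}
    if set_a_only:
        reasons = b.loc[set_a_only, "failure_reason"]
        counts = reasons.value_counts()
        breakdown = {str(k): float(v) / len(set_a_only) for k, v in counts.items()}

    ct = phase_crosstab(a, b, set_both, period=period, phase_step=phase_step)
    shifts = np.array([
        circular_phase_shift(a.loc[g, "phase"], b.loc[g, "phase"], period)
        for g in set_both
    ])
    median_shift = circular_median_shift(shifts, period)

    comp = CircadiomeComparison(
        set_A_only=set_a_only, set_B_only=set_b_only, set_both=set_both,
        failure_breakdown=breakdown, phase_crosstab=ct,
        phase_shift_median_h=median_shift,
    )
    logger.info("comparison:\n%s", comp.summary())
    return comp


@dataclass(frozen=True)
class ExpressionChangeProfile:
    log2_change: pd.Series                 # per gene, log2(mean_B / mean_A)
    histogram: pd.DataFrame                # phase-in-A x log2-change bin
    up_set: list[str]
    down_set: list[str]
    skipped: list[str]


def expression_change_profile(
    ds, group_a: tuple[str, str], group_b: tuple[str, str],
    genes: list[str], phase_source: pd.DataFrame,
    fold: float = 1.5, period: float = 24.0, phase_step: float = 1.0,
    edges: tuple = LOG2_CHANGE_EDGES,
) -> ExpressionChangeProfile:
    """log2 mean-expression change B vs A, binned by phase in A.

    ``phase_source`` supplies the reference phase (calls from group A).
    Genes with a non-positive mean in either group are skipped with a
    warning.  up/down sets use a mean-change fold threshold: down iff
    mean_B <= mean_A / fold, up iff mean_B >= fold * mean_A.
    """
    samples_a = ds.group_samples(*group_a)
    samples_b = ds.group_samples(*group_b)
    mean_a = ds.values.loc[genes, samples_a].mean(axis=1)
    mean_b = ds.values.loc[genes, samples_b].mean(axis=1)

    ok = (mean_a > 0) & (mean_b > 0)
    skipped = list(mean_a.index[~ok])
    if skipped:
        logger.warning("skipping %d genes with non-positive group mean", len(skipped))
    mean_a, mean_b = mean_a[ok], mean_b[ok]

    log2_change = np.log2(mean_b / mean_a)
    log2_change.name = "log2_change"

    up_set = list(mean_a.index[mean_b >= fold * mean_a])
    down_set = list(mean_a.index[mean_b <= mean_a / fold])

    n_bins = int(round(period / phase_step))
    phase_labels = np.arange(n_bins) * phase_step
    phases = phase_source.loc[log2_change.index, "phase"].to_numpy(dtype=float)
    phase_idx = np.round(phases / phase_step).astype(int) % n_bins
    change_idx = np.digitize(log2_change.to_numpy(), edges[1:-1])
    n_change_bins = len(edges) - 1
    mat = np.zeros((n_bins, n_change_bins), dtype=int)
    np.add.at(mat, (phase_idx, change_idx), 1)
    bin_labels = [f"({edges[i]}, {edges[i+1]}]" for i in range(n_change_bins)]
    histogram = pd.DataFrame(mat, index=phase_labels, columns=bin_labels)

    return ExpressionChangeProfile(
        log2_change=log2_change, histogram=histogram,
        up_set=up_set, down_set=down_set, skipped=skipped,
    )
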