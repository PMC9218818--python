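"""Phase-scanned sine-correlation rhythmicity classification.

Each gene's time course is correlated against a bank of cosine
templates with a fixed 24-h period, one template per candidate peak
phase on a 1-h grid.  The best-correlating phase gives the gene's
phase of expression; a t-test on the maximal Pearson r gives the
significance; and a gene is called rhythmic only if it additionally
clears one of two amplitude criteria — an extrapolated peak-to-trough
fold change of at least ``fold_threshold``, or an absolute min-to-max
change of at least ``abs_change_multiplier`` times the dataset grand
mean.

Template waveform convention: ``s_p(t) = mean + amplitude *
cos(2*pi*(t - p)/period)``, so a template peaks at circadian time equal
to its phase label and "phase" reads directly as time of peak
expression (hours after subjective dawn).  Pearson correlation is
invariant to the template's mean and amplitude, so those constants are
cosmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FAIL_NONE = "none"
FAIL_CORRELATION = "fails_correlation"
FAIL_AMPLITUDE = "fails_amplitude"


@dataclass(frozen=True)
class RhythmParams:
    """Classifier configuration.

    ``abs_change_multiplier`` has no default: the absolute-change
    threshold (multiplier x grand mean) is scale-dependent and must be
    chosen explicitly for the expression scale at hand.  Set it to 0 to
    disable the absolute-change route, or use ``abs_change_units`` to
    supply a threshold in raw expression units instead.
    """

    abs_change_multiplier: float
    period_h: float = 24.0
    phase_step_h: float = 1.0
    template_mean: float = 60.0
    template_amplitude: float = 60.0
    alpha: float = 0.01
    fold_threshold: float = 1.5
    floor_fraction: float = 0.05
    one_sided: bool = False
    abs_change_units: float | None = None

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.phase_step_h <= 0:
            raise ValueError("phase_step_h must be positive")
        n_phases = self.period_h / self.phase_step_h
        if abs(n_phases - round(n_phases)) > 1e-9:
            raise ValueError("phase_step_h must divide period_h evenly")
        if self.abs_change_multiplier < 0:
            raise ValueError("abs_change_multiplier must be non-negative")

    @property
    def n_phases(self) -> int:
        return int(round(self.period_h / self.phase_step_h))

    @property
    def phases(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.phase_step_h

    def abs_change_threshold(self, grand_mean: float) -> float:
        if self.abs_change_units is not None:
            return self.abs_change_units
        return self.abs_change_multiplier * grand_mean


@dataclass(frozen=True)
class SineTemplateBank:
    """Cosine templates evaluated at the sample times, one per phase."""

    times_h: np.ndarray
    phases: np.ndarray
    template_values: np.ndarray  # shape (n_phases, n_times)
    period_h: float

    def template(self, phase: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.phases - phase)))
        return self.template_values[idx]


@dataclass(frozen=True)
class RhythmCall:
    """Per-gene classification result."""

    probe_id: str
    phase: float
    r: float
    p_value: float
    predicted_fc: float
    abs_change: float
    rhythmic: bool
    failure_reason: str

    def as_dict(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "phase": self.phase,
            "r": self.r,
            "p_value": self.p_value,
            "predicted_fc": self.predicted_fc,
            "abs_change": self.abs_change,
            "rhythmic": self.rhythmic,
            "failure_reason": self.failure_reason,
        }


def circadian_time(t_h: float | np.ndarray, period_h: float = 24.0) -> float | np.ndarray:
    """Hours since transfer mapped to circadian time in [0, period)."""
    return np.mod(t_h, period_h)


def build_template_bank(times_h: Sequence[float], params: RhythmParams) -> SineTemplateBank:
    """One cosine template per candidate phase, evaluated at clock time.

    Requires at least 3 distinct circadian times among the samples so
    the correlation t-test has at least one degree of freedom.
    """
    times = np.asarray(times_h, dtype=float)
    distinct_ct = np.unique(np.round(circadian_time(times, params.period_h), 9))
    if distinct_ct.size < 3:
        raise ValueError(
            f"need >= 3 distinct circadian times, got {distinct_ct.size}"
        )
    phases = params.phases
    angles = 2 * np.pi * (times[None, :] - phases[:, None]) / params.period_h
    values = params.template_mean + params.template_amplitude * np.cos(angles)
    return SineTemplateBank(
        times_h=times, phases=phases, template_values=values, period_h=params.period_h
    )


def _pearson_to_templates(series: np.ndarray, bank: SineTemplateBank) -> np.ndarray:
    """Pearson r of one series against every template (vectorized)."""
    y = series - series.mean()
    t = bank.template_values - bank.template_values.mean(axis=1, keepdims=True)
    denom = np.sqrt((y @ y) * (t * t).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t @ y) / denom
    return np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)


def best_phase_correlation(
    series: Sequence[float], bank: SineTemplateBank
) -> tuple[float, float]:
    """Phase whose template maximizes Pearson r, and that r.

    Ties break to the smallest phase label.  A zero-variance series has
    undefined correlation and returns (phase 0, r = 0); callers classify
    it as arrhythmic via the correlation criterion.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] != bank.times_h.shape[0]:
        raise ValueError("series length does not match template bank times")
    if np.ptp(series) == 0:
        return float(bank.phases[0]), 0.0
    r = _pearson_to_templates(series, bank)
    best = int(np.argmax(r))  # argmax takes the first (smallest phase) on ties
    return float(bank.phases[best]), float(r[best])


def correlation_pvalue(r: float, n: int, one_sided: bool = False) -> float:
    """t-test p-value for H0: r = 0 with n - 2 degrees of freedom."""
    if n < 3:
        raise ValueError(f"need n >= 3 samples for the correlation t-test, got {n}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    if one_sided:
        return float(stats.t.sf(t, df))
    return float(2.0 * stats.t.sf(abs(t), df))


def critical_r(n: int, alpha: float = 0.01, one_sided: bool = False) -> float:
    """Smallest |r| achieving p < alpha at sample size n."""
    df = n - 2
    q = alpha if one_sided else alpha / 2.0
    t_crit = stats.t.isf(q, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def nearest_extremum_samples(
    times_h: Sequence[float], phase: float, period_h: float = 24.0
) -> tuple[int, int]:
    """Indices of the samples circularly closest to the peak and trough.

    The peak target is the phase itself; the trough target is phase +
    period/2.  Ties break to the earliest clock time of sampling.
    """
    times = np.asarray(times_h, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 samples")
    ct = circadian_time(times, period_h)

    def _closest(target: float) -> int:
        d = np.abs(ct - target % period_h)
        d = np.minimum(d, period_h - d)
        # stable argmin on (distance, clock time): sort-free two-key min
        best = np.flatnonzero(d == d.min())
        return int(best[np.argmin(times[best])])

    return _closest(phase), _closest(phase + period_h / 2.0)


def predicted_fold_change(
    series: Sequence[float],
    times_h: Sequence[float],
    phase: float,
    params: RhythmParams,
) -> float:
    """Extrapolated peak-to-trough fold change.

    The observed fold change between the samples nearest the calculated
    peak and trough is compared with the fold change a reference sine of
    the same phase and mean but an exactly ``fold_threshold`` peak-to-
    trough ratio would show between those same samples:

        predicted_fc = fold_threshold * FC_obs / FC_ref

    so the amplitude criterion reads ``predicted_fc >= fold_threshold``.
    A non-positive value at either extremum sample fails the criterion
    (returns 0).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times_h, dtype=float)
    i_peak, i_trough = nearest_extremum_samples(times, phase, params.period_h)
    v_peak, v_trough = series[i_peak], series[i_trough]
    if v_peak <= 0 or v_trough <= 0:
        return 0.0
    fc_obs = v_peak / v_trough
    # reference sine, ratio R = fold_threshold: amplitude/mean = (R-1)/(R+1);
    # FC_ref is independent of the mean level.
    ratio = params.fold_threshold
    am = (ratio - 1.0) / (ratio + 1.0)
    w = 2 * np.pi / params.period_h
    ref_peak = 1.0 + am * np.cos(w * (times[i_peak] - phase))
    ref_trough = 1.0 + am * np.cos(w * (times[i_trough] - phase))
    fc_ref = ref_peak / ref_trough
    return float(params.fold_threshold * fc_obs / fc_ref)


def absolute_change_criterion(
    series: Sequence[float], grand_mean: float, params: RhythmParams
) -> bool:
    """True iff max - min reaches the absolute-change threshold."""
    if grand_mean <= 0:
        raise ValueError("grand_mean must be positive")
    series = np.asarray(series, dtype=float)
    return bool(np.ptp(series) >= params.abs_change_threshold(grand_mean))


def classify_gene(
    series: Sequence[float],
    times_h: Sequence[float],
    grand_mean: float,
    params: RhythmParams,
    bank: SineTemplateBank | None = None,
    probe_id: str = "",
) -> RhythmCall:
    """Full dual-criteria classification of one gene's time course."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if bank is None:
        bank = build_template_bank(times, params)
    n = series.shape[0]
    abs_change = float(np.ptp(series))

    if np.ptp(series) == 0:
        return RhythmCall(
            probe_id=probe_id, phase=float(bank.phases[0]), r=0.0, p_value=1.0,
            predicted_fc=0.0, abs_change=0.0, rhythmic=False,
            failure_reason=FAIL_CORRELATION,
        )

    phase, r = best_phase_correlation(series, bank)
    p = correlation_pvalue(r, n, one_sided=params.one_sided)
    pfc = predicted_fold_change(series, times, phase, params)
    abs_ok = abs_change >= params.abs_change_threshold(grand_mean)
    # relative epsilon keeps series lying exactly on the boundary ratio
    # (FC_obs == FC_ref up to round-off) on the passing side
    fold_ok = pfc >= params.fold_threshold * (1.0 - 1e-9)

    if p >= params.alpha:
        reason = FAIL_CORRELATION
        rhythmic = False
    elif not (fold_ok or abs_ok):
        reason = FAIL_AMPLITUDE
        rhythmic = False
    else:
        reason = FAIL_NONE
        rhythmic = True
    return RhythmCall(
        probe_id=probe_id, phase=phase, r=r, p_value=p, predicted_fc=pfc,
        abs_change=abs_change, rhythmic=rhythmic, failure_reason=reason,
    )


def classify_all(ds, group: tuple[str, str], params: RhythmParams,
                 probes: Sequence[str] | None = None) -> pd.DataFrame:
    """Classify every retained probe of one (condition, genotype) group.

    Returns a DataFrame with one row per probe: phase, r, p_value,
    predicted_fc, abs_change, rhythmic, failure_reason.  The dataset's
    grand_mean at call time feeds the absolute-change criterion.
    """
    cond, geno = group
    samples = ds.group_samples(cond, geno)
    times = ds.group_times(cond, geno)
    values = ds.values[samples] if probes is None else ds.values.loc[list(probes), samples]
    bank = build_template_bank(times, params)

    rows = []
    for probe_id, series in zip(values.index, values.to_numpy(dtype=float)):
        call = classify_gene(series, times, ds.grand_mean, params, bank=bank,
                             probe_id=str(probe_id))
        rows.append(call.as_dict())
    calls = pd.DataFrame(rows).set_index("probe_id")

    n_rhythmic = int(calls["rhythmic"].sum())
    breakdown = calls.loc[~calls["rhythmic"], "failure_reason"].value_counts().to_dict()
    logger.info(
        "group (%s, %s): %d/%d rhythmic (%.1f%%); failures: %s",
        cond, geno, n_rhythmic, len(calls),
        100.0 * n_rhythmic / max(len(calls), 1), breakdown,
    )
    return calls


def calls_to_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="probe_id")


def calls_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str}).set_index("probe_id")
    df["rhythmic"] = df["rhythmic"].astype(bool)
    return df
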