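"""Bootstrap z-scores for phase enrichment of motif-carrying genes.

For each circadian phase a rolling four-phase window collects the
rhythmic genes peaking there.  The observed number of motif carriers in
the window is compared against the carrier counts of random same-size
groups drawn (without replacement, window genes included) from all
rhythmic genes in the dataset: z = (observed - null mean) / null sd.
The z profile is smoothed with a 3-point circular moving average and
masked at the two-sided normal critical value 1.96 (p = 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_CRITICAL = 1.96
DEFAULT_WINDOW = 4
DEFAULT_N_BOOT = 100


@dataclass(frozen=True)
class EnrichmentParams:
    seed: int
    window_width: int = DEFAULT_WINDOW
    n_boot: int = DEFAULT_N_BOOT
    period: float = 24.0
    phase_step: float = 1.0
    z_threshold: float = Z_CRITICAL

    def __post_init__(self) -> None:
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")

    @property
    def n_windows(self) -> int:
        return int(round(self.period / self.phase_step))


@dataclass(frozen=True)
class PhaseEnrichmentProfile:
    """Per-window enrichment results as a tidy DataFrame plus run metadata.

    ``table`` columns: center, observed, n_window, null_mean, null_sd,
    z, z_smoothed, significant (on smoothed z), significant_raw.
    z is NaN (undefined) where null_sd = 0 or the window is empty.
    """

    table: pd.DataFrame
    n_boot: int
    window_width: int
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def window_phases(center: float, width: int, period: float = 24.0,
                  phase_step: float = 1.0) -> np.ndarray:
    """Phase labels covered by the window anchored at ``center``.

    A width-w window covers ``center - floor((w-1)/2) ... center +
    ceil((w-1)/2)`` circularly — for the even width 4 this is
    {c-1, c, c+1, c+2}, biased late, matching windows labeled by the
    earlier of the two central phases.
    """
    start = center - ((width - 1) // 2) * phase_step
    return np.mod(start + np.arange(width) * phase_step, period)


def window_membership(phases: np.ndarray, center: float, width: int = DEFAULT_WINDOW,
                      period: float = 24.0, phase_step: float = 1.0) -> np.ndarray:
    """Boolean mask of genes whose phase falls in the circular window."""
    phases = np.asarray(phases, dtype=float)
    wp = window_phases(center, width, period, phase_step)
    return np.isin(np.mod(phases, period), wp)


def bootstrap_null(carrier_flags: np.ndarray, group_size: int, n_boot: int,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Mean and sample sd of carrier counts in random same-size groups.

    Each of the ``n_boot`` groups is drawn without replacement from all
    rhythmic genes (window genes included).  Returns (0, 0) for an
    empty window.
    """
    carrier_flags = np.asarray(carrier_flags, dtype=bool)
    n_genes = carrier_flags.size
    if group_size > n_genes:
        raise ValueError(f"group_size {group_size} exceeds {n_genes} rhythmic genes")
    if n_boot < 2:
        raise ValueError("need n_boot >= 2 for a sample sd")
    if group_size == 0:
        return 0.0, 0.0
    counts = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        idx = rng.choice(n_genes, size=group_size, replace=False)
        counts[b] = carrier_flags[idx].sum()
    return float(counts.mean()), float(counts.std(ddof=1))


def smooth3_circular(z: np.ndarray) -> np.ndarray:
    """3-point circular moving average, skipping NaN neighbours.

    Each entry becomes the mean of itself and its two circular
    neighbours; NaN entries are dropped from their neighbours' means
    (reduced denominator).  An entry with no finite value among the
    three stays NaN.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 points for circular smoothing")
    stacked = np.vstack([np.roll(z, 1), z, np.roll(z, -1)])
    finite = np.isfinite(stacked)
    sums = np.where(finite, stacked, 0.0).sum(axis=0)
    counts = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def zscore_profile(calls: pd.DataFrame, carrier_flags: pd.Series,
                   params: EnrichmentParams) -> PhaseEnrichmentProfile:
    """Full rolling-window bootstrap enrichment profile.

    ``calls`` is a rhythm-call table (indexed by gene, with ``rhythmic``
    and ``phase`` columns); ``carrier_flags`` maps gene -> bool motif
    presence and must cover every rhythmic gene.  Deterministic for a
    given ``params.seed``.
    """
    rhythmic = calls.loc[calls["rhythmic"]]
    missing = set(rhythmic.index) - set(carrier_flags.index)
    if missing:
        raise ValueError(f"carrier flags missing for rhythmic genes: {sorted(missing)[:5]}")
    phases = rhythmic["phase"].to_numpy(dtype=float)
    flags = carrier_flags.loc[rhythmic.index].to_numpy(dtype=bool)

    rng = np.random.default_rng(params.seed)
    centers = np.arange(params.n_windows) * params.phase_step
    rows = []
    for center in centers:
        member = window_membership(phases, center, params.window_width,
                                   params.period, params.phase_step)
        n_window = int(member.sum())
        observed = int(flags[member].sum())
        null_mean, null_sd = bootstrap_null(flags, n_window, params.n_boot, rng)
        z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
        rows.append({
            "center": float(center), "observed": observed, "n_window": n_window,
            "null_mean": null_mean, "null_sd": null_sd, "z": z,
        })
    table = pd.DataFrame(rows)
    table["z_smoothed"] = smooth3_circular(table["z"].to_numpy())
    table["significant"] = np.abs(table["z_smoothed"]) > params.z_threshold
    table["significant_raw"] = np.abs(table["z"]) > params.z_threshold
    # NaN comparisons are False already; keep them explicit
    table.loc[~np.isfinite(table["z_smoothed"]), "significant"] = False
    table.loc[~np.isfinite(table["z"]), "significant_raw"] = False

    n_sig = int(table["significant"].sum())
    logger.info("phase enrichment: %d/%d significant windows (|z_smoothed| > %.2f)",
                n_sig, len(table), params.z_threshold)
    return PhaseEnrichmentProfile(table=table, n_boot=params.n_boot,
                                  window_width=params.window_width, seed=params.seed)


def hypergeometric_null_moments(n_genes: int, n_carriers: int,
                                group_size: int) -> tuple[float, float]:
    """Closed-form mean/sd of carrier counts in a random group (test oracle)."""
    if group_size == 0:
        return 0.0, 0.0
    p = n_carriers / n_genes
    mean = group_size * p
    if n_genes < 2:
        return float(mean), 0.0
    var = group_size * p * (1 - p) * (n_genes - group_size) / (n_genes - 1)
    return float(mean), float(np.sqrt(var))
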