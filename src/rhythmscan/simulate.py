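"""Synthetic circadian datasets with full ground truth.

Generates expression matrices on the two sampling schedules the
analysis supports (one cycle at 8-h spacing, two cycles at 4-h
spacing), paired-condition variants with programmed per-gene effects,
and promoter FASTA with phase-coupled motif planting — everything
deterministic given a seed, so each pipeline stage can be validated
against known truth without downloads.

Signal model per gene:

    value(g, t) = max(eps, m * (1 + a(t) * cos(2*pi*(t - phi)/24)) + noise)
    a(t) = (A/m) * exp(-damping * t / 24),  A = m * (ratio-1)/(ratio+1)
    noise ~ Normal(0, (noise_sd_frac * m)^2), i.i.d. per sample

With zero noise and damping this is exactly the classifier's template
family, so recovery there is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rhythmscan.dataset_io import ExpressionDataset
from rhythmscan.motifs import IUPACMotif

EPSILON = 1e-6

SCHEDULES: dict[str, np.ndarray] = {
    # two cycles, 12 samples at 4-h intervals starting 24 h after transfer
    "white": np.arange(24.0, 68.0 + 1e-9, 4.0),
    # one cycle, 4 samples at 8-h intervals
    "red": np.array([24.0, 32.0, 40.0, 48.0]),
}


@dataclass(frozen=True)
class PairedEffects:
    """Per-gene modifications applied to derive condition B from A.

    ``force_arrhythmic_fraction`` flattens a random subset of the
    A-rhythmic genes completely (they lose the waveform, so they
    typically fail the correlation criterion downstream).
    ``amplitude_loss_fraction`` instead drops a random subset's
    peak-to-trough ratio to ``amplitude_loss_ratio`` — the waveform
    survives but its amplitude no longer clears the fold threshold, so
    those genes fail on amplitude.
    """

    phase_delay_h: float = 0.0
    amplitude_scale: float = 1.0
    mean_scale: float = 1.0
    force_arrhythmic_fraction: float = 0.0
    amplitude_loss_fraction: float = 0.0
    amplitude_loss_ratio: float = 1.2

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0 or self.mean_scale <= 0:
            raise ValueError("scales must be positive")
        for name in ("force_arrhythmic_fraction", "amplitude_loss_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.amplitude_loss_ratio < 1:
            raise ValueError("amplitude_loss_ratio must be >= 1")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_genes: int
    seed: int
    schedule: str | np.ndarray = "white"
    fraction_rhythmic: float = 0.5
    phase_distribution: str | np.ndarray = "uniform"   # or explicit phases
    mean_level: float = 100.0
    mean_level_sd_log2: float = 0.0    # lognormal spread of gene means
    peak_trough_ratio: float = 2.0
    noise_sd_frac: float = 0.0
    damping_rate: float = 0.0
    condition: str = "synthetic"
    genotype: str = "WT"
    paired_effects: PairedEffects | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.fraction_rhythmic <= 1:
            raise ValueError("fraction_rhythmic must be in [0, 1]")
        if self.peak_trough_ratio < 1:
            raise ValueError("peak_trough_ratio must be >= 1")
        if self.noise_sd_frac < 0 or self.damping_rate < 0:
            raise ValueError("noise_sd_frac and damping_rate must be >= 0")
        if self.mean_level <= 0:
            raise ValueError("mean_level must be positive")
        times = self.times()
        if (np.diff(times) <= 0).any() or (times < 0).any():
            raise ValueError("schedule times must be non-negative and strictly increasing")

    def times(self) -> np.ndarray:
        if isinstance(self.schedule, str):
            try:
                return SCHEDULES[self.schedule].copy()
            except KeyError:
                raise ValueError(f"unknown schedule preset {self.schedule!r}") from None
        return np.asarray(self.schedule, dtype=float)


def _draw_truth(spec: SyntheticDatasetSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_genes
    n_rhythmic = int(round(spec.fraction_rhythmic * n))
    rhythmic = np.zeros(n, dtype=bool)
    rhythmic[:n_rhythmic] = True

    if isinstance(spec.phase_distribution, str):
        if spec.phase_distribution != "uniform":
            raise ValueError(f"unknown phase distribution {spec.phase_distribution!r}")
        phases = rng.integers(0, 24, size=n).astype(float)
    else:
        phases = np.asarray(spec.phase_distribution, dtype=float)
        if phases.shape[0] != n:
            raise ValueError("explicit phase vector length must equal n_genes")
    phases = np.where(rhythmic, phases, 0.0)

    if spec.mean_level_sd_log2 > 0:
        means = spec.mean_level * 2.0 ** rng.normal(0, spec.mean_level_sd_log2, size=n)
    else:
        means = np.full(n, spec.mean_level)
    ratios = np.where(rhythmic, spec.peak_trough_ratio, 1.0)

    return pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(n)],
        "rhythmic": rhythmic,
        "phase_h": phases,
        "mean_level": means,
        "peak_trough_ratio": ratios,
        "noise_sd_frac": spec.noise_sd_frac,
        "damping_rate": spec.damping_rate,
    }).set_index("gene_id")


def _evaluate(truth: pd.DataFrame, times: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    m = truth["mean_level"].to_numpy()[:, None]
    ratio = truth["peak_trough_ratio"].to_numpy()[:, None]
    phase = truth["phase_h"].to_numpy()[:, None]
    damping = truth["damping_rate"].to_numpy()[:, None]
    noise_frac = truth["noise_sd_frac"].to_numpy()[:, None]

    amp_frac = (ratio - 1.0) / (ratio + 1.0)
    a_t = amp_frac * np.exp(-damping * times[None, :] / 24.0)
    signal = m * (1.0 + a_t * np.cos(2 * np.pi * (times[None, :] - phase) / 24.0))
    noise = rng.normal(0.0, 1.0, size=signal.shape) * (noise_frac * m)
    return np.maximum(EPSILON, signal + noise)


def _to_dataset(values: np.ndarray, truth: pd.DataFrame, times: np.ndarray,
                condition: str, genotype: str,
                sample_prefix: str = "S") -> ExpressionDataset:
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(len(times))]
    design = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": condition,
        "genotype": genotype,
        "time_h": times,
    })
    annotation = pd.DataFrame({
        "probe_id": truth.index,
        "agi_code": [f"AT1G{i:05d}" for i in range(len(truth))],
        "compartment": "nuclear",
    })
    frame = pd.DataFrame(values, index=truth.index, columns=sample_ids)
    frame.index.name = "probe_id"
    return ExpressionDataset(values=frame, design=design, annotation=annotation)


def simulate_expression(
    spec: SyntheticDatasetSpec,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate one condition's expression matrix plus its truth table."""
    rng = np.random.default_rng(spec.seed)
    truth = _draw_truth(spec, rng)
    times = spec.times()
    values = _evaluate(truth, times, rng)
    ds = _to_dataset(values, truth, times, spec.condition, spec.genotype)
    return ds, truth


def simulate_paired(
    spec: SyntheticDatasetSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Generate two paired conditions (B derived from A via programmed effects).

    The combined truth table carries both parameter sets; the column
    ``forced_arrhythmic`` marks A-rhythmic genes silenced in B.
    """
    if spec.paired_effects is None:
        raise ValueError("paired_effects must be set for simulate_paired")
    eff = spec.paired_effects
    rng = np.random.default_rng(spec.seed)
    truth_a = _draw_truth(spec, rng)
    times = spec.times()
    values_a = _evaluate(truth_a, times, rng)

    truth_b = truth_a.copy()
    truth_b["phase_h"] = np.mod(truth_b["phase_h"] + eff.phase_delay_h, 24.0)
    truth_b["mean_level"] = truth_b["mean_level"] * eff.mean_scale
    # amplitude scale acts on the amplitude fraction, re-expressed as a ratio
    amp_frac = ((truth_b["peak_trough_ratio"] - 1) / (truth_b["peak_trough_ratio"] + 1)
                * eff.amplitude_scale).clip(upper=0.999)
    truth_b["peak_trough_ratio"] = (1 + amp_frac) / (1 - amp_frac)

    ratio_col = truth_b.columns.get_loc("peak_trough_ratio")
    forced = np.zeros(len(truth_b), dtype=bool)
    amp_lost = np.zeros(len(truth_b), dtype=bool)
    candidates = np.flatnonzero(truth_a["rhythmic"].to_numpy())
    if eff.force_arrhythmic_fraction > 0:
        n_force = int(round(eff.force_arrhythmic_fraction * candidates.size))
        forced_idx = rng.choice(candidates, size=n_force, replace=False)
        forced[forced_idx] = True
        truth_b.iloc[forced_idx, ratio_col] = 1.0
        truth_b.iloc[forced_idx, truth_b.columns.get_loc("rhythmic")] = False
    if eff.amplitude_loss_fraction > 0:
        free = np.setdiff1d(candidates, np.flatnonzero(forced))
        n_loss = int(round(eff.amplitude_loss_fraction * candidates.size))
        if n_loss > free.size:
            raise ValueError("force_arrhythmic and amplitude_loss fractions overlap")
        loss_idx = rng.choice(free, size=n_loss, replace=False)
        amp_lost[loss_idx] = True
        truth_b.iloc[loss_idx, ratio_col] = eff.amplitude_loss_ratio

    values_b = _evaluate(truth_b, times, rng)

    ds_a = _to_dataset(values_a, truth_a, times, "A", spec.genotype, sample_prefix="A")
    ds_b = _to_dataset(values_b, truth_b, times, "B", spec.genotype, sample_prefix="B")

    truth = truth_a.join(truth_b, lsuffix="_A", rsuffix="_B")
    truth["forced_arrhythmic"] = forced
    truth["amplitude_lost"] = amp_lost
    return ds_a, ds_b, truth


def simulate_promoters(
    gene_truth: pd.DataFrame,
    motif: IUPACMotif,
    base_rate: float,
    phase_coupling: dict[float, float] | None = None,
    length: int = 500,
    seed: int = 0,
    planted_offset: int | None = None,
    window_width: int = 4,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with probabilistic, optionally phase-coupled planting.

    Each gene gets an i.i.d. uniform A/C/G/T background sequence; with
    probability given by its phase window's rate (``phase_coupling``
    maps window-center phase -> rate; genes outside any window use
    ``base_rate``) a single motif instance is written at a uniform
    random offset (or at ``planted_offset`` bp upstream, measured at
    the footprint's TSS-proximal end).  Returns (promoters, truth) —
    the truth table lists carrier flag and planted offset per gene.
    """
    from rhythmscan.phase_enrichment import window_phases

    if not 0 <= base_rate <= 1:
        raise ValueError("base_rate must be in [0, 1]")
    k = len(motif)
    if k > length:
        raise ValueError(f"motif length {k} exceeds promoter length {length}")
    rng = np.random.default_rng(seed)

    rate_by_phase: dict[float, float] = {}
    if phase_coupling:
        for center, rate in phase_coupling.items():
            if not 0 <= rate <= 1:
                raise ValueError("phase_coupling rates must be in [0, 1]")
            for p in window_phases(float(center), window_width):
                rate_by_phase[float(p)] = rate

    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    rows = []
    # concrete instance for degenerate patterns: draw per gene
    pattern_choices = [sorted(_iupac_options(c)) for c in motif.pattern]
    for gene_id, row in gene_truth.iterrows():
        seq = rng.choice(bases, size=length)
        rate = base_rate
        if row.get("rhythmic", False):
            rate = rate_by_phase.get(float(row["phase_h"]) % 24.0, base_rate)
        planted = bool(rng.random() < rate)
        offset = 0
        if planted:
            if planted_offset is None:
                offset = int(rng.integers(1, length - k + 2))
            else:
                offset = int(planted_offset)
            start = length - offset - k + 1
            instance = [opts[rng.integers(len(opts))] for opts in pattern_choices]
            seq[start:start + k] = instance
        promoters[str(gene_id)] = "".join(seq)
        rows.append({"gene_id": gene_id, "carrier": planted, "offset": offset})
    truth = pd.DataFrame(rows).set_index("gene_id")
    return promoters, truth


def _iupac_options(code: str) -> frozenset[str]:
    from rhythmscan.motifs import IUPAC_CODES
    return IUPAC_CODES[code]


def write_fasta(promoters: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
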