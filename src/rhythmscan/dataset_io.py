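"""Ingestion, validation, and filtering of expression time-course data.

The central container is :class:`ExpressionDataset`: a genes x samples
matrix of non-negative expression values plus a per-column sample design
(condition, genotype, hours in constant light) and a per-row gene
annotation (AGI code, subcellular compartment).  The dataset-level
``grand_mean`` — the mean of all retained values across all arrays —
feeds two downstream criteria: the 5% expressed-gene floor and the
absolute-change amplitude test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("sample_id", "condition", "genotype", "time_h")
ANNOTATION_COLUMNS = ("probe_id", "agi_code", "compartment")
VALID_COMPARTMENTS = frozenset({"nuclear", "mitochondrial", "chloroplastic"})


class IngestionError(ValueError):
    """Raised when an input table fails validation."""


@dataclass(frozen=True)
class ExpressionDataset:
    """Expression matrix with sample design and gene annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression matrix, index = probe_id, columns =
        sample_id, column order matching ``design``.
    design : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``condition``,
        ``genotype``, ``time_h``.
    annotation : pandas.DataFrame
        One row per probe with columns ``probe_id``, ``agi_code``
        (empty string when absent), ``compartment``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.DataFrame
    _grand_mean: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _validate_dataset(self.values, self.design, self.annotation)
        if self._grand_mean is None:
            gm = float(self.values.to_numpy(dtype=float).mean()) if self.values.size else 0.0
            object.__setattr__(self, "_grand_mean", gm)

    @property
    def grand_mean(self) -> float:
        """Mean of all retained probe values across all arrays."""
        return self._grand_mean

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[tuple[str, str]]:
        """(condition, genotype) pairs present in the design, in order."""
        seen: list[tuple[str, str]] = []
        for _, row in self.design.iterrows():
            key = (row["condition"], row["genotype"])
            if key not in seen:
                seen.append(key)
        return seen

    def group_samples(self, condition: str, genotype: str) -> list[str]:
        """Sample ids of one (condition, genotype) group, time-ordered."""
        mask = (self.design["condition"] == condition) & (self.design["genotype"] == genotype)
        sub = self.design.loc[mask].sort_values("time_h")
        if sub.empty:
            raise KeyError(f"no samples for group (condition={condition!r}, genotype={genotype!r})")
        return sub["sample_id"].tolist()

    def group_times(self, condition: str, genotype: str) -> np.ndarray:
        samples = self.group_samples(condition, genotype)
        times = self.design.set_index("sample_id").loc[samples, "time_h"]
        return times.to_numpy(dtype=float)

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionDataset":
        """Dataset restricted to ``probes``; grand_mean recomputed."""
        probes = list(probes)
        missing = set(probes) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown probes: {sorted(missing)[:5]}")
        values = self.values.loc[probes]
        annotation = self.annotation.set_index("probe_id").loc[probes].reset_index()
        return ExpressionDataset(values=values, design=self.design, annotation=annotation)


def _validate_dataset(values: pd.DataFrame, design: pd.DataFrame, annotation: pd.DataFrame) -> None:
    if list(values.columns) != design["sample_id"].tolist():
        raise IngestionError("matrix columns do not match design sample order")
    if list(values.index) != annotation["probe_id"].tolist():
        raise IngestionError("matrix rows do not match annotation probe order")
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise IngestionError(f"duplicate sample ids: {dupes}")
    if annotation["probe_id"].duplicated().any():
        dupes = annotation.loc[annotation["probe_id"].duplicated(), "probe_id"].tolist()
        raise IngestionError(f"duplicate probe ids: {dupes}")
    if (design["time_h"].to_numpy(dtype=float) < 0).any():
        raise IngestionError("negative time_h in design")
    arr = values.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise IngestionError("non-numeric values in expression matrix")
    if arr.size and np.isnan(arr.astype(float)).any():
        r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
        raise IngestionError(
            f"missing value at probe {values.index[r]!r}, sample {values.columns[c]!r}"
        )
    for (cond, geno), sub in design.groupby(["condition", "genotype"], sort=False):
        t = np.sort(sub["time_h"].to_numpy(dtype=float))
        if len(t) > 1 and (np.diff(t) <= 0).any():
            raise IngestionError(
                f"non-increasing sample times within group ({cond}, {geno})"
            )


def read_expression_table(
    path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read matrix + design + annotation tables into an ExpressionDataset.

    The matrix file's first column is ``probe_id``; remaining column
    headers are sample ids.  Columns are reordered to match the design
    order.  Delimiter is sniffed from the file extension (``.csv`` ->
    comma, otherwise tab) unless ``sep`` is given.
    """
    def _sep(p: str | Path) -> str:
        if sep is not None:
            return sep
        return "," if str(p).endswith(".csv") else "\t"

    design = pd.read_csv(design_path, sep=_sep(design_path), dtype={"sample_id": str})
    missing_cols = set(DESIGN_COLUMNS) - set(design.columns)
    if missing_cols:
        raise IngestionError(f"design table missing columns: {sorted(missing_cols)}")
    design = design[list(DESIGN_COLUMNS)].copy()
    design["time_h"] = design["time_h"].astype(float)

    annotation = pd.read_csv(
        annotation_path, sep=_sep(annotation_path), dtype=str, keep_default_na=False
    )
    missing_cols = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing_cols:
        raise IngestionError(f"annotation table missing columns: {sorted(missing_cols)}")
    annotation = annotation[list(ANNOTATION_COLUMNS)].copy()
    bad_comp = set(annotation["compartment"]) - VALID_COMPARTMENTS
    if bad_comp:
        raise IngestionError(f"unknown compartment labels: {sorted(bad_comp)}")

    raw = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "probe_id"

    missing_samples = [s for s in design["sample_id"] if s not in raw.columns]
    if missing_samples:
        raise IngestionError(f"samples in design missing from matrix: {missing_samples}")
    raw = raw[design["sample_id"].tolist()]

    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.argmax()]
            raise IngestionError(
                f"non-numeric cell at probe {probe!r}, sample {col!r}: {raw.loc[probe, col]!r}"
            )
        raw[col] = coerced

    missing_ann = set(raw.index) - set(annotation["probe_id"])
    if missing_ann:
        raise IngestionError(f"probes missing annotation: {sorted(missing_ann)[:5]}")
    annotation = annotation.set_index("probe_id").loc[list(raw.index)].reset_index()

    return ExpressionDataset(values=raw.astype(float), design=design, annotation=annotation)


def filter_annotation(ds: ExpressionDataset) -> ExpressionDataset:
    """Drop probes without an AGI code and non-nuclear probes.

    Idempotent.  grand_mean is recomputed on the retained set.
    """
    ann = ds.annotation
    keep = (ann["agi_code"].astype(str).str.strip() != "") & (ann["compartment"] == "nuclear")
    retained = ann.loc[keep, "probe_id"].tolist()
    if not retained:
        raise IngestionError("annotation filter removed every probe; nothing to analyze")
    if len(retained) == ds.n_probes:
        return ds
    out = ds.subset_probes(retained)
    logger.info("annotation filter: %d -> %d probes", ds.n_probes, out.n_probes)
    return out


def filter_expressed(
    ds: ExpressionDataset,
    groups: Iterable[tuple[str, str]] | None = None,
    floor_fraction: float = 0.05,
) -> list[str]:
    """Probes whose mean reaches the expression floor in at least one group.

    A probe is discarded only when its per-group mean expression is
    below ``floor_fraction * grand_mean`` in EVERY (condition, genotype)
    group considered.  Returns the retained probe list (matrix order).
    """
    if not 0 <= floor_fraction < 1:
        raise ValueError(f"floor_fraction must be in [0, 1), got {floor_fraction}")
    if groups is None:
        groups = ds.groups()
    groups = list(groups)
    if not groups:
        raise ValueError("no groups to consider")
    floor = floor_fraction * ds.grand_mean
    keep = np.zeros(ds.n_probes, dtype=bool)
    for cond, geno in groups:
        samples = ds.group_samples(cond, geno)
        group_mean = ds.values[samples].to_numpy(dtype=float).mean(axis=1)
        keep |= group_mean >= floor
    retained = ds.values.index[keep].tolist()
    logger.info(
        "expression floor %.3g x grand_mean=%.4g over %d groups: %d -> %d probes",
        floor_fraction, ds.grand_mean, len(groups), ds.n_probes, len(retained),
    )
    return retained


def median_dynamic_range(ds: ExpressionDataset, probes: Sequence[str] | None = None) -> float:
    """Median over probes of (max / min) across that probe's samples."""
    values = ds.values if probes is None else ds.values.loc[list(probes)]
    arr = values.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("no probes to summarize")
    mins = arr.min(axis=1)
    if (mins <= 0).any():
        probe = values.index[int(np.argmax(mins <= 0))]
        raise ValueError(f"non-positive minimum for probe {probe!r}; dynamic range undefined")
    return float(np.median(arr.max(axis=1) / mins))


def rescale_arrays(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each array so its median equals the median of array medians.

    Convenience stand-in only — NOT equivalent to model-based
    invariant-set normalization; use pre-normalized input when counts
    matter.
    """
    logger.warning(
        "rescale_arrays: simple median scaling, not equivalent to model-based normalization"
    )
    arr = ds.values.to_numpy(dtype=float)
    medians = np.median(arr, axis=0)
    target = np.median(medians)
    if (medians <= 0).any():
        raise ValueError("non-positive array median; cannot rescale")
    scaled = arr * (target / medians)
    values = pd.DataFrame(scaled, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(values=values, design=ds.design, annotation=ds.annotation)


def write_expression_dataset(ds: ExpressionDataset, matrix_path: str | Path,
                             design_path: str | Path, annotation_path: str | Path) -> None:
    """Write the three tables back out as TSV."""
    ds.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    ds.design.to_csv(design_path, sep="\t", index=False)
    ds.annotation.to_csv(annotation_path, sep="\t", index=False)
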