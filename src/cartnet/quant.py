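"""Peptide-to-protein quantification for targeted (SRM) proteomics.

The quantification chain converts raw peptide peak areas into a normalized
protein abundance matrix:

1. **Rollup** — the response of each protein is the geometric mean of the
   peak areas of its two protein-specific peptides.
2. **Standards normalization** — each sample is divided by its BSA spike-in
   response (correcting per-sample processing variation) and then by its
   spike-in-normalized response of a stable endogenous reference protein
   (MDH1), which therefore becomes identically 1.
3. **Batch normalization** — samples were acquired in separate runs; within
   each run, every protein is divided by its median response over the
   anchor-group samples of that run (the groups present in every run), so
   run-level multiplicative offsets cancel.
4. **Quantifiability filter** — proteins insufficiently detected in any
   group are dropped.

Every step is multiplicative, so the full chain is invariant to scaling all
areas of any single sample by a constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError, SchemaError

__all__ = [
    "PeptideTable",
    "SampleSheet",
    "AbundanceMatrix",
    "rollup_protein",
    "rollup_table",
    "normalize_to_standards",
    "batch_normalize",
    "filter_quantifiable",
    "quantify",
]


@dataclass
class PeptideTable:
    """Raw peak areas keyed by (protein, peptide) x sample.

    ``data`` has a two-level index ``(protein_id, peptide_id)`` and one
    column per sample; values are non-negative areas or NaN for missing.
    Every non-spike-in protein must have exactly two peptide rows; the
    spike-in standard has a single row.
    """

    data: pd.DataFrame
    spikein_id: str = "BSA"

    def proteins(self) -> list[str]:
        return list(self.data.index.get_level_values(0).unique())

    def samples(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> None:
        if self.data.index.nlevels != 2:
            raise SchemaError("peptide table must be indexed by (protein_id, peptide_id)")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate sample ids: {dupes}")
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate (protein, peptide) rows")
        counts = self.data.groupby(level=0).size()
        for protein, k in counts.items():
            if protein == self.spikein_id:
                if k != 1:
                    raise SchemaError(
                        f"spike-in {protein!r} must have exactly 1 peptide row, has {k}"
                    )
            elif k != 2:
                raise SchemaError(
                    f"protein {protein!r} must have exactly 2 peptide rows, has {k}"
                )
        if (self.data < 0).any().any():
            raise SchemaError("peak areas must be >= 0 or missing")


@dataclass
class SampleSheet:
    """Per-sample metadata: diet group and acquisition run."""

    data: pd.DataFrame  # index sample_id; columns: group, run

    def validate(self, samples: list[str] | None = None) -> None:
        for col in ("group", "run"):
            if col not in self.data.columns:
                raise SchemaError(f"sample sheet missing required column {col!r}")
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate sample ids in sample sheet")
        if samples is not None:
            missing = [s for s in samples if s not in self.data.index]
            if missing:
                raise SchemaError(
                    f"samples present in peptide table but absent from sample sheet: {missing}"
                )

    def groups_in_all_runs(self) -> set[str]:
        """Groups present in every run — the default batch anchor set."""
        per_run = self.data.groupby("run")["group"].agg(set)
        return set.intersection(*per_run.tolist()) if len(per_run) else set()


@dataclass
class AbundanceMatrix:
    """Normalized protein x sample abundances with sample metadata.

    ``provenance`` records the normalization steps applied, in order.
    """

    values: pd.DataFrame  # index protein_id, columns sample_id
    samples: pd.DataFrame  # index sample_id; columns group, run
    provenance: list[str] = field(default_factory=list)

    def group_values(self, group: str) -> pd.DataFrame:
        cols = self.samples.index[self.samples["group"] == group]
        if len(cols) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[list(cols)]

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))


def rollup_protein(peptide_area_1: float, peptide_area_2: float) -> float:
    """Geometric mean of the two protein-specific peptide areas."""
    if peptide_area_1 <= 0 or peptide_area_2 <= 0:
        raise ValueError(
            "geometric mean undefined for non-positive areas: "
            f"({peptide_area_1}, {peptide_area_2})"
        )
    return math.sqrt(peptide_area_1 * peptide_area_2)


def rollup_table(table: PeptideTable, missing_policy: str = "drop") -> pd.DataFrame:
    """Roll peptide areas up to one response per (protein, sample).

    Both peptides present -> geometric mean; exactly one present ->
    ``missing_policy`` ("single": use the lone peptide; "drop": mark the
    cell missing); both missing -> missing.  The spike-in's single row
    passes through unchanged.
    """
    if missing_policy not in ("drop", "single"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    table.validate()
    log = np.log(table.data.where(table.data > 0))
    n_present = log.notna().groupby(level=0).sum()
    mean_log = log.groupby(level=0).mean()  # skips NaN -> lone-peptide value
    out = np.exp(mean_log)
    n_expected = pd.Series(
        {p: (1 if p == table.spikein_id else 2) for p in n_present.index}
    )
    if missing_policy == "drop":
        out = out.where(n_present.eq(n_expected, axis=0))
    else:
        out = out.where(n_present > 0)
    return out.loc[table.proteins()]


def normalize_to_standards(
    responses: pd.DataFrame,
    spikein_id: str = "BSA",
    reference_id: str = "MDH1",
) -> pd.DataFrame:
    """Divide each sample by its spike-in response, then by its reference.

    After this step the reference protein row is identically 1 and the
    spike-in row is removed.  Raises :class:`NormalizationError` naming the
    first sample whose spike-in or reference response is missing or zero.
    """
    for row_id, label in ((spikein_id, "spike-in"), (reference_id, "reference")):
        if row_id not in responses.index:
            raise NormalizationError(f"{label} protein {row_id!r} not in response table")
        row = responses.loc[row_id]
        bad = row.index[~(row > 0)].tolist()
        if bad:
            raise NormalizationError(
                f"{label} {row_id!r} missing or non-positive in sample(s) {bad}"
            )
    out = responses.div(responses.loc[spikein_id], axis=1)
    out = out.div(out.loc[reference_id], axis=1)
    return out.drop(index=spikein_id)


def batch_normalize(
    matrix: AbundanceMatrix,
    anchor_groups: set[str] | None = None,
    mode: str = "per-protein",
) -> AbundanceMatrix:
    """Remove run-level multiplicative offsets via anchor-group medians.

    Within each run, divide each protein by the median of its responses
    over the run's anchor-group samples (``mode="per-protein"``), or divide
    the whole run by one grand median over anchor samples and all proteins
    (``mode="global"``).  Anchor groups default to the groups present in
    every run.  After per-protein anchoring, each protein's anchor-sample
    median is 1 in every run, so the operation is idempotent.
    """
    if mode not in ("per-protein", "global"):
        raise ValueError(f"unknown batch-median mode {mode!r}")
    sheet = matrix.samples
    if anchor_groups is None:
        per_run = sheet.groupby("run")["group"].agg(set)
        anchor_groups = set.intersection(*per_run.tolist())
        if not anchor_groups:
            raise ConfigurationError(
                "no group is present in every run; pass anchor_groups explicitly"
            )
    values = matrix.values.copy()
    for run, run_sheet in sheet.groupby("run"):
        run_cols = list(run_sheet.index)
        anchor_cols = list(run_sheet.index[run_sheet["group"].isin(anchor_groups)])
        if not anchor_cols:
            raise ConfigurationError(
                f"run {run!r} contains no sample from anchor groups {sorted(anchor_groups)}"
            )
        if mode == "global":
            med = float(np.nanmedian(values[anchor_cols].to_numpy()))
            values[run_cols] = values[run_cols] / med
            continue
        med = values[anchor_cols].median(axis=1)
        unscalable = med.index[~(med > 0)].tolist()
        if unscalable:
            warnings.warn(
                f"run {run!r}: protein(s) {unscalable} missing in all anchor "
                "samples; left unscaled",
                stacklevel=2,
            )
            med = med.where(med > 0, 1.0)
        values[run_cols] = values[run_cols].div(med, axis=0)
    return AbundanceMatrix(
        values=values,
        samples=matrix.samples,
        provenance=matrix.provenance
        + [f"batch_normalize(mode={mode}, anchors={sorted(anchor_groups)})"],
    )


def filter_quantifiable(
    matrix: AbundanceMatrix, min_detect_fraction: float = 1.0
) -> AbundanceMatrix:
    """Keep proteins detected in >= ``min_detect_fraction`` of every group."""
    if not (0 < min_detect_fraction <= 1):
        raise ValueError("min_detect_fraction must be in (0, 1]")
    keep = pd.Series(True, index=matrix.values.index)
    for group in matrix.groups():
        gv = matrix.group_values(group)
        keep &= gv.notna().mean(axis=1) >= min_detect_fraction
    dropped = int((~keep).sum())
    return AbundanceMatrix(
        values=matrix.values[keep],
        samples=matrix.samples,
        provenance=matrix.provenance
        + [
            f"filter_quantifiable(min_detect_fraction={min_detect_fraction}): "
            f"kept {int(keep.sum())}, dropped {dropped}"
        ],
    )


def quantify(
    table: PeptideTable,
    sheet: SampleSheet,
    spikein_id: str = "BSA",
    reference_id: str = "MDH1",
    anchor_groups: set[str] | None = None,
    missing_policy: str = "drop",
    min_detect_fraction: float = 1.0,
    batch_median: str = "per-protein",
) -> AbundanceMatrix:
    """Full quantification chain: rollup -> standards -> batch -> filter."""
    sheet.validate(samples=table.samples())
    responses = rollup_table(table, missing_policy=missing_policy)
    normalized = normalize_to_standards(responses, spikein_id, reference_id)
    matrix = AbundanceMatrix(
        values=normalized,
        samples=sheet.data.loc[table.samples()],
        provenance=[
            f"rollup(geometric mean, missing={missing_policy})",
            f"standards(spikein={spikein_id}, reference={reference_id})",
        ],
    )
    matrix = batch_normalize(matrix, anchor_groups=anchor_groups, mode=batch_median)
    return filter_quantifiable(matrix, min_detect_fraction=min_detect_fraction)
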