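"""Relative qPCR quantification by the 2^-dCt method.

Expression of each target gene is computed relative to the geometric mean
of three reference genes.  Because Ct is a log2-scale quantity, the
geometric mean in expression space is the arithmetic mean in Ct space:

    dCt = Ct_target - mean(Ct_ref1, Ct_ref2, Ct_ref3)
    relative expression = 2^-dCt

No calibrator sample is used (2^-dCt, not 2^-ddCt): without longitudinal
data there is no baseline condition to calibrate against.  Amplification
efficiency is fixed at 2.0 per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["CtTable", "relative_expression", "expression_table"]


@dataclass
class CtTable:
    """Ct values (cycles), gene x sample, with a designated reference set."""

    data: pd.DataFrame  # index gene_id, columns sample_id
    reference_genes: tuple[str, ...]
    samples: pd.DataFrame | None = None  # optional: index sample_id, column group

    def validate(self) -> None:
        if len(self.reference_genes) < 3:
            raise SchemaError("need >= 3 reference genes")
        missing = [g for g in self.reference_genes if g not in self.data.index]
        if missing:
            raise SchemaError(f"reference gene(s) absent from Ct table: {missing}")
        refs = self.data.loc[list(self.reference_genes)]
        if refs.isna().any().any():
            bad = refs.columns[refs.isna().any()].tolist()
            raise SchemaError(f"reference Ct missing in sample(s): {bad}")


def relative_expression(ct_target: float, ct_refs: "list[float]") -> float:
    """2^-dCt for one target Ct against its sample's reference Cts."""
    ct_refs = list(ct_refs)
    if not np.isfinite(ct_target) or not np.all(np.isfinite(ct_refs)):
        raise ValueError(f"non-finite Ct value: target={ct_target}, refs={ct_refs}")
    dct = ct_target - float(np.mean(ct_refs))
    return float(2.0 ** (-dct))


def expression_table(ct: CtTable) -> pd.DataFrame:
    """Per-(gene, sample) relative expression; reference genes excluded.

    Strictly positive output; per-sample additive Ct shifts common to all
    genes (loading/efficiency artifacts) cancel in the dCt.
    """
    ct.validate()
    ref_mean = ct.data.loc[list(ct.reference_genes)].mean(axis=0)
    targets = ct.data.drop(index=list(ct.reference_genes))
    dct = targets.sub(ref_mean, axis=1)
    return 2.0 ** (-dct)
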