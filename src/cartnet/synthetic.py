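"""Synthetic peptide-level and Ct-level data with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external data:

* **Ground truth** — log2 protein abundance follows a single-latent-factor
  block model: proteins of the same functional pathway load on one shared
  standard-normal factor per (group, pathway, sample), giving an expected
  pairwise Pearson correlation equal to the configured ``block_rho``.
  Group mean shifts are added in log2 units.
* **Peptide areas** — truth x fixed per-peptide response factor x
  per-sample global scale x per-run batch factor x mean-1 lognormal noise,
  plus one BSA spike-in row per sample carrying the same sample/run factors.
* **Ct values** — Ct = baseline - log2(expression) + per-sample offset +
  noise, with three reference genes at expression 1 sharing the offset, so
  the 2^-dCt transform recovers the planted expression.

All randomness flows through explicit seeds; identical (config, seed)
yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .qpcr import CtTable
from .quant import PeptideTable, SampleSheet

__all__ = [
    "TrueAbundanceMatrix",
    "simulate_true_abundance",
    "simulate_peptide_table",
    "simulate_ct_table",
    "simulate_dataset",
]


@dataclass
class TrueAbundanceMatrix:
    """Ground-truth relative abundances (linear scale) with group labels."""

    values: pd.DataFrame  # index protein_id, columns sample_id; > 0
    samples: pd.DataFrame  # index sample_id; column group


def _rng(config: SimConfig, seed: int | None, stream: int) -> np.random.Generator:
    base = seed if seed is not None else config.seed
    if base is None:
        base = 0
    return np.random.default_rng([stream, int(base)])


def simulate_true_abundance(
    config: SimConfig, seed: int | None = None
) -> TrueAbundanceMatrix:
    """Draw a ground-truth protein x sample abundance matrix.

    log2 abundance of protein *i* in sample *s* of group *g* is

        baseline_i + effect_{g, path(i)} + lambda_{g, path(i)} * F_{g, path(i), s} + eps_{i,s}

    with ``F`` a shared standard-normal latent factor, ``eps`` iid
    ``N(0, residual_log2_sd^2)`` and ``lambda = residual_log2_sd *
    sqrt(rho / (1 - rho))`` so that two same-pathway proteins of group *g*
    have expected Pearson correlation ``rho = block_rho[g][path]``.
    The stable reference protein is appended with constant abundance.
    """
    config.validate()
    rng = _rng(config, seed, stream=1)
    proteins = config.protein_ids()
    samples = config.sample_ids()
    groups = config.sample_groups()
    annotation = config.annotation()
    sd = config.residual_log2_sd

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(proteins))
    log2 = pd.DataFrame(
        rng.normal(0.0, sd, (len(proteins), len(samples))),
        index=proteins,
        columns=samples,
    )
    log2 = log2.add(pd.Series(baseline, index=proteins), axis=0)

    for g in config.groups:
        cols = [s for s in samples if groups[s] == g]
        effects = config.group_log2_effects.get(g, {})
        rhos = config.block_rho.get(g, {})
        for pathway, _count in config.pathways:
            members = [p for p in proteins if annotation[p] == pathway]
            shift = effects.get(pathway, 0.0)
            if shift:
                log2.loc[members, cols] += shift
            rho = rhos.get(pathway, 0.0)
            factor = rng.normal(0.0, 1.0, len(cols))  # drawn even when rho == 0
            if rho > 0:
                lam = sd * math.sqrt(rho / (1.0 - rho))
                log2.loc[members, cols] += lam * factor[np.newaxis, :]

    values = 2.0 ** log2
    values.loc[config.reference_id] = 2.0 ** config.reference_log2_abundance
    sample_meta = pd.DataFrame({"group": [groups[s] for s in samples]}, index=samples)
    return TrueAbundanceMatrix(values=values, samples=sample_meta)


def _lognormal_noise(
    rng: np.random.Generator, cv: float, shape: tuple[int, ...]
) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV; 1 when cv=0."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, shape))


def simulate_peptide_table(
    truth: TrueAbundanceMatrix, config: SimConfig, seed: int | None = None
) -> tuple[PeptideTable, SampleSheet]:
    """Expand ground truth into a peptide-level peak-area table.

    area(peptide, sample) = truth(protein, sample) * response_factor(peptide)
    * 2^scale(sample) * 2^shift(run(sample)) * noise.  The spike-in row
    carries the sample scale and run shift but not the biology.
    """
    config.validate()
    samples = list(truth.values.columns)
    if set(samples) != set(config.sample_ids()):
        raise ValueError("truth matrix samples do not match config sample layout")
    rng = _rng(config, seed, stream=2)
    runs = config.resolve_batches()

    peptide_index: list[tuple[str, str]] = []
    for protein in truth.values.index:
        peptide_index.append((protein, f"{protein}_pep1"))
        peptide_index.append((protein, f"{protein}_pep2"))

    # Fixed per-peptide response factors, drawn once from the seed unless
    # supplied explicitly.
    if config.peptide_response_factors is not None:
        factors = np.array(
            [config.peptide_response_factors.get(pep, 1.0) for _, pep in peptide_index]
        )
    else:
        factors = 2.0 ** rng.normal(
            0.0, config.peptide_response_log2_sd, len(peptide_index)
        )

    sample_scale = 2.0 ** rng.normal(0.0, config.sample_scale_sd, len(samples))
    run_shift = np.array(
        [2.0 ** config.batch_log2_shift.get(runs[s], 0.0) for s in samples]
    )
    per_sample = sample_scale * run_shift

    truth_rows = truth.values.loc[[p for p, _ in peptide_index]].to_numpy()
    noise = _lognormal_noise(rng, config.peptide_cv, truth_rows.shape)
    areas = truth_rows * factors[:, None] * per_sample[None, :] * noise

    spike_noise = _lognormal_noise(rng, config.peptide_cv, (len(samples),))
    spike = config.spikein_amount * per_sample * spike_noise

    index = pd.MultiIndex.from_tuples(
        peptide_index + [(config.spikein_id, f"{config.spikein_id}_pep1")],
        names=["protein_id", "peptide_id"],
    )
    data = pd.DataFrame(
        np.vstack([areas, spike[None, :]]), index=index, columns=samples
    )
    table = PeptideTable(data=data, spikein_id=config.spikein_id)
    sheet = SampleSheet(
        data=pd.DataFrame(
            {
                "group": [config.sample_groups()[s] for s in samples],
                "run": [runs[s] for s in samples],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return table, sheet


def simulate_ct_table(config: SimConfig, seed: int | None = None) -> CtTable:
    """Generate a qPCR Ct table with planted relative expression.

    Ct(gene, sample) = baseline - log2(expression) + offset(sample) + noise;
    reference genes have expression 1 and share the per-sample offset, so
    relative quantification against their mean recovers the expression.
    """
    config.validate()
    rng = _rng(config, seed, stream=3)
    samples = config.sample_ids()
    groups = config.sample_groups()
    targets = list(config.ct_targets)
    refs = list(config.ct_reference_genes)

    offsets = rng.normal(0.0, config.ct_sample_offset_sd, len(samples))
    rows = {}
    for gene in targets + refs:
        per_group = config.ct_targets.get(gene, {})
        expr = np.array([per_group.get(groups[s], 1.0) for s in samples])
        noise = (
            rng.normal(0.0, config.ct_noise_sd, len(samples))
            if config.ct_noise_sd > 0
            else np.zeros(len(samples))
        )
        rows[gene] = config.ct_baseline - np.log2(expr) + offsets + noise
    data = pd.DataFrame(rows, index=samples).T
    data.index.name = "gene_id"
    sample_meta = pd.DataFrame({"group": [groups[s] for s in samples]}, index=samples)
    return CtTable(data=data, reference_genes=tuple(refs), samples=sample_meta)


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> dict[str, object]:
    """Convenience bundle: truth, peptide table, sample sheet, annotation, Ct."""
    truth = simulate_true_abundance(config, seed=seed)
    table, sheet = simulate_peptide_table(truth, config, seed=seed)
    ct = simulate_ct_table(config, seed=seed)
    return {
        "truth": truth,
        "peptide_table": table,
        "sample_sheet": sheet,
        "annotation": config.annotation(),
        "ct_table": ct,
    }
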