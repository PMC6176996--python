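"""Study-design configuration for the synthetic-data generator.

The defaults encode the design of a three-diet mouse cartilage study:
3 diet groups (LFLS, LFHS, HFLS) x 8 biological replicates, ~100 proteins
spread over six functional categories, two tryptic peptides per protein,
one BSA spike-in standard per sample, a stable endogenous reference
protein (MDH1), and samples split across two mass-spectrometry runs with
group overlap between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError

#: Default functional categories and member counts (totalling 100 proteins).
DEFAULT_PATHWAYS: tuple[tuple[str, int], ...] = (
    ("glycolysis", 16),
    ("beta_oxidation", 18),
    ("tca_cycle", 16),
    ("etc", 20),
    ("antioxidant", 14),
    ("proteostasis", 16),
)

#: Short prefixes used to build protein identifiers per category.
_PATHWAY_PREFIX = {
    "glycolysis": "GLY",
    "beta_oxidation": "BOX",
    "tca_cycle": "TCA",
    "etc": "ETC",
    "antioxidant": "AOX",
    "proteostasis": "PRO",
}

DEFAULT_GROUPS: tuple[str, ...] = ("LFLS", "LFHS", "HFLS")

# Within-pathway latent-factor correlation per diet group.  The high-sucrose
# network is the densest and the high-fat network the sparsest, with fatty
# acid (beta-oxidation) co-regulation relatively strongest under high fat.
DEFAULT_BLOCK_RHO: dict[str, dict[str, float]] = {
    "LFLS": {p: 0.50 for p, _ in DEFAULT_PATHWAYS},
    "LFHS": {p: 0.65 for p, _ in DEFAULT_PATHWAYS},
    "HFLS": {**{p: 0.30 for p, _ in DEFAULT_PATHWAYS}, "beta_oxidation": 0.60},
}

# Mean log2 abundance shifts per (group, pathway) relative to the LFLS
# baseline: high sucrose lowers antioxidant/glycolysis/TCA enzymes, high
# fat raises beta-oxidation enzymes.
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    "LFLS": {},
    "LFHS": {"glycolysis": -0.5, "tca_cycle": -0.4, "antioxidant": -0.8},
    "HFLS": {"beta_oxidation": 0.8, "antioxidant": -0.3},
}

#: qPCR panel: target genes with planted relative expression per group.
DEFAULT_CT_TARGETS: dict[str, dict[str, float]] = {
    "Acan": {}, "Col2a1": {}, "Adamts5": {}, "Mmp13": {},
    "Prkaa1": {"LFLS": 1.5}, "Sirt1": {"LFLS": 1.5},
    "Foxo3": {"LFLS": 2.0}, "Ddit3": {"LFLS": 2.5},
    "Ptgs2": {}, "Epas1": {}, "Xbp1": {},
    "Hsp90aa1": {"LFLS": 1.8}, "Hspe1": {"LFLS": 1.8},
    "Clpp": {"LFLS": 1.6}, "Lonp1": {"LFLS": 1.4},
    "Hif1a": {}, "Bcl2": {}, "Mtif2": {"LFLS": 1.4},
    "Acaca": {}, "Cpt1a": {"HFLS": 2.0},
}

DEFAULT_CT_REFERENCES: tuple[str, str, str] = ("B2m", "Gapdh", "Actb")


@dataclass
class SimConfig:
    """Parameters of the synthetic peptide-level and Ct-level generators.

    Parameters
    ----------
    groups
        Diet group labels.
    n_replicates_per_group
        Biological replicates per group (>= 3 so correlation p-values have
        at least one degree of freedom).
    pathways
        ``(name, protein_count)`` pairs defining the functional categories.
    block_rho
        ``group -> pathway -> rho`` with ``rho in [0, 1)``: the expected
        pairwise Pearson correlation of the log-abundances of two proteins
        in the same pathway for samples of that group.
    group_log2_effects
        ``group -> pathway -> shift``: mean log2-abundance shift applied to
        every protein of the pathway in that group.
    residual_log2_sd
        SD of the independent per-(protein, sample) log2 residual.
    peptide_cv
        Coefficient of variation of the multiplicative (lognormal)
        peptide-level measurement noise.
    peptide_response_factors
        Optional explicit ``peptide_id -> multiplier``; if None, per-peptide
        response factors are drawn once (lognormally) from the seed.
    peptide_response_log2_sd
        SD (log2) of the drawn response factors when not given explicitly.
    spikein_amount
        Nominal spike-in quantity added to every sample.
    sample_scale_sd
        SD (log2) of the per-sample global scale factor (loading/injection).
    batch_assignment
        Optional explicit ``sample_id -> run``; if None, a two-run design
        with group overlap is built (first group entirely in run2, the
        others split across both runs, mirroring a 3+5 / 8+5+3 layout).
    batch_log2_shift
        ``run -> shift``: multiplicative (log2) per-run offset.
    seed
        Default RNG seed used when an operation's ``seed`` argument is None.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates_per_group: int = 8
    pathways: tuple[tuple[str, int], ...] = DEFAULT_PATHWAYS
    block_rho: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BLOCK_RHO.items()}
    )
    group_log2_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_EFFECTS.items()}
    )
    residual_log2_sd: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    peptide_cv: float = 0.15
    peptide_response_factors: Mapping[str, float] | None = None
    peptide_response_log2_sd: float = 1.0
    spikein_amount: float = 8.0
    spikein_id: str = "BSA"
    reference_id: str = "MDH1"
    reference_log2_abundance: float = 5.0
    sample_scale_sd: float = 0.25
    batch_assignment: Mapping[str, str] | None = None
    batch_log2_shift: Mapping[str, float] = field(
        default_factory=lambda: {"run1": 0.5, "run2": 0.0}
    )
    ct_targets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CT_TARGETS.items()}
    )
    ct_reference_genes: Sequence[str] = DEFAULT_CT_REFERENCES
    ct_baseline: float = 20.0
    ct_noise_sd: float = 0.2
    ct_sample_offset_sd: float = 0.5
    seed: int | None = None

    # -- derived layout -------------------------------------------------

    def sample_ids(self) -> list[str]:
        """Sample identifiers, grouped: ``<group>_<replicate>``."""
        return [
            f"{g}_{i:02d}"
            for g in self.groups
            for i in range(1, self.n_replicates_per_group + 1)
        ]

    def sample_groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids()}

    def protein_ids(self) -> list[str]:
        """Protein identifiers per pathway (reference protein excluded)."""
        out: list[str] = []
        for name, count in self.pathways:
            prefix = _PATHWAY_PREFIX.get(name, name[:3].upper())
            out.extend(f"{prefix}{i:02d}" for i in range(1, count + 1))
        return out

    def annotation(self) -> dict[str, str]:
        """``protein_id -> pathway`` map, including the reference protein."""
        out: dict[str, str] = {}
        for name, count in self.pathways:
            prefix = _PATHWAY_PREFIX.get(name, name[:3].upper())
            for i in range(1, count + 1):
                out[f"{prefix}{i:02d}"] = name
        out[self.reference_id] = "reference"
        return out

    def resolve_batches(self) -> dict[str, str]:
        """Sample -> run map; builds the default overlapping design if unset."""
        if self.batch_assignment is not None:
            return dict(self.batch_assignment)
        n = self.n_replicates_per_group
        runs: dict[str, str] = {}
        for j, g in enumerate(self.groups):
            ids = [f"{g}_{i:02d}" for i in range(1, n + 1)]
            if j == 0:
                n_run1 = 0  # first group measured entirely in run2
            elif j == 1:
                n_run1 = max(1, round(n * 3 / 8))
            else:
                n_run1 = max(1, round(n * 5 / 8))
            for k, s in enumerate(ids):
                runs[s] = "run1" if k < n_run1 else "run2"
        return runs

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        if self.n_replicates_per_group < 3:
            raise ConfigurationError(
                "n_replicates_per_group: need >= 3 replicates per group "
                f"(got {self.n_replicates_per_group}); correlation p-values "
                "require n - 2 >= 1"
            )
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("groups: duplicate group labels")
        if not self.pathways:
            raise ConfigurationError("pathways: at least one pathway required")
        for name, count in self.pathways:
            if count < 1:
                raise ConfigurationError(f"pathways: pathway {name!r} has count {count}")
        pathway_names = {name for name, _ in self.pathways}
        for g, per_path in self.block_rho.items():
            if g not in self.groups:
                raise ConfigurationError(f"block_rho: unknown group {g!r}")
            for p, rho in per_path.items():
                if p not in pathway_names:
                    raise ConfigurationError(f"block_rho: unknown pathway {p!r}")
                if not (0.0 <= rho < 1.0):
                    raise ConfigurationError(
                        f"block_rho: rho for ({g}, {p}) must be in [0, 1), got {rho}"
                    )
        for g in self.group_log2_effects:
            if g not in self.groups:
                raise ConfigurationError(f"group_log2_effects: unknown group {g!r}")
        if self.peptide_cv < 0:
            raise ConfigurationError(f"peptide_cv: must be >= 0, got {self.peptide_cv}")
        if self.sample_scale_sd < 0:
            raise ConfigurationError("sample_scale_sd: must be >= 0")
        if self.residual_log2_sd <= 0:
            raise ConfigurationError("residual_log2_sd: must be > 0")
        if self.spikein_amount <= 0:
            raise ConfigurationError("spikein_amount: must be > 0")
        if len(self.ct_reference_genes) < 3:
            raise ConfigurationError("ct_reference_genes: need >= 3 reference genes")
        runs = self.resolve_batches()
        samples = set(self.sample_ids())
        if set(runs) != samples:
            raise ConfigurationError("batch_assignment: must cover exactly all samples")
        by_run: dict[str, set[str]] = {}
        grp = self.sample_groups()
        for s, r in runs.items():
            by_run.setdefault(r, set()).add(grp[s])
        if len(by_run) > 1 and not set.intersection(*by_run.values()):
            raise ConfigurationError(
                "batch_assignment: no group is present in every run; batch "
                "anchoring requires group overlap between runs"
            )
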