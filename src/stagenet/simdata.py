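"""Synthetic staged-transcriptome generator with known ground truth.

Emulates the study design this package targets: single oocytes/embryos over 8
developmental stages with 2 biological replicates each (16 samples), roughly
half of all genes detected per stage, planted co-expressed gene modules whose
shared profiles peak at single stages, and the four archetypal expression
dynamics of early development (maternal decay, genome-activation increase,
transient, constant).  Counts carry negative-binomial noise; an FPKM-like
matrix is derived by library-size scaling with unit gene lengths.

The signal model per gene g and sample s (stage t):

    log2 mu_gs = log2(background_mean) + baseline_g
                 + amplitude * archetype(t)
                 + sigma * (loading * z_s + sqrt(1 - loading^2) * e_gs)

where z_s is a per-sample latent factor shared by all members of a module
(this is what makes ``loading`` tune within-module correlation) and e_gs is
private noise.  Counts ~ NB(mean = lib_s * mu_gs, dispersion), with
Var = mu + dispersion * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .iohub import DEFAULT_STAGES, ExpressionMatrix, OrthologMap, StageDesign

ARCHETYPES = ("increasing", "decreasing", "transient", "constant", "stage_peak")


class ConfigurationError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedModule:
    """A co-expressed gene set planted into the simulation.

    ``archetype`` is one of :data:`ARCHETYPES`; for ``stage_peak`` the
    ``peak_stage`` index selects the stage where the shared profile is high.
    ``loading`` in [0, 1] tunes within-module correlation strength;
    ``amplitude`` is the archetype effect size in log2 units.
    """

    module_id: str
    size: int
    archetype: str = "stage_peak"
    peak_stage: int = 0
    loading: float = 0.8
    amplitude: float = 4.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if not 0.0 <= self.loading <= 1.0:
            raise ConfigurationError("loading must be in [0, 1]")
        if self.size < 3:
            raise ConfigurationError("module size must be >= 3")

    def profile(self, n_stages: int) -> np.ndarray:
        """Archetype profile over stages, values in [0, 1]."""
        t = np.linspace(0.0, 1.0, n_stages)
        if self.archetype == "increasing":
            return t
        if self.archetype == "decreasing":
            return 1.0 - t
        if self.archetype == "transient":
            return 1.0 - np.abs(2.0 * t - 1.0)
        if self.archetype == "constant":
            return np.ones(n_stages)
        # stage_peak
        if not 0 <= self.peak_stage < n_stages:
            raise ConfigurationError(
                f"peak_stage {self.peak_stage} outside 0..{n_stages - 1}"
            )
        prof = np.zeros(n_stages)
        prof[self.peak_stage] = 1.0
        return prof


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic staged-transcriptome dataset."""

    n_stages: int = 8
    n_replicates: int = 2
    n_genes: int = 2000
    modules: tuple[PlantedModule, ...] = ()
    dispersion: float = 0.1
    library_sizes: tuple[float, ...] | None = None
    background_mean: float = 50.0
    detect_fraction: float = 0.5
    baseline_sd: float = 1.0
    signal_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ConfigurationError("n_stages must be >= 2")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.background_mean <= 0:
            raise ConfigurationError("background_mean must be > 0")
        if not 0.0 <= self.detect_fraction <= 1.0:
            raise ConfigurationError("detect_fraction must be in [0, 1]")
        planted = sum(m.size for m in self.modules)
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted module sizes ({planted}) exceed n_genes ({self.n_genes})"
            )
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate module_id in config")
        if self.library_sizes is not None:
            if len(self.library_sizes) != self.n_samples:
                raise ConfigurationError(
                    "library_sizes must have one entry per sample"
                )
            if any(s <= 0 for s in self.library_sizes):
                raise ConfigurationError("library_sizes must all be > 0")

    @property
    def n_samples(self) -> int:
        return self.n_stages * self.n_replicates

    @property
    def stage_labels(self) -> tuple[str, ...]:
        if self.n_stages == len(DEFAULT_STAGES):
            return DEFAULT_STAGES
        return tuple(f"stage{i + 1}" for i in range(self.n_stages))

    def design(self) -> StageDesign:
        return StageDesign.balanced(self.stage_labels, self.n_replicates)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset: gene -> module assignment,
    per-module archetype profile over stages, and the config/seed used."""

    assignments: pd.Series  # gene_id -> module_id or "background"
    archetypes: dict[str, np.ndarray] = field(default_factory=dict)
    config: SimConfig | None = None
    seed: int = 0
    preserved: dict[str, bool] = field(default_factory=dict)

    def module_genes(self, module_id: str) -> list[str]:
        return list(self.assignments.index[self.assignments == module_id])

    @property
    def module_ids(self) -> list[str]:
        return [m for m in self.assignments.unique() if m != "background"]


def default_config(seed: int = 0, n_genes: int = 2000,
                   module_size: int | None = None,
                   loading: float = 0.8) -> SimConfig:
    """The package's reference study conditions: 8 stages x 2 replicates and
    five planted modules peaking at distinct single stages.

    ``module_size`` defaults to 5% of the gene count (100 genes at the
    reference 2,000-gene scale).
    """
    peaks = (0, 2, 3, 5, 7)
    if module_size is None:
        module_size = max(5, n_genes // 20)
    modules = tuple(
        PlantedModule(
            module_id=f"planted{i + 1}",
            size=module_size,
            archetype="stage_peak",
            peak_stage=p,
            loading=loading,
            amplitude=4.0,
        )
        for i, p in enumerate(peaks)
    )
    return SimConfig(n_genes=n_genes, modules=modules, seed=seed)


def _simulate_log_means(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.Series, dict[str, np.ndarray]]:
    """Per-gene per-sample log2 mean matrix plus truth bookkeeping."""
    n_genes, n_samples = config.n_genes, config.n_samples
    stage_of_sample = np.repeat(np.arange(config.n_stages), config.n_replicates)

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    assignment = pd.Series("background", index=pd.Index(gene_ids, name="gene_id"))
    archetypes: dict[str, np.ndarray] = {}

    baseline = rng.normal(0.0, config.baseline_sd, size=n_genes)
    log_mu = np.tile(np.log2(config.background_mean) + baseline[:, None], (1, n_samples))

    pos = 0
    for mod in config.modules:
        members = slice(pos, pos + mod.size)
        assignment.iloc[members] = mod.module_id
        prof = mod.profile(config.n_stages)
        archetypes[mod.module_id] = prof
        z = rng.normal(0.0, 1.0, size=n_samples)  # shared latent factor
        e = rng.normal(0.0, 1.0, size=(mod.size, n_samples))  # private noise
        shared = mod.loading * z[None, :] + np.sqrt(1.0 - mod.loading**2) * e
        log_mu[members] += (
            mod.amplitude * prof[stage_of_sample][None, :]
            + config.signal_sd * shared
        )
        pos += mod.size

    # Detection masking: a fixed fraction of background genes is silent in
    # every stage (staged series re-detect mostly the same genes stage after
    # stage), calibrated so the expected detected fraction per stage matches
    # detect_fraction; planted genes are always expressed.
    n_planted = pos
    n_background = n_genes - n_planted
    if n_background > 0:
        e_bg = rng.normal(0.0, 1.0, size=(n_background, n_samples))
        log_mu[n_planted:] += config.signal_sd * e_bg
        if config.detect_fraction < 1.0:
            target = config.detect_fraction * n_genes - n_planted
            p_on = float(np.clip(target / n_background, 0.0, 1.0))
            silent = rng.random(n_background) >= p_on
            log_mu[n_planted:][silent] = np.log2(1e-3)  # below detection

    return log_mu, assignment, archetypes


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate one staged dataset.

    Returns the integer count matrix, the matching FPKM-like matrix
    (counts / library size, unit gene lengths) and the ground truth.
    Identical config (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    log_mu, assignment, archetypes = _simulate_log_means(config, rng)

    lib = (
        np.asarray(config.library_sizes, dtype=float)
        if config.library_sizes is not None
        else np.ones(config.n_samples)
    )
    mu = np.exp2(log_mu) * lib[None, :]

    # NB parameterization: Var = mu + dispersion * mu^2
    n_param = 1.0 / config.dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))

    design = config.design()
    sample_ids = design.sample_ids
    counts_df = pd.DataFrame(counts, index=assignment.index, columns=sample_ids)
    fpkm_df = counts_df / lib[None, :]

    truth = SyntheticTruth(
        assignments=assignment,
        archetypes=archetypes,
        config=config,
        seed=config.seed,
    )
    return (
        ExpressionMatrix(counts_df, kind="counts"),
        ExpressionMatrix(fpkm_df.astype(float), kind="fpkm"),
        truth,
    )


def simulate_sister_species(
    counts: ExpressionMatrix,
    truth: SyntheticTruth,
    preserve_fraction: float,
    seed: int,
    species_a: str = "speciesA",
    species_b: str = "speciesB",
) -> tuple[ExpressionMatrix, OrthologMap, SyntheticTruth]:
    """Simulate a sister-species dataset with a controlled fraction of the
    planted modules preserved.

    Preserved modules are regenerated with the same archetype/loading (fresh
    noise); the rest are regenerated with loading and amplitude zero, so the
    genes carrying those labels are plain background — their co-expression
    structure is destroyed.  Gene IDs are renamed and a complete one-group-
    per-gene ortholog map is returned.
    """
    if not 0.0 <= preserve_fraction <= 1.0:
        raise ConfigurationError("preserve_fraction must be in [0, 1]")
    if truth.config is None:
        raise ConfigurationError("truth must carry its SimConfig")
    if list(truth.assignments.index) != counts.gene_ids:
        raise ConfigurationError("truth does not match the count matrix gene set")

    rng = np.random.default_rng(seed)
    module_ids = [m.module_id for m in truth.config.modules]
    n_preserve = int(round(preserve_fraction * len(module_ids)))
    order = rng.permutation(len(module_ids))
    preserved_set = {module_ids[i] for i in order[:n_preserve]}

    sister_modules = tuple(
        m if m.module_id in preserved_set else replace(m, loading=0.0, amplitude=0.0)
        for m in truth.config.modules
    )
    sister_seed = int(rng.integers(0, 2**31 - 1))
    sister_config = replace(truth.config, modules=sister_modules, seed=sister_seed)
    sister_counts, _sister_fpkm, sister_truth = simulate_dataset(sister_config)

    rename = {g: f"{species_b}_{g}" for g in sister_counts.gene_ids}
    renamed = sister_counts.values.rename(index=rename)
    sister_counts = ExpressionMatrix(renamed, kind="counts")
    sister_truth.assignments.index = pd.Index(
        [rename[g] for g in sister_truth.assignments.index], name="gene_id"
    )
    sister_truth.preserved = {m: (m in preserved_set) for m in module_ids}

    records = []
    for i, gene in enumerate(counts.gene_ids):
        grp = f"HG{i + 1:06d}"
        records.append((grp, species_a, gene))
        records.append((grp, species_b, f"{species_b}_{gene}"))
    omap = OrthologMap(
        pd.DataFrame(records, columns=["group_id", "species", "gene_id"])
    )
    return sister_counts, omap, sister_truth
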