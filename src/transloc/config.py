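"""Simulation and pipeline configuration.

Every analysis threshold used by the pipeline is a named key with a
default matching the study design this package models (MAF 0.05, 33%
missingness, max observed heterozygosity 0.6, LD r2 < 0.2 in 1 Mb
windows, |z| > 2.5 outlier loadings, 0.3 batch-loading cutoff, FDR 0.05,
3000 bp annotation flank, 3 PCs per data block, 1000/10000 permutations,
k = 10 imputation neighbours, rarefaction to g = 8 individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["PopulationSpec", "IsotopeNiche", "SimulationConfig", "AnalysisParams",
           "load_config", "save_config", "default_simulation_config"]


@dataclass
class PopulationSpec:
    """One population in a translocation system.

    ``role`` is "source" or "refuge".  Refuge populations are founded by a
    bottleneck of ``n_families`` founder families (modelled as two parents
    each), then drift for ``generations_since_founding`` Wright-Fisher
    generations at ``effective_size`` diploids.
    """

    name: str
    role: str = "refuge"
    n_families: int = 10
    n_released: int = 1000
    generations_since_founding: int = 3
    effective_size: int = 100
    n_sampled: int = 20
    age_class: str = "young"  # "young" (7-9 y) or "old" (~30 y) cohort label

    def __post_init__(self) -> None:
        if self.role not in ("source", "refuge"):
            raise ValueError(f"role must be source/refuge, got {self.role!r}")
        for attr in ("n_families", "n_released", "effective_size", "n_sampled"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        if self.generations_since_founding < 0:
            raise ValueError("generations_since_founding must be >= 0")


@dataclass
class IsotopeNiche:
    """Per-population bivariate (d13C, d15N) niche: means and SDs in per-mil."""

    mean_d13c: float = -28.0
    mean_d15n: float = 10.0
    sd_d13c: float = 1.0
    sd_d15n: float = 0.8


@dataclass
class SimulationConfig:
    """Full specification of a synthetic translocation study.

    Defaults emulate the study design this package targets: two lake
    systems, one source plus two refuge populations each, founder
    bottlenecks of differing size/age, thousands of SNPs and a large
    epiRAD count table with library batch effects.
    """

    seed: int = 0
    systems: dict[str, list[PopulationSpec]] = field(default_factory=dict)
    n_snps: int = 3000
    n_count_loci: int = 20000
    n_selected_snps: int = 20
    selection_shift: float = 0.03
    n_planted_dm: int = 100
    dm_log2fc: float = 2.0
    batch_frac: float = 0.02
    n_batches: int = 3
    batch_log2fc: float = 1.0
    nb_dispersion: float = 0.2
    count_mean: float = 80.0
    morph_variance_fractions: tuple[float, float, float] = (0.2, 0.2, 0.6)
    isotope_niche: dict[str, IsotopeNiche] = field(default_factory=dict)
    isotope_n_per_pop: int = 10
    muscle_stomach_slope: float = 0.8
    muscle_stomach_noise_sd: float = 0.3
    afs_alpha: float = 0.8
    afs_beta: float = 0.8
    n_chromosomes: int = 40

    def __post_init__(self) -> None:
        fr = np.asarray(self.morph_variance_fractions, dtype=float)
        if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("morph_variance_fractions must be 3 non-negative values summing to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for attr in ("n_snps", "n_count_loci"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        if not 0 <= self.batch_frac <= 1:
            raise ValueError("batch_frac must be in [0, 1]")

    @property
    def populations(self) -> list[PopulationSpec]:
        return [p for specs in self.systems.values() for p in specs]


@dataclass
class AnalysisParams:
    """Pipeline thresholds; defaults are the study's values."""

    maf: float = 0.05
    max_missing_global: float = 0.33
    max_missing_per_pop: float = 0.33
    max_obs_het: float = 0.6
    max_ind_missing: float = 0.30
    hwe_alpha: float = 0.001
    hwe_pop_fraction: float = 0.5
    ld_r2_max: float = 0.2
    ld_window_bp: int = 1_000_000
    knn_k: int = 10
    rarefaction_g: int = 8
    outlier_z: float = 2.5
    batch_loading_threshold: float = 0.3
    dm_fdr: float = 0.05
    min_nonzero_frac: float = 0.33
    annotation_flank: int = 3000
    n_pcs: int = 3
    n_perm_rda: int = 1000
    n_perm_morpho: int = 1000
    n_perm_fst: int = 10_000


def default_simulation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Two-system study mirroring the modelled translocation design.

    System A ("Lomond-like"): one source, two old small-founder refuges and
    two young larger-founder refuges.  System B ("Eck-like"): one source
    and two young refuges with the largest founder groups.
    """

    systems = {
        "A": [
            PopulationSpec("A_source", "source", n_sampled=30),
            PopulationSpec("A_old1", "refuge", n_families=5, generations_since_founding=10,
                           effective_size=80, n_sampled=18, age_class="old"),
            PopulationSpec("A_old2", "refuge", n_families=6, generations_since_founding=10,
                           effective_size=80, n_sampled=18, age_class="old"),
            PopulationSpec("A_young1", "refuge", n_families=15, generations_since_founding=3,
                           effective_size=120, n_sampled=12, age_class="young"),
            PopulationSpec("A_young2", "refuge", n_families=18, generations_since_founding=3,
                           effective_size=120, n_sampled=15, age_class="young"),
        ],
        "B": [
            PopulationSpec("B_source", "source", n_sampled=30),
            PopulationSpec("B_young1", "refuge", n_families=30, generations_since_founding=3,
                           effective_size=150, n_sampled=20, age_class="young"),
            PopulationSpec("B_young2", "refuge", n_families=25, generations_since_founding=3,
                           effective_size=150, n_sampled=20, age_class="young"),
        ],
    }
    niches = {}
    for sysname, specs in systems.items():
        for i, p in enumerate(specs):
            wide = 1.0 if p.role == "source" else 1.8  # refuge niches wider (ecological release)
            niches[p.name] = IsotopeNiche(
                mean_d13c=-28.0 + 1.5 * i + (0.0 if sysname == "A" else 1.0),
                mean_d15n=11.0 - 0.8 * i,
                sd_d13c=0.8 * wide, sd_d15n=0.6 * wide,
            )
    cfg = SimulationConfig(seed=seed, systems=systems, isotope_niche=niches, **overrides)
    return cfg


def save_config(cfg: SimulationConfig, path) -> None:
    data = asdict(cfg)
    data["systems"] = {k: [asdict(p) for p in v] for k, v in cfg.systems.items()}
    data["isotope_niche"] = {k: asdict(v) for k, v in cfg.isotope_niche.items()}
    data["morph_variance_fractions"] = list(cfg.morph_variance_fractions)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["systems"] = {k: [PopulationSpec(**p) for p in v]
                       for k, v in data.get("systems", {}).items()}
    data["isotope_niche"] = {k: IsotopeNiche(**v)
                             for k, v in data.get("isotope_niche", {}).items()}
    data["morph_variance_fractions"] = tuple(data["morph_variance_fractions"])
    return SimulationConfig(**data)
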