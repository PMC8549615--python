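"""Synthetic translocation-study generator with known ground truth.

The generator emulates the structure of a conservation-translocation
study on lake fish: two translocation systems, each with one wild source
population and several refuge populations founded from it by small
founder groups (families) that subsequently drift for a handful of
Wright-Fisher generations.  For every individual it produces

* biallelic SNP genotypes (with optional planted selected loci whose
  allele frequencies shift deterministically each generation),
* methylation-sensitive RAD (epiRAD) locus read counts, negative-
  binomially distributed with planted differentially methylated loci and
  library batch effects,
* 14-landmark body-shape configurations carrying planted genomic and
  epigenomic variance fractions plus allometry,
* stable-isotope values (d13C, d15N) for muscle and stomach tissue, with
  refuge niches wider than source niches,

together with a :class:`SyntheticTruth` record of everything planted, so
each downstream analysis stage can be checked against ground truth.

Simplifications relative to real data: loci are unlinked, there is no
mutation or migration, families are not tracked past the founder draw,
and selection is a deterministic per-generation frequency shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PopulationSpec, SimulationConfig
from .containers import CountMatrix, GenotypeMatrix, MISSING
from .morphometrics import LandmarkConfiguration, centroid_size
from .utils import as_rng, child_rng

__all__ = [
    "SyntheticTruth", "FISH_TEMPLATE",
    "simulate_source_pool", "simulate_translocation", "simulate_epicounts",
    "simulate_morphology", "simulate_isotopes", "simulate_study",
]

# Fixed stream offsets per component so any piece can be regenerated alone.
_STREAM_MAP, _STREAM_GENO, _STREAM_COUNTS, _STREAM_MORPH, _STREAM_ISO, _STREAM_MISS = range(6)

# 14-landmark fish body template (snout, head, dorsal/adipose/caudal fin
# bases, peduncle, anal/pelvic/pectoral fins, lower jaw), unit body length.
FISH_TEMPLATE = np.array([
    [0.00, 0.00], [0.15, 0.08], [0.35, 0.12], [0.50, 0.11], [0.70, 0.08],
    [0.85, 0.04], [0.95, 0.02], [0.95, -0.02], [0.85, -0.04], [0.72, -0.07],
    [0.62, -0.09], [0.45, -0.10], [0.22, -0.08], [0.05, -0.04],
])


@dataclass
class SyntheticTruth:
    """Hidden parameters of a simulated study, for recovery tests."""

    seed: int
    source_allele_freqs: dict[str, np.ndarray]
    refuge_allele_freqs: dict[str, np.ndarray]
    selected_snp_ids: np.ndarray
    selection_signs: np.ndarray
    planted_dm_locus_ids: np.ndarray
    dm_signs: np.ndarray
    batch_locus_ids: np.ndarray
    gen_scores: np.ndarray
    epi_scores: np.ndarray
    morph_variance_fractions: tuple[float, float, float]
    founder_families: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_source_pool(n_snps: int, afs_alpha: float = 0.8, afs_beta: float = 0.8,
                         seed=None) -> np.ndarray:
    """I.i.d. Beta(alpha, beta) allele frequencies for a wild source pool."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if afs_alpha <= 0 or afs_beta <= 0:
        raise ValueError("Beta parameters must be > 0")
    rng = as_rng(seed)
    return rng.beta(afs_alpha, afs_beta, size=n_snps)


def sample_genotypes(freqs: np.ndarray, n: int, seed=None) -> np.ndarray:
    """Hardy-Weinberg diploid genotypes (alt dosage) from allele frequencies."""
    rng = as_rng(seed)
    return rng.binomial(2, np.clip(freqs, 0, 1)[None, :], size=(n, freqs.size)).astype(np.int8)


def simulate_translocation(
    source_freqs: np.ndarray,
    pop_spec: PopulationSpec,
    seed=None,
    selected_idx: np.ndarray | None = None,
    selection_shift: float = 0.0,
    selection_signs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Found a refuge population and drift it; return (freqs, genotypes).

    Founders are 2 x n_families parental diploids drawn binomially from
    the source frequencies; each later generation resamples 2 x Ne gene
    copies (Wright-Fisher).  Selected loci get a deterministic frequency
    shift of ``selection_signs * selection_shift`` per generation, clipped
    to [0, 1]; fixed loci (p in {0, 1}) are absorbing, as there is no
    mutation.  Sampled genotypes are Hardy-Weinberg draws from the final
    frequencies.
    """
    rng = as_rng(seed)
    p = np.asarray(source_freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("source frequencies must be in [0, 1]")
    n_founder_copies = 2 * (2 * pop_spec.n_families)
    p = rng.binomial(n_founder_copies, p) / n_founder_copies

    shift = np.zeros_like(p)
    if selected_idx is not None and selection_shift != 0.0:
        signs = np.ones(len(selected_idx)) if selection_signs is None else np.asarray(selection_signs)
        shift[np.asarray(selected_idx)] = signs * selection_shift

    copies = 2 * pop_spec.effective_size
    for _ in range(pop_spec.generations_since_founding):
        p = rng.binomial(copies, p) / copies
        segregating = (p > 0) & (p < 1)
        p = np.where(segregating, np.clip(p + shift, 0.0, 1.0), p)

    genotypes = sample_genotypes(p, pop_spec.n_sampled, rng)
    return p, genotypes


# ---------------------------------------------------------------------------
# epiRAD counts
# ---------------------------------------------------------------------------


def simulate_epicounts(
    samples: pd.DataFrame,
    n_count_loci: int,
    *,
    mean: float = 80.0,
    dispersion: float = 0.2,
    locus_means: np.ndarray | None = None,
    dm_locus_idx: np.ndarray | None = None,
    dm_log2fc: float = 2.0,
    dm_signs: np.ndarray | None = None,
    batch_locus_idx: np.ndarray | None = None,
    batch_log2fc: float = 1.0,
    lib_size_factors: np.ndarray | None = None,
    loci: pd.DataFrame | None = None,
    seed=None,
) -> CountMatrix:
    """Negative-binomial epiRAD read counts.

    count[i, l] ~ NB(mean = s_i * mu_l * 2^(beta_l * refuge_i) * b_{l, batch(i)},
    dispersion phi) where ``beta_l`` is ``+/- dm_log2fc`` at planted DM
    loci (signs alternate unless given) and batch loci get a
    2^batch_log2fc multiplier in the last batch level.  epiRAD semantics:
    a methylated cut site yields fewer reads, so a negative count
    log2-fold-change in refuge reads as a methylation gain.
    """
    rng = as_rng(seed)
    n = len(samples)
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if locus_means is None:
        locus_means = mean * rng.lognormal(0.0, 0.7, size=n_count_loci)
    if np.any(locus_means <= 0):
        raise ValueError("locus means must be > 0")
    s = np.ones(n) if lib_size_factors is None else np.asarray(lib_size_factors, float)
    if np.any(s <= 0):
        raise ValueError("library-size factors must be > 0")

    beta = np.zeros(n_count_loci)
    if dm_locus_idx is not None:
        dm_locus_idx = np.asarray(dm_locus_idx)
        if dm_signs is None:
            dm_signs = np.where(np.arange(dm_locus_idx.size) % 2 == 0, -1.0, 1.0)
        beta[dm_locus_idx] = np.asarray(dm_signs) * dm_log2fc

    refuge = (samples["type"].to_numpy() == "refuge").astype(float) \
        if "type" in samples else np.zeros(n)

    mu = s[:, None] * locus_means[None, :] * np.exp2(beta[None, :] * refuge[:, None])

    if batch_locus_idx is not None and "batch" in samples and len(batch_locus_idx):
        batches = samples["batch"].to_numpy()
        levels = np.unique(batches)
        if len(levels) > 1:
            affected = batches == levels[-1]
            mu[np.ix_(affected, np.asarray(batch_locus_idx))] *= 2.0 ** batch_log2fc

    if dispersion < 1e-7:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(1.0 / dispersion, dispersion * mu)
        counts = rng.poisson(lam)

    if loci is None:
        loci = pd.DataFrame({
            "locus_id": [f"epi{l}" for l in range(n_count_loci)],
            "chrom": [f"chr{(l % 40) + 1}" for l in range(n_count_loci)],
            "start": np.arange(n_count_loci) * 200,
            "end": np.arange(n_count_loci) * 200 + 120,
        })
    return CountMatrix(counts.astype(np.int64), samples.copy(), loci)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def _shape_basis(template: np.ndarray, n_dirs: int, rng) -> np.ndarray:
    """Orthonormal deformation directions orthogonal to similarity space.

    Directions are orthogonalized against translation (x, y), scaling and
    rotation of the template so the planted signal survives Procrustes
    superimposition.
    """
    k = template.shape[0]
    cen = template - template.mean(axis=0)
    sim = np.stack([
        np.tile([1.0, 0.0], k),
        np.tile([0.0, 1.0], k),
        cen.ravel(),
        np.column_stack([-cen[:, 1], cen[:, 0]]).ravel(),
    ])
    basis = []
    while len(basis) < n_dirs:
        v = rng.standard_normal(2 * k)
        for u in list(sim) + basis:
            v = v - np.dot(v, u) / np.dot(u, u) * u
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.stack(basis)


def simulate_morphology(
    gen_scores: np.ndarray,
    epi_scores: np.ndarray,
    variance_fractions: tuple[float, float, float] = (0.2, 0.2, 0.6),
    sizes: np.ndarray | None = None,
    *,
    template: np.ndarray | None = None,
    allometry_coef: float = 0.05,
    total_shape_var: float = 4e-4,
    noise_frac_of_residual: float = 1.0,
    ids: list[str] | None = None,
    populations=None,
    seed=None,
) -> tuple[list[LandmarkConfiguration], np.ndarray]:
    """Landmark configurations carrying planted variance fractions.

    shape_i = template + a * log(size_i / size0) * dir_a
              + w_g * z_gen_i * dir_g + w_e * z_epi_i * dir_e + noise

    with ``w_g^2 : w_e^2 : (residual)`` proportional to
    ``variance_fractions`` of a total planted shape variance
    ``total_shape_var`` (in squared template units).  Scores are
    standardized internally; sizes default to log-normal around 200 mm.
    """
    gen_scores = np.asarray(gen_scores, dtype=float)
    epi_scores = np.asarray(epi_scores, dtype=float)
    if gen_scores.shape != epi_scores.shape:
        raise ValueError("score vectors must have the same length")
    fr = np.asarray(variance_fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1) > 1e-12:
        raise ValueError("variance fractions must be non-negative and sum to 1")
    n = gen_scores.size
    rng = as_rng(seed)

    tmpl = FISH_TEMPLATE if template is None else np.asarray(template, float)
    if centroid_size(tmpl) <= 0:
        raise ValueError("degenerate (zero-size) template")
    cen = tmpl - tmpl.mean(axis=0)
    if np.linalg.matrix_rank(cen) < 2:
        raise ValueError("degenerate (collinear) template")

    def _std(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    zg, ze = _std(gen_scores), _std(epi_scores)
    dirs = _shape_basis(tmpl, 3, np.random.default_rng(12345))  # fixed deformation axes
    dir_a, dir_g, dir_e = dirs

    if sizes is None:
        sizes = 200.0 * rng.lognormal(0.0, 0.15, size=n)
    sizes = np.asarray(sizes, dtype=float)
    log_rel_size = np.log(sizes) - np.mean(np.log(sizes))

    w_g = np.sqrt(fr[0] * total_shape_var)
    w_e = np.sqrt(fr[1] * total_shape_var)
    p = tmpl.size
    noise_sd = np.sqrt(fr[2] * total_shape_var * noise_frac_of_residual / p)

    flat = (
        tmpl.ravel()[None, :]
        + allometry_coef * log_rel_size[:, None] * dir_a[None, :]
        + w_g * zg[:, None] * dir_g[None, :]
        + w_e * ze[:, None] * dir_e[None, :]
        + noise_sd * rng.standard_normal((n, p))
    )
    coords = flat.reshape(n, -1, 2)
    # scale each configuration so its centroid size equals the drawn size (mm)
    configs = []
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    pops = [None] * n if populations is None else list(populations)
    out_sizes = np.empty(n)
    for i in range(n):
        c = coords[i]
        cs = centroid_size(c)
        c_mm = c * (sizes[i] / cs)
        configs.append(LandmarkConfiguration(ids[i], c_mm, scale=1.0, population=pops[i]))
        out_sizes[i] = sizes[i]
    return configs, out_sizes


# ---------------------------------------------------------------------------
# isotopes
# ---------------------------------------------------------------------------


def simulate_isotopes(
    pop_params: dict,
    n_per_pop: int = 10,
    *,
    muscle_stomach_slope: float = 0.8,
    muscle_stomach_noise_sd: float = 0.3,
    ids_by_pop: dict | None = None,
    seed=None,
) -> pd.DataFrame:
    """Per-individual stomach and muscle (d13C, d15N), bivariate normal.

    Stomach values are drawn from each population's niche; muscle values
    follow muscle = slope * stomach + noise on both axes, emulating the
    slower isotopic turnover of muscle tissue.
    """
    rng = as_rng(seed)
    rows = []
    for pop, niche in pop_params.items():
        if niche.sd_d13c < 0 or niche.sd_d15n < 0:
            raise ValueError("isotope SDs must be >= 0")
        ids = (ids_by_pop or {}).get(pop) or [f"{pop}_iso{i}" for i in range(n_per_pop)]
        for ind in ids:
            st = np.array([
                rng.normal(niche.mean_d13c, niche.sd_d13c),
                rng.normal(niche.mean_d15n, niche.sd_d15n),
            ])
            mu = muscle_stomach_slope * st + muscle_stomach_noise_sd * rng.standard_normal(2)
            rows.append({"individual_id": ind, "population": pop, "tissue": "stomach",
                         "d13C": st[0], "d15N": st[1]})
            rows.append({"individual_id": ind, "population": pop, "tissue": "muscle",
                         "d13C": mu[0], "d15N": mu[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def _snp_map(n_snps: int, n_chrom: int, rng) -> pd.DataFrame:
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=n_snps))
    pos = np.empty(n_snps, dtype=int)
    for c in np.unique(chrom):
        m = chrom == c
        draw = np.unique(rng.integers(1, 30_000_000, size=3 * m.sum()))[: m.sum()]
        while draw.size < m.sum():  # vanishingly unlikely; top up
            draw = np.unique(np.concatenate(
                [draw, rng.integers(1, 30_000_000, size=m.sum())]))[: m.sum()]
        pos[m] = np.sort(draw)
    ref = rng.choice(list("ACGT"), size=n_snps)
    alt_pick = rng.integers(0, 3, size=n_snps)
    alt = np.array(["ACGT".replace(r, "")[k] for r, k in zip(ref, alt_pick)])
    return pd.DataFrame({
        "chrom": [f"chr{c}" for c in chrom], "pos": pos, "ref": ref, "alt": alt,
        "snp_id": [f"snp{i}" for i in range(n_snps)],
        "locus_id": [f"rad{i}" for i in range(n_snps)],
    })


def simulate_study(config: SimulationConfig):
    """Generate a complete study bundle plus its ground truth.

    Returns a :class:`transloc.io.StudyBundle` and a
    :class:`SyntheticTruth`.  Genotypes for the two systems share a SNP
    panel; system source pools are drifted copies of a common ancestral
    pool.  Latent genomic/epigenomic scores driving morphology are the
    first PCs of the realized genotype and (orthogonalized) log-count
    matrices, so downstream variance partitioning can recover the planted
    fractions.
    """
    from .io import StudyBundle  # local import avoids a module cycle

    seed = config.seed
    rng_map = child_rng(seed, _STREAM_MAP)
    rng_geno = child_rng(seed, _STREAM_GENO)
    rng_counts = child_rng(seed, _STREAM_COUNTS)
    rng_morph = child_rng(seed, _STREAM_MORPH)
    rng_iso = child_rng(seed, _STREAM_ISO)
    rng_miss = child_rng(seed, _STREAM_MISS)

    snps = _snp_map(config.n_snps, config.n_chromosomes, rng_map)
    ancestral = simulate_source_pool(config.n_snps, config.afs_alpha, config.afs_beta, rng_geno)

    sel_idx = rng_map.choice(config.n_snps, size=config.n_selected_snps, replace=False)
    sel_idx.sort()
    anc_sel = ancestral[sel_idx]
    sel_signs = np.where(anc_sel <= 0.5, 1.0, -1.0)

    samples_rows = []
    geno_blocks = []
    source_freqs: dict[str, np.ndarray] = {}
    refuge_freqs: dict[str, np.ndarray] = {}
    founder_families: dict[str, int] = {}
    for sysname, specs in config.systems.items():
        # system source pool: mild drift away from the common ancestral pool
        src = rng_geno.binomial(1000, ancestral) / 1000.0
        source_freqs[sysname] = src
        for spec in specs:
            if spec.role == "source":
                g = sample_genotypes(src, spec.n_sampled, rng_geno)
            else:
                freqs, g = simulate_translocation(
                    src, spec, rng_geno, selected_idx=sel_idx,
                    selection_shift=config.selection_shift, selection_signs=sel_signs,
                )
                refuge_freqs[spec.name] = freqs
                founder_families[spec.name] = spec.n_families
            geno_blocks.append(g)
            for i in range(spec.n_sampled):
                samples_rows.append({
                    "id": f"{spec.name}_{i:02d}", "population": spec.name,
                    "system": sysname, "type": spec.role, "age_class": spec.age_class,
                })
    samples = pd.DataFrame(samples_rows)
    genotypes = np.vstack(geno_blocks)

    # library batches assigned at random across populations (not confounded)
    samples["batch"] = [f"lib{b + 1}" for b in
                        rng_counts.integers(0, config.n_batches, size=len(samples))]

    # plant missing genotype calls
    miss_mask = rng_miss.random(genotypes.shape) < 0.03
    genotypes = np.where(miss_mask, MISSING, genotypes).astype(np.int8)
    gmat = GenotypeMatrix(genotypes, samples, snps)

    # epiRAD counts per system, shared locus panel and planted DM ids
    n_loci = config.n_count_loci
    dm_idx = rng_map.choice(n_loci, size=config.n_planted_dm, replace=False)
    dm_idx.sort()
    dm_signs = np.where(np.arange(dm_idx.size) % 2 == 0, -1.0, 1.0)
    n_batch_loci = int(round(config.batch_frac * n_loci))
    batch_idx = rng_map.choice(np.setdiff1d(np.arange(n_loci), dm_idx),
                               size=n_batch_loci, replace=False)
    batch_idx.sort()
    locus_means = config.count_mean * rng_counts.lognormal(0.0, 0.7, size=n_loci)
    locus_chrom = rng_map.integers(1, config.n_chromosomes + 1, size=n_loci)
    starts = np.sort(rng_map.integers(0, 29_000_000, size=n_loci))
    loci = pd.DataFrame({
        "locus_id": [f"epi{l}" for l in range(n_loci)],
        "chrom": [f"chr{c}" for c in locus_chrom],
        "start": starts, "end": starts + 120,
    })

    counts_by_system = {}
    for sysname in config.systems:
        sub = samples[samples["system"] == sysname].reset_index(drop=True)
        lib_factors = rng_counts.lognormal(0.0, 0.3, size=len(sub))
        counts_by_system[sysname] = simulate_epicounts(
            sub, n_loci, mean=config.count_mean, dispersion=config.nb_dispersion,
            locus_means=locus_means, dm_locus_idx=dm_idx, dm_log2fc=config.dm_log2fc,
            dm_signs=dm_signs, batch_locus_idx=batch_idx, batch_log2fc=config.batch_log2fc,
            lib_size_factors=lib_factors, loci=loci, seed=rng_counts,
        )

    # latent scores from the realized molecular data
    g_filled = np.where(gmat.genotypes == MISSING, 0, gmat.genotypes).astype(float)
    g_filled -= g_filled.mean(axis=0)
    u, s, _ = np.linalg.svd(g_filled, full_matrices=False)
    gen_scores = u[:, 0] * s[0]

    log_parts = []
    order = []
    for sysname in config.systems:
        cm = counts_by_system[sysname]
        lc = np.log2(cm.counts / cm.lib_sizes[:, None] * cm.lib_sizes.mean() + 1.0)
        lc -= lc.mean(axis=0)
        uu, ss, _ = np.linalg.svd(lc, full_matrices=False)
        log_parts.append(uu[:, 0] * ss[0])
        order.extend(cm.samples["id"])
    epi_raw = pd.Series(np.concatenate(log_parts), index=order).reindex(samples["id"]).to_numpy()
    # orthogonalize the epigenomic score against the genomic one
    zg = (gen_scores - gen_scores.mean()) / gen_scores.std()
    ze = epi_raw - epi_raw.mean()
    ze = ze - np.dot(ze, zg) / np.dot(zg, zg) * zg
    ze = ze / ze.std() if ze.std() > 0 else ze

    pop_of = samples["population"].to_numpy()
    base_size = {p.name: 180.0 + 10.0 * i for i, p in enumerate(config.populations)}
    sizes = np.array([base_size[p] for p in pop_of]) * rng_morph.lognormal(0.0, 0.12, len(samples))
    landmarks, cs = simulate_morphology(
        zg, ze, config.morph_variance_fractions, sizes=sizes,
        ids=list(samples["id"]), populations=pop_of, seed=rng_morph,
    )

    iso_ids = {p.name: [f"{p.name}_{i:02d}" for i in range(min(config.isotope_n_per_pop, p.n_sampled))]
               for p in config.populations}
    isotopes = simulate_isotopes(
        config.isotope_niche, config.isotope_n_per_pop,
        muscle_stomach_slope=config.muscle_stomach_slope,
        muscle_stomach_noise_sd=config.muscle_stomach_noise_sd,
        ids_by_pop=iso_ids, seed=rng_iso,
    )

    truth = SyntheticTruth(
        seed=seed,
        source_allele_freqs=source_freqs,
        refuge_allele_freqs=refuge_freqs,
        selected_snp_ids=snps["snp_id"].to_numpy()[sel_idx],
        selection_signs=sel_signs,
        planted_dm_locus_ids=loci["locus_id"].to_numpy()[dm_idx],
        dm_signs=dm_signs,
        batch_locus_ids=loci["locus_id"].to_numpy()[batch_idx],
        gen_scores=zg,
        epi_scores=ze,
        morph_variance_fractions=config.morph_variance_fractions,
        founder_families=founder_families,
    )
    bundle = StudyBundle(
        genotypes=gmat, counts_by_system=counts_by_system, landmarks=landmarks,
        isotopes=isotopes, metadata=samples, truth=truth,
    )
    return bundle, truth
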