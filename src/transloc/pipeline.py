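"""End-to-end pipeline driver.

Runs the study's analysis graph on a bundle: morphometrics (GPA, shape
PCA, allometry, trajectories) -> linear traits -> isotope niches -> SNP
QC and imputation -> population genomics (diversity, kinship, FST, PCA)
-> RDA outliers + allele-frequency-change z-scores -> epiRAD count
processing and differential methylation -> morphology variance
partitioning.  Every stochastic step consumes a seed derived from the
master seed; a JSON manifest records parameters, seeds and row/column
counts at every stage.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import methylation as meth
from . import morphometrics as morpho
from . import isotopes as iso
from . import outliers as outl
from . import popgen
from . import qc
from . import traits as traits_mod
from .config import AnalysisParams
from .io import StudyBundle
from .ordination import pca, rda
from .varpart import varpart_morphology

__all__ = ["run_pipeline"]


def _seed_for(master: int, stage: str) -> int:
    digest = zlib.crc32(f"{master}:{stage}".encode())
    return digest % (2**31 - 1)


def run_pipeline(
    bundle: StudyBundle,
    outdir,
    params: AnalysisParams | None = None,
    seed: int = 0,
    n_perm: int | None = None,
) -> dict:
    """Run all stages; writes tables under ``outdir`` and returns results.

    ``n_perm`` overrides every permutation count (handy for quick runs).
    """
    p = params or AnalysisParams()
    if n_perm is not None:
        p.n_perm_rda = n_perm
        p.n_perm_morpho = max(n_perm, 99)
        p.n_perm_fst = n_perm
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    meta = bundle.metadata.set_index("id")
    manifest: dict = {"seed": seed, "stages": {}}
    results: dict = {"manifest": manifest}

    # ---- morphometrics -------------------------------------------------
    if bundle.landmarks:
        aligned = morpho.generalized_procrustes(bundle.landmarks)
        ids = aligned.ids
        pops = meta.loc[ids, "population"].to_numpy()
        systems = meta.loc[ids, "system"].to_numpy()
        types = meta.loc[ids, "type"].to_numpy()
        spca = morpho.shape_pca(aligned)
        anova = morpho.allometry_anova(aligned, aligned.centroid_sizes, pops,
                                       n_perm=p.n_perm_morpho,
                                       seed=_seed_for(seed, "allometry"))
        traj = morpho.trajectory_analysis(aligned, systems, types,
                                          n_perm=p.n_perm_morpho,
                                          seed=_seed_for(seed, "pta"))
        anova.to_csv(out / "allometry_anova.tsv", sep="\t", index=False)
        results["morpho"] = {"aligned": aligned, "pca": spca, "anova": anova,
                             "trajectory": traj}
        manifest["stages"]["morpho"] = {
            "n": aligned.n, "theta_p": traj.theta, "delta_lp": traj.delta_l,
            "p_theta": traj.p_theta, "p_delta_l": traj.p_delta_l,
        }

        # ---- linear traits ---------------------------------------------
        ttab = traits_mod.interlandmark_traits(bundle.landmarks)
        lengths = ttab["fork_length"].to_numpy()
        cols = [c for c in ttab.columns
                if c not in ("individual_id", "population", "fork_length")]
        std, slopes = traits_mod.allometric_standardize(ttab, lengths, pops, cols)
        kw = traits_mod.kw_dunn_bh(std, pops, cols)
        std.to_csv(out / "traits_standardized.tsv", sep="\t", index=False)
        kw.to_csv(out / "traits_tests.tsv", sep="\t", index=False)
        results["traits"] = {"table": std, "slopes": slopes, "tests": kw}
        manifest["stages"]["traits"] = {"n_traits": len(cols)}

    # ---- isotopes ------------------------------------------------------
    if bundle.isotopes is not None:
        niche = iso.population_metrics(bundle.isotopes, tissue="muscle")
        reg = iso.tissue_diet_regression(bundle.isotopes)
        niche.to_csv(out / "isotope_niche.tsv", sep="\t", index=False)
        results["isotopes"] = {"niche": niche, "regression": reg}
        manifest["stages"]["isotopes"] = {"n_pops": len(niche), **reg}

    # ---- genotype QC ---------------------------------------------------
    gmat = bundle.genotypes
    if gmat is not None:
        filt, report = qc.filter_genotypes(gmat, qc.QCParams(
            maf=p.maf, max_missing_global=p.max_missing_global,
            max_missing_per_pop=p.max_missing_per_pop, max_obs_het=p.max_obs_het,
            max_ind_missing=p.max_ind_missing, hwe_alpha=p.hwe_alpha,
            hwe_pop_fraction=p.hwe_pop_fraction))
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        imputed = qc.knn_impute(filt, k=p.knn_k)
        kept = qc.ld_prune(imputed, r2_max=p.ld_r2_max, window_bp=p.ld_window_bp)
        pruned = imputed.take_snps(kept)
        results["qc"] = {"filtered": filt, "imputed": imputed, "pruned": pruned,
                         "report": report}
        manifest["stages"]["qc"] = {
            "snps_in": gmat.n_snps, "snps_filtered": filt.n_snps,
            "snps_pruned": pruned.n_snps, "individuals": filt.n_individuals,
        }

        # ---- population genomics ---------------------------------------
        div = popgen.diversity_stats(filt, rarefaction_g=p.rarefaction_g)
        src_pops = filt.samples.loc[filt.samples["type"] == "source", "population"].unique()
        src_mask = filt.samples["type"].to_numpy() == "source"
        ref_freqs = pruned.allele_freq(pruned.samples["type"].to_numpy() == "source")
        kin = popgen.inbreeding_relatedness(pruned, ref_freqs)
        fst = popgen.wc_fst(filt, n_perm=min(p.n_perm_fst, 200),
                            seed=_seed_for(seed, "fst"))
        gpca = popgen.genotype_pca(imputed)
        div.table.to_csv(out / "diversity.tsv", sep="\t")
        fst.theta.to_csv(out / "fst.tsv", sep="\t")
        kin.f_h.to_frame().to_csv(out / "f_h.tsv", sep="\t")
        results["popgen"] = {"diversity": div, "kinship": kin, "fst": fst, "pca": gpca}
        manifest["stages"]["popgen"] = {
            "He_by_pop": div.table["He"].to_dict(),
            "mean_fst": float(np.nanmean(fst.theta.to_numpy()[np.triu_indices(len(fst.theta), 1)])),
        }

        # ---- outliers ---------------------------------------------------
        g = imputed.genotypes.astype(float)
        type_ind = (imputed.samples["type"] == "refuge").astype(float).to_numpy()
        sys_labels = imputed.samples["system"].astype("category").cat.codes.to_numpy().astype(float)
        X = np.column_stack([type_ind, sys_labels])
        ordn = rda(g, X, n_perm=p.n_perm_rda, seed=_seed_for(seed, "rda"))
        # lake-type axis: the constrained axis most correlated with type
        cors = [abs(np.corrcoef(ordn.fitted_scores[:, a], type_ind)[0, 1])
                for a in range(ordn.constrained_axes)]
        type_axis = int(np.argmax(cors))
        rda_tab = outl.rda_outliers(ordn, axis=type_axis, z_threshold=p.outlier_z)
        refuge_pops = imputed.samples.loc[imputed.samples["type"] == "refuge",
                                          "population"].unique()
        afz = outl.af_change_z(imputed, list(src_pops), list(refuge_pops))
        calls = outl.combine_outlier_calls(rda_tab, afz, z_threshold=p.outlier_z)
        calls.insert(0, "snp_id", imputed.snps.get("snp_id", imputed.snps.index))
        calls.to_csv(out / "outliers.tsv", sep="\t", index=False)
        results["outliers"] = {"rda": ordn, "calls": calls, "type_axis": type_axis}
        manifest["stages"]["outliers"] = {
            "rda_adj_r2": ordn.adj_r2, "rda_p": ordn.perm_p,
            "n_rda": int(calls["rda"].sum()), "n_afz": int(calls["afz"].sum()),
            "n_shared": int(calls["shared"].sum()),
        }

    # ---- methylation ---------------------------------------------------
    dm_results = {}
    log_blocks = {}
    for sysname, cm in bundle.counts_by_system.items():
        stage = {"n_loci_in": cm.n_loci}
        bl, _ = meth.batch_blacklist(cm, "batch", fdr=p.dm_fdr,
                                     dispersion=0.3)
        keep = np.setdiff1d(np.arange(cm.n_loci), bl)
        cm2 = cm.take_loci(keep)
        stage["n_batch_blacklisted"] = int(len(bl))
        cm2 = meth.filter_informative(cm2, p.min_nonzero_frac)
        stage["n_informative"] = cm2.n_loci
        cm2.norm_factors = meth.tmm_normalize(cm2)
        source_pop = meta.loc[cm2.samples["id"], :]
        src = source_pop.loc[source_pop["type"] == "source", "population"].unique()
        comparisons = {}
        for refuge in source_pop.loc[source_pop["type"] == "refuge", "population"].unique():
            res = meth.dm_test(cm2, src[0], refuge, fdr=p.dm_fdr)
            comparisons[refuge] = res
        dm_results[sysname] = {"counts": cm2, "comparisons": comparisons}
        stage["n_dm"] = {k: int(v.table["dm"].sum()) for k, v in comparisons.items()}
        manifest["stages"][f"methylation_{sysname}"] = stage
        log_blocks[sysname] = meth.log_transform(cm2)
        pd.concat({k: v.table.loc[v.table["dm"]] for k, v in comparisons.items()},
                  names=["comparison"]).to_csv(out / f"dm_{sysname}.tsv", sep="\t")
    results["methylation"] = dm_results

    # ---- variance partitioning ----------------------------------------
    if bundle.landmarks and gmat is not None and dm_results:
        aligned = results["morpho"]["aligned"]
        ids = aligned.ids
        morpho_scores = results["morpho"]["pca"].site_scores[:, :p.n_pcs]
        gpca = results["popgen"]["pca"]
        gen_ids = list(results["qc"]["imputed"].samples["id"])
        gen_scores = pd.DataFrame(gpca.site_scores[:, :p.n_pcs], index=gen_ids)
        epi_parts = []
        for sysname, block in log_blocks.items():
            epca = pca(block)
            epi_parts.append(pd.DataFrame(
                epca.site_scores[:, :p.n_pcs],
                index=list(dm_results[sysname]["counts"].samples["id"])))
        epi_scores = pd.concat(epi_parts)
        common = [i for i in ids if i in gen_scores.index and i in epi_scores.index]
        if len(common) > 10:
            sel = [ids.index(i) for i in common]
            mo = morpho_scores[sel]
            ge = gen_scores.loc[common].to_numpy()
            ep = epi_scores.loc[common].to_numpy()
            sub = meta.loc[common]
            cohorts = {}
            for sysname in sub["system"].unique():
                cohorts[f"system_{sysname}"] = (sub["system"] == sysname).to_numpy()
            if "age_class" in sub:
                src_m = (sub["type"] == "source").to_numpy()
                for age in ("young", "old"):
                    m = src_m | ((sub["age_class"] == age) & (sub["type"] == "refuge")).to_numpy()
                    cohorts[f"source_plus_{age}"] = m
            vp = varpart_morphology(mo, ge, ep, cohorts, n_perm=p.n_perm_rda,
                                    seed=_seed_for(seed, "varpart"))
            vp.to_csv(out / "varpart.tsv", sep="\t", index=False)
            results["varpart"] = vp
            manifest["stages"]["varpart"] = vp.drop(
                columns=[c for c in vp.columns if c.startswith("p_")]).to_dict("records")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return results
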