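"""File formats and the study bundle.

All file I/O flows through this module.  Conventions are fixed
project-wide: VCF positions are 1-based inclusive; count-locus and gene
intervals are 0-based half-open; conversions happen only here.

Formats: VCF v4.2 (genotypes; GT field only), TPS landmark files
(LM=, optional SCALE=, ID= records), TSV tables (counts with locus
coordinate columns, isotopes, traits, metadata), JSON for the synthetic
ground truth and run manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GenotypeMatrix, MISSING
from .morphometrics import LandmarkConfiguration

__all__ = [
    "StudyBundle", "read_tps", "write_tps", "read_vcf", "write_vcf",
    "read_counts_tsv", "write_counts_tsv", "load_bundle", "write_bundle",
]


@dataclass
class StudyBundle:
    """All data layers of one study, keyed by individual id.

    ``metadata`` must contain every analysis individual with columns
    id / population / system / type (source|refuge); optional age_class
    and batch.
    """

    genotypes: GenotypeMatrix | None = None
    counts_by_system: dict[str, CountMatrix] = field(default_factory=dict)
    landmarks: list[LandmarkConfiguration] = field(default_factory=list)
    isotopes: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    truth: object | None = None

    def validate(self) -> None:
        if self.metadata is None or "id" not in self.metadata:
            raise ValueError("metadata with an 'id' column is required")
        known = set(self.metadata["id"])
        problems = []
        if self.genotypes is not None:
            unknown = set(self.genotypes.samples["id"]) - known
            if unknown:
                problems.append(f"VCF samples not in metadata: {sorted(unknown)[:5]}")
        for sysname, cm in self.counts_by_system.items():
            unknown = set(cm.samples["id"]) - known
            if unknown:
                problems.append(f"count samples ({sysname}) not in metadata: {sorted(unknown)[:5]}")
        unknown = {c.individual_id for c in self.landmarks} - known
        if unknown:
            problems.append(f"landmark ids not in metadata: {sorted(unknown)[:5]}")
        if self.isotopes is not None:
            unknown = set(self.isotopes["individual_id"]) - known
            if unknown:
                problems.append(f"isotope ids not in metadata: {sorted(unknown)[:5]}")
        if problems:
            raise ValueError("bundle id mismatches: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file (LM=, coordinate lines, SCALE=, ID=)."""
    configs = []
    coords: list[list[float]] = []
    n_expected = 0
    scale = 1.0
    ident = None
    line_no = 0

    def flush():
        nonlocal coords, scale, ident, n_expected
        if n_expected:
            if len(coords) != n_expected:
                raise ValueError(
                    f"{path}: record {ident!r} has {len(coords)} landmarks, expected {n_expected}")
            configs.append(LandmarkConfiguration(
                ident or f"specimen{len(configs)}", np.array(coords), scale=scale))
        coords, scale, ident, n_expected = [], 1.0, None, 0

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush()
                n_expected = int(line.split("=", 1)[1])
            elif upper.startswith("SCALE="):
                scale = float(line.split("=", 1)[1])
            elif upper.startswith("ID=") or upper.startswith("IMAGE="):
                ident = line.split("=", 1)[1]
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{line_no}: expected 'x y', got {line!r}")
                coords.append([float(parts[0]), float(parts[1])])
    flush()
    return configs


def write_tps(configs, path) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.coords.shape[0]}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"SCALE={cfg.scale:.6f}\n")
            fh.write(f"ID={cfg.individual_id}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write genotypes as a plain-text VCF v4.2 (GT field only)."""
    snps = matrix.snps
    samples = matrix.samples["id"].tolist()
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        ids = snps["snp_id"] if "snp_id" in snps else [f"snp{i}" for i in range(len(snps))]
        ref = snps["ref"] if "ref" in snps else ["A"] * len(snps)
        alt = snps["alt"] if "alt" in snps else ["T"] * len(snps)
        for j, (chrom, pos, sid, r, a) in enumerate(
                zip(snps["chrom"], snps["pos"], ids, ref, alt)):
            gts = "\t".join(gt_map[int(g)] for g in matrix.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t{sid}\t{r}\t{a}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF (via cyvcf2); multiallelic records are skipped and counted.

    When ``metadata`` is given, sample labels are joined from it; samples
    missing there raise with the offending ids listed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    genos = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        g = np.asarray(variant.genotype.array())[:, :2]
        dosage = np.where((g < 0).any(axis=1), MISSING, g.clip(min=0).sum(axis=1))
        genos.append(dosage.astype(np.int8))
        rows.append({"chrom": variant.CHROM, "pos": variant.POS,
                     "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                     "ref": variant.REF, "alt": variant.ALT[0]})
    snps = pd.DataFrame(rows)
    genotypes = np.stack(genos, axis=1) if genos else np.empty((len(samples), 0), np.int8)
    sample_df = pd.DataFrame({"id": samples})
    if metadata is not None:
        unknown = set(samples) - set(metadata["id"])
        if unknown:
            raise ValueError(f"VCF samples missing from metadata: {sorted(unknown)}")
        sample_df = sample_df.merge(metadata, on="id", how="left")
    m = GenotypeMatrix(genotypes, sample_df, snps)
    m.snps.attrs["skipped_multiallelic"] = n_skipped
    return m


# ---------------------------------------------------------------------------
# count tables & bundle
# ---------------------------------------------------------------------------


def write_counts_tsv(cm: CountMatrix, path) -> None:
    """Loci as rows (locus_id, chrom, start, end), samples as columns."""
    df = cm.loci[["locus_id", "chrom", "start", "end"]].copy()
    for i, sid in enumerate(cm.samples["id"]):
        df[sid] = cm.counts[i]
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, metadata: pd.DataFrame | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["locus_id", "chrom", "start", "end"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    counts = df[sample_ids].to_numpy().T
    sample_df = pd.DataFrame({"id": sample_ids})
    if metadata is not None:
        unknown = set(sample_ids) - set(metadata["id"])
        if unknown:
            raise ValueError(f"count samples missing from metadata: {sorted(unknown)}")
        sample_df = sample_df.merge(metadata, on="id", how="left")
    return CountMatrix(counts, sample_df, df[meta_cols])


def write_bundle(bundle: StudyBundle, outdir) -> dict:
    """Write all layers to ``outdir``; returns the path manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if bundle.metadata is not None:
        paths["metadata"] = str(out / "metadata.tsv")
        bundle.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    if bundle.genotypes is not None:
        paths["vcf"] = str(out / "genotypes.vcf")
        write_vcf(bundle.genotypes, paths["vcf"])
    for sysname, cm in bundle.counts_by_system.items():
        key = f"counts_{sysname}"
        paths[key] = str(out / f"counts_{sysname}.tsv")
        write_counts_tsv(cm, paths[key])
    if bundle.landmarks:
        paths["tps"] = str(out / "landmarks.tps")
        write_tps(bundle.landmarks, paths["tps"])
    if bundle.isotopes is not None:
        paths["isotopes"] = str(out / "isotopes.tsv")
        bundle.isotopes.to_csv(paths["isotopes"], sep="\t", index=False)
    if bundle.truth is not None:
        paths["truth"] = str(out / "truth.json")
        truth = bundle.truth
        with open(paths["truth"], "w") as fh:
            json.dump({
                "seed": truth.seed,
                "selected_snp_ids": list(map(str, truth.selected_snp_ids)),
                "planted_dm_locus_ids": list(map(str, truth.planted_dm_locus_ids)),
                "batch_locus_ids": list(map(str, truth.batch_locus_ids)),
                "morph_variance_fractions": list(truth.morph_variance_fractions),
                "founder_families": truth.founder_families,
                "source_allele_freqs": {k: v.tolist() for k, v in
                                        truth.source_allele_freqs.items()},
            }, fh)
    return paths


def load_bundle(paths: dict) -> StudyBundle:
    """Load a bundle from a path manifest (as produced by write_bundle).

    All cross-file id mismatches are collected and reported before
    failing.
    """
    metadata = pd.read_csv(paths["metadata"], sep="\t") if "metadata" in paths else None
    bundle = StudyBundle(metadata=metadata)
    if "vcf" in paths:
        bundle.genotypes = read_vcf(paths["vcf"], metadata)
        if metadata is not None:
            meta_cols = metadata.set_index("id")
            bundle.genotypes.samples = (
                bundle.genotypes.samples[["id"]]
                .join(meta_cols, on="id").reset_index(drop=True))
    for key, p in paths.items():
        if key.startswith("counts_"):
            sysname = key.split("_", 1)[1]
            bundle.counts_by_system[sysname] = read_counts_tsv(p, metadata)
    if "tps" in paths:
        bundle.landmarks = read_tps(paths["tps"])
        if metadata is not None:
            pop_of = dict(zip(metadata["id"], metadata.get("population", metadata["id"])))
            for cfg in bundle.landmarks:
                cfg.population = pop_of.get(cfg.individual_id)
    if "isotopes" in paths:
        bundle.isotopes = pd.read_csv(paths["isotopes"], sep="\t")
    bundle.validate()
    return bundle
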