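"""End-to-end orchestration: simulation -> reads -> repeats -> DE -> waves -> images.

A :class:`RunConfig` bundles every stage's parameters plus a global seed and
an output directory; :func:`run_pipeline` executes the enabled stages
deterministically, writes per-stage TSV outputs, and returns a
machine-readable report (also written as JSON) that records every numeric
decision — seeds, thresholds, discard tallies, class counts.

Config files are YAML mappings mirroring the dataclass fields;
:func:`validate_config` collects all problems before anything runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mztkit import de as de_mod
from mztkit import images as img_mod
from mztkit import repeats as rep_mod
from mztkit import waves as waves_mod
from mztkit.mapping import MapConfig, map_multi, filter_rrna, write_sam
from mztkit.readqc import QCConfig, qc_filter_reads
from mztkit.repeats import RepeatConfig
from mztkit.sim import (
    CountSimConfig,
    ImageSimConfig,
    QCNoiseParams,
    RepeatGenomeConfig,
    make_wave_catalogue,
    simulate_embryo_counts,
    simulate_nucleus_images,
    simulate_reads,
    simulate_repeat_genome,
)

ALL_STAGES = ("counts", "repeats", "images")


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results/pipeline"
    stages: tuple = ALL_STAGES
    counts: CountSimConfig = field(default_factory=CountSimConfig)
    de: de_mod.DEConfig = field(default_factory=de_mod.DEConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    mapping: MapConfig = field(default_factory=MapConfig)
    repeat_genome: RepeatGenomeConfig = field(default_factory=RepeatGenomeConfig)
    repeat_config: RepeatConfig = field(default_factory=RepeatConfig)
    qc_noise: QCNoiseParams = field(default_factory=lambda: QCNoiseParams(0.02, 0.02, 0.04))
    reads_per_sample: int = 3000
    repeat_samples_per_group: int = 8
    target_family_fold: float = 2.0  # planted mutant fold on the target LINE family
    target_family_weight: float = 0.5  # baseline abundance of the target family
    other_family_weight: float = 2.0
    rrna_abundance: float = 0.2
    images: ImageSimConfig = field(default_factory=ImageSimConfig)


_SECTION_TYPES = {
    "counts": CountSimConfig,
    "de": de_mod.DEConfig,
    "qc": QCConfig,
    "mapping": MapConfig,
    "repeat_genome": RepeatGenomeConfig,
    "repeat_config": RepeatConfig,
    "qc_noise": QCNoiseParams,
    "images": ImageSimConfig,
}


def validate_config(config) -> list:
    """Return a list of problems (empty iff the config is runnable).

    Accepts either a RunConfig or a mapping of YAML sections; dataclass
    invariant violations are collected rather than raised.
    """
    problems: list = []
    if isinstance(config, RunConfig):
        mapping = {
            name: dataclasses.asdict(getattr(config, name)) for name in _SECTION_TYPES
        }
        top = {
            k: getattr(config, k)
            for k in ("seed", "stages", "reads_per_sample", "repeat_samples_per_group",
                      "target_family_fold", "target_family_weight", "other_family_weight",
                      "rrna_abundance")
        }
    else:
        mapping = {k: v for k, v in dict(config).items() if k in _SECTION_TYPES}
        top = {k: v for k, v in dict(config).items() if k not in _SECTION_TYPES}

    for name, cls_ in _SECTION_TYPES.items():
        section = mapping.get(name, {})
        try:
            kwargs = dict(section)
            for key in ("image_shape", "rrna_refs", "nb_mean_range"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in kwargs[key]
                    )
            cls_(**kwargs)
        except (ValueError, TypeError) as exc:
            problems.append(f"{name}: {exc}")

    unknown = set(top.get("stages", ALL_STAGES)) - set(ALL_STAGES)
    if unknown:
        problems.append(f"unknown stages: {sorted(unknown)}")
    if top.get("reads_per_sample", 1) < 1:
        problems.append("reads_per_sample must be >= 1")
    if top.get("repeat_samples_per_group", 2) < 2:
        problems.append("repeat_samples_per_group must be >= 2")
    if top.get("target_family_fold", 1.0) <= 0:
        problems.append("target_family_fold must be > 0")
    if top.get("target_family_weight", 1.0) < 0 or top.get("other_family_weight", 1.0) < 0:
        problems.append("family weights must be >= 0")
    if top.get("rrna_abundance", 0.0) < 0:
        problems.append("rrna_abundance must be >= 0")
    cfg_counts = mapping.get("counts", {})
    if cfg_counts.get("n_samples_per_group", 2) < 2:
        problems.append("counts: n_samples_per_group must be >= 2 for DE")
    return problems


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML config file into a validated RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems = validate_config(raw)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    kwargs = {}
    for name, cls_ in _SECTION_TYPES.items():
        if name in raw:
            section = dict(raw.pop(name))
            for key in ("image_shape", "rrna_refs", "nb_mean_range"):
                if key in section and isinstance(section[key], list):
                    section[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in section[key]
                    )
            kwargs[name] = cls_(**section)
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    kwargs.update(raw)
    return RunConfig(**kwargs)


# -- stages -------------------------------------------------------------------


def _counts_stage(config: RunConfig, outdir: Path) -> dict:
    counts_cfg = dataclasses.replace(config.counts, seed=(config.seed * 7 + 1) % 2**31)
    catalogue = make_wave_catalogue(counts_cfg)
    matrix, truth = simulate_embryo_counts(catalogue, counts_cfg)
    matrix.write(outdir / "counts.tsv", outdir / "sample_metadata.tsv")
    catalogue.write(outdir / "wave_catalogue.tsv")
    truth.to_csv(outdir / "counts_truth.tsv", sep="\t")

    res = de_mod.run_de(matrix, config.de)
    res.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene_id")

    overlap = waves_mod.build_overlap_table(res, catalogue)
    overlap.write(outdir / "wave_overlap.tsv")
    pct = waves_mod.category_percentages(overlap)
    pct.to_csv(outdir / "wave_percentages.tsv", sep="\t")
    coverage, min_cov = waves_mod.coverage_stats(overlap)
    summary = waves_mod.summarize_overlap(overlap)

    factors = de_mod.size_factors(
        de_mod.filter_genes(matrix, config.de).counts
    )
    norm = de_mod.normalized_counts(
        de_mod.filter_genes(matrix, config.de).counts, factors
    )
    Z, clusters = de_mod.cluster_samples(norm)
    with open(outdir / "sample_tree.nwk", "w") as fh:
        fh.write(de_mod.linkage_to_newick(Z, list(norm.columns)))
    coords, varexp = de_mod.pca_samples(norm)
    coords.join(varexp, how="outer").to_csv(outdir / "pca_coordinates.tsv", sep="\t")

    class_counts = res["de_class"].value_counts().to_dict()
    return {
        "n_genes_simulated": int(len(matrix.gene_ids)),
        "n_genes_tested": int(len(res)),
        "de_class_counts": {c: int(class_counts.get(c, 0)) for c in de_mod.DE_CLASSES},
        "size_factors": {s: float(f) for s, f in factors.items()},
        "overlap_table": overlap.table.to_dict(orient="index"),
        "overlap_summary": summary,
        "min_category_coverage_pct": min_cov,
        "cluster_labels": {s: int(c) for s, c in clusters.items()},
        "pc1_variance_explained": float(varexp.iloc[0]),
    }


def _repeats_stage(config: RunConfig, outdir: Path) -> dict:
    genome_cfg = dataclasses.replace(
        config.repeat_genome, seed=(config.seed * 7 + 2) % 2**31
    )
    genome, annotation, rrna = simulate_repeat_genome(genome_cfg)
    annotation.write(outdir / "repeats.bed", outdir / "repeat_classes.tsv")
    map_cfg = dataclasses.replace(config.mapping, rrna_references=rrna)

    families = annotation.families
    target = next(f for f in families if f.startswith("LINE"))
    base = {
        f: (config.target_family_weight if f == target else config.other_family_weight)
        for f in families
    }

    n = config.repeat_samples_per_group
    records_by_sample: dict = {}
    design = {}
    qc_tallies_total: dict = {}
    map_tallies_total = {"mapped": 0, "unmapped": 0, "over_cap": 0}
    n_rrna_discarded = 0
    for g_i, genotype in enumerate(("control", "mutant")):
        for s_i in range(n):
            sample = f"{genotype}_{s_i+1}"
            design[sample] = genotype
            abundances = dict(base)
            if genotype == "mutant":
                abundances[target] *= config.target_family_fold
            reads, _ = simulate_reads(
                genome,
                annotation,
                abundances,
                n_reads=config.reads_per_sample,
                qc_noise=config.qc_noise,
                rrna_references=rrna,
                rrna_abundance=config.rrna_abundance,
                seed=(config.seed * 7 + 100 + g_i * n + s_i) % 2**31,
            )
            kept, tallies = qc_filter_reads(reads, config.qc)
            for k, v in tallies.items():
                qc_tallies_total[k] = qc_tallies_total.get(k, 0) + v
            kept, n_rrna = filter_rrna(kept, map_cfg)
            n_rrna_discarded += n_rrna
            records, m_tallies = map_multi(kept, genome, map_cfg)
            for k in map_tallies_total:
                map_tallies_total[k] += m_tallies[k]
            records_by_sample[sample] = records

    first = next(iter(records_by_sample))
    write_sam(
        records_by_sample[first], {"genome": len(genome)}, outdir / f"{first}.sam"
    )
    table = rep_mod.build_count_table(records_by_sample, annotation, config.repeat_config)
    table.write(outdir / "repeat_counts.tsv")
    composition = rep_mod.class_composition(table, annotation)
    composition.to_csv(outdir / "class_composition.tsv", sep="\t")
    tests = rep_mod.test_families(
        table, pd.Series(design), config.repeat_config
    )
    fam2cls = annotation.family_class_map()
    tests.insert(0, "repeat_class", [fam2cls[f] for f in tests.index])
    tests.to_csv(outdir / "repeat_tests.tsv", sep="\t")

    ctrl_cols = [s for s, g in design.items() if g == "control"]
    mut_cols = [s for s, g in design.items() if g == "mutant"]
    recovered = float(
        table.normalized.loc[target, mut_cols].mean()
        / table.normalized.loc[target, ctrl_cols].mean()
    )
    return {
        "target_family": target,
        "planted_fold": config.target_family_fold,
        "recovered_normalized_fold": recovered,
        "target_significant": bool(tests.loc[target, "significant"]),
        "qc_discard_tallies": qc_tallies_total,
        "n_rrna_discarded": int(n_rrna_discarded),
        "map_tallies": map_tallies_total,
        "family_tests": tests.reset_index().to_dict(orient="records"),
    }


def _images_stage(config: RunConfig, outdir: Path) -> dict:
    img_cfg = dataclasses.replace(config.images, seed=(config.seed * 7 + 3) % 2**31)
    nuclei = simulate_nucleus_images(img_cfg)
    per_nucleus = []
    for nuc in nuclei:
        image = img_mod.NucleusImage(nuc.image, nuc.mask, nuc.metadata)
        glcm = img_mod.compute_glcm(image)
        row = {
            "nucleus": nuc.metadata["embryo_id"],
            "genotype": nuc.genotype,
            "integrated_intensity": img_mod.integrated_intensity(image),
            "mean_intensity": float(nuc.image[nuc.mask].mean()),
            "max_intensity": float(nuc.image[nuc.mask].max()),
        }
        row.update(img_mod.haralick_features(glcm))
        per_nucleus.append(row)
    df = pd.DataFrame(per_nucleus).set_index("nucleus")
    df.to_csv(outdir / "nucleus_stats.tsv", sep="\t")

    mut = df[df["genotype"] == "mutant"]["integrated_intensity"]
    ctrl = df[df["genotype"] == "control"]["integrated_intensity"]
    ratio, p = img_mod.group_fold_change(mut, ctrl)
    ent_cmp = img_mod.compare_groups(
        df[df["genotype"] == "mutant"]["entropy"],
        df[df["genotype"] == "control"]["entropy"],
    )
    return {
        "planted_intensity_ratio": img_cfg.mutant_intensity_ratio,
        "recovered_intensity_ratio": float(ratio),
        "intensity_p": float(p),
        "entropy_t_p": ent_cmp.p_value,
        "entropy_groups_normal": ent_cmp.normality_ok,
        "n_nuclei_per_group": img_cfg.n_nuclei,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns (and writes) the JSON report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config": {
            name: dataclasses.asdict(getattr(config, name)) for name in _SECTION_TYPES
        },
    }
    stage_fns = {
        "counts": _counts_stage,
        "repeats": _repeats_stage,
        "images": _images_stage,
    }
    for stage in config.stages:
        report[stage] = stage_fns[stage](config, outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
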