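"""End-to-end orchestration: demo dataset generation and the staged pipeline.

``make_demo`` writes a complete synthetic dataset (genome, gene models,
fragments per condition and replicate, counts, ground-truth tables) plus a
ready-to-run YAML config.  ``run_pipeline`` executes the stages in order —
profiles, peaks, DPNs, phasing, mapping, metaprofiles, clustering, DE,
overlap — writing plain-text outputs and a run manifest; a rerun with the
same config is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, expression, genes as gene_context, phasing, profiles, synthetic

log = logging.getLogger("nucdyn")

STAGES = (
    "profiles",
    "peaks",
    "dpns",
    "phasing",
    "mapping",
    "metaprofiles",
    "clustering",
    "de",
    "overlap",
)

DEMO_SCALES = {
    # genome bp, n genes, fragments per sample, counts replicates
    "default": dict(length=2_000_000, n_genes=300, n_fragments=600_000, n_reps=3),
    "tiny": dict(length=300_000, n_genes=40, n_fragments=60_000, n_reps=3),
}

#: planted treatment patterns for induced genes, cycled gene by gene; they
#: mirror six archetypes: body loss, +2 loss, promoter loss, +2 gain,
#: +1 gain, and -1 gain.
INDUCED_EFFECT_CYCLE = (
    ("body_depletion", 0.5),
    ("plus2_gain", -0.5),
    ("promoter_depletion", 0.5),
    ("plus2_gain", 0.75),
    ("plus1_gain", 0.75),
    ("minus1_gain", 0.75),
)
REPRESSED_EFFECT = ("body_depletion", -0.5)  # negative depletion = body gain


@dataclass
class PipelineConfig:
    fragments: dict  # condition -> list of BED paths
    gene_models: str
    counts: str
    genome: str  # TSV chrom, length
    out_dir: str
    seed: int = 0
    fdr: float = 0.01
    padj: float = 0.05
    fc: float = 1.5
    promoter: int = 1000
    tss_halfwidth: int = 90
    k: int = 6
    max_dist: int = 1500
    bandwidth: int = 36
    min_height: float | None = None
    min_distance: int = 120
    max_shift: int = 90
    bin_size: int = 10
    window: tuple = (-1000, 1500)
    universe_size: int | None = None  # None: all genes in the annotation
    term_map: str | None = None
    reference_condition: str = "mock"

    def validate(self) -> None:
        for name in ("fdr", "padj"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.fc <= 1:
            raise ValueError("fold-change threshold must exceed 1")
        if self.promoter <= 0:
            raise ValueError("promoter length must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(self.fragments) != 2:
            raise ValueError("exactly two conditions required")
        if self.reference_condition not in self.fragments:
            raise ValueError(f"reference condition {self.reference_condition!r} missing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_genome_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def make_demo(outdir, scale: str = "default", seed: int = 42) -> Path:
    """Write a synthetic two-condition dataset plus a ready config.

    Returns the path of the written config file.  Ground-truth tables
    (nucleosome landscapes per condition and the planted per-gene effects)
    are written alongside so tests can compare calls against truth.
    """
    if scale not in DEMO_SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(DEMO_SCALES)}")
    params = DEMO_SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, genes = synthetic.make_genome(1, params["length"], params["n_genes"], seed)
    effects = demo_effect_plan(genes)
    mock, treated = synthetic.make_landscape(genome, genes, effects, seed=seed)

    pd.DataFrame(
        {"chrom": genome.chrom_names, "length": genome.chrom_lengths}
    ).to_csv(outdir / "genome.tsv", sep="\t", index=False)
    synthetic.write_gene_models(genes, outdir / "genes.tsv")
    mock.to_csv(outdir / "truth_landscape_mock.tsv", sep="\t", index=False)
    treated.to_csv(outdir / "truth_landscape_treated.tsv", sep="\t", index=False)
    effect_rows = [
        (g, cls, mag, effects.expression.get(g, 0.0))
        for g in genes["gene_id"]
        for cls, mag in [effects.effect_for(g)]
    ]
    pd.DataFrame(
        effect_rows, columns=["gene_id", "effect_class", "magnitude", "log2fc"]
    ).to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)

    frag_paths: dict = {}
    for cond, truth in (("mock", mock), ("treated", treated)):
        frag_paths[cond] = []
        for rep in (1, 2):
            frags = synthetic.sample_fragments(
                truth,
                genome,
                params["n_fragments"],
                seed=seed,
                stream=f"fragments_{cond}_rep{rep}",
            )
            p = outdir / f"fragments_{cond}_rep{rep}.bed"
            synthetic.write_fragments_bed(frags, p)
            frag_paths[cond].append(str(p))

    rng = synthetic.rng_for(seed, "demo_count_truth")
    base = np.exp(rng.normal(np.log(100.0), 1.0, len(genes)))
    lfc = np.array([effects.expression.get(g, 0.0) for g in genes["gene_id"]])
    count_truth = synthetic.CountTruth(
        genes["gene_id"].tolist(), base, np.full(len(genes), 0.1), lfc,
        n_replicates=params["n_reps"],
    )
    counts = synthetic.sample_counts(count_truth, seed)
    counts.to_csv(outdir / "counts.tsv", sep="\t")

    cfg = PipelineConfig(
        fragments=frag_paths,
        gene_models=str(outdir / "genes.tsv"),
        counts=str(outdir / "counts.tsv"),
        genome=str(outdir / "genome.tsv"),
        out_dir=str(outdir / "results"),
        seed=seed,
    )
    cfg_path = outdir / "config.yaml"
    cfg.to_yaml(cfg_path)
    return cfg_path


def demo_effect_plan(genes: pd.DataFrame) -> synthetic.EffectPlan:
    """Planted effects for the demo: induced genes with six occupancy-change
    archetypes, repressed genes with gene-body occupancy gain, plus a few
    pure shift and fuzziness changes among non-DE genes."""
    gids = genes["gene_id"].tolist()
    n = len(gids)
    n_ind = max(6, round(0.13 * n))
    n_rep = max(3, round(0.10 * n))
    n_shift = max(2, round(0.03 * n))
    n_fuzz = max(2, round(0.03 * n))
    nuc, expr = {}, {}
    i = 0
    for j in range(n_ind):
        nuc[gids[i]] = INDUCED_EFFECT_CYCLE[j % len(INDUCED_EFFECT_CYCLE)]
        expr[gids[i]] = 2.0
        i += 1
    for _ in range(n_rep):
        nuc[gids[i]] = REPRESSED_EFFECT
        expr[gids[i]] = -2.0
        i += 1
    for _ in range(n_shift):
        nuc[gids[i]] = ("shift", 30.0)
        i += 1
    for _ in range(n_fuzz):
        nuc[gids[i]] = ("fuzz_change", 1.8)
        i += 1
    return synthetic.EffectPlan(nucleosome=nuc, expression=expr)


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest dictionary.

    Fails fast (and removes partial outputs) if an input is missing.
    Replicate fragment files are pooled per condition before peak calling,
    and all comparisons are treated-vs-mock.
    """
    config.validate()
    for cond, paths in config.fragments.items():
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"stage profiles: missing fragment file {p}")
    for name in ("gene_models", "counts", "genome"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"stage profiles: missing input {p}")

    out = Path(config.out_dir)
    if out.exists():
        shutil.rmtree(out)
    out.mkdir(parents=True)
    manifest: dict = {
        "stages": [],
        "seed": config.seed,
        "parameters": {
            k: v for k, v in config.__dict__.items() if k not in ("fragments",)
        },
        "inputs": {
            cond: {p: _md5(p) for p in paths}
            for cond, paths in config.fragments.items()
        },
        "counts_records": {},
    }
    manifest["parameters"]["window"] = list(config.window)

    chrom_lengths = read_genome_table(config.genome)
    genes = gene_context.read_gene_models(config.gene_models)
    ref = config.reference_condition
    trt = [c for c in config.fragments if c != ref][0]

    # --- profiles -----------------------------------------------------------
    frags = {
        cond: pd.concat([profiles.read_bed3(p) for p in paths], ignore_index=True)
        for cond, paths in config.fragments.items()
    }
    tracks = {
        cond: profiles.midpoint_coverage(df, chrom_lengths, config.bandwidth)
        for cond, df in frags.items()
    }
    (scaled_ref, scaled_trt), factors = profiles.normalize_depth(
        [tracks[ref], tracks[trt]]
    )
    tracks = {ref: scaled_ref, trt: scaled_trt}
    for cond, t in tracks.items():
        profiles.write_bedgraph(t, out / f"occupancy_{cond}.bedgraph")
    _stage_done(manifest, "profiles", {f"n_fragments_{c}": len(frags[c]) for c in frags})

    # --- peaks --------------------------------------------------------------
    peaks = {
        cond: calling.call_peaks(t, config.min_height, config.min_distance)
        for cond, t in tracks.items()
    }
    for cond, pk in peaks.items():
        pk.to_csv(out / f"peaks_{cond}.tsv", sep="\t", index=False)
    _stage_done(manifest, "peaks", {f"n_peaks_{c}": len(p) for c, p in peaks.items()})

    # --- dpns ---------------------------------------------------------------
    idx = {cond: calling.FragmentIndex.from_fragments(df) for cond, df in frags.items()}
    pairs = calling.match_peaks(peaks[ref], peaks[trt], config.max_shift)
    scored = calling.score_pairs(pairs, idx[ref], idx[trt])
    dpns = calling.call_dpns(scored, config.fdr)
    dpns.to_csv(out / "dpns.tsv", sep="\t", index=False)
    calling.dpns_to_bed(dpns).to_csv(
        out / "dpns.bed", sep="\t", header=False, index=False
    )
    _stage_done(
        manifest, "dpns",
        {"n_pairs": len(dpns), "n_dpns": int(dpns["is_dpn"].sum())},
    )

    # --- phasing ------------------------------------------------------------
    phase = {}
    for cond, df in frags.items():
        hist = phasing.phasogram(df, config.max_dist)
        fit = phasing.estimate_phase(hist)
        pd.DataFrame({"distance": fit.distances, "count": fit.counts.astype(int)}).to_csv(
            out / f"phasogram_{cond}.tsv", sep="\t", index=False
        )
        phase[cond] = {
            "slope_bp_per_nucleosome": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "peaks": fit.peaks.tolist(),
        }
    if len(chrom_lengths) >= 3:
        sl_ref = phasing.per_chromosome_slopes(frags[ref], config.max_dist)
        sl_trt = phasing.per_chromosome_slopes(frags[trt], config.max_dist)
        chroms = sorted(set(sl_ref) & set(sl_trt))
        phase["paired_t_p"] = phasing.compare_phase(
            [sl_ref[c] for c in chroms], [sl_trt[c] for c in chroms]
        )
    with open(out / "phase.json", "w") as fh:
        json.dump(phase, fh, indent=1)
    _stage_done(
        manifest, "phasing",
        {f"slope_{c}": phase[c]["slope_bp_per_nucleosome"] for c in frags},
    )

    # --- mapping ------------------------------------------------------------
    regions = gene_context.assign_regions(
        genes, chrom_lengths, config.promoter, config.tss_halfwidth
    )
    flagged = dpns[dpns["is_dpn"]]
    gene_hits = gene_context.map_dpns_to_genes(flagged, regions)
    gene_hits.to_csv(out / "dpn_genes.tsv", sep="\t", index=False)
    region_counts = gene_context.count_dpns_by_region(flagged, regions)
    with open(out / "dpn_region_counts.json", "w") as fh:
        json.dump(region_counts, fh, indent=1)
    dpn_genes = sorted(gene_hits["gene_id"].unique())
    _stage_done(
        manifest, "mapping",
        {"n_dpn_genes": len(dpn_genes), "region_counts": region_counts},
    )

    # --- metaprofiles -------------------------------------------------------
    anchors = gene_context.locate_plus1(peaks[ref], genes)
    mp = {
        cond: gene_context.metaprofile(
            t, genes, anchors, config.window, config.bin_size
        )
        for cond, t in tracks.items()
    }
    dmp = gene_context.differential_metaprofile(
        tracks[trt], tracks[ref], genes, anchors, config.window, config.bin_size
    )
    for cond, m in mp.items():
        m.to_frame().to_csv(out / f"metaprofile_{cond}.tsv", sep="\t")
    dmp.to_frame().to_csv(out / "metaprofile_diff.tsv", sep="\t")
    _stage_done(
        manifest, "metaprofiles",
        {"n_genes_profiled": len(dmp.gene_ids), "n_no_plus1": dmp.n_excluded},
    )

    # --- clustering ---------------------------------------------------------
    diff_frame = dmp.to_frame()
    cluster_rows = diff_frame.loc[diff_frame.index.isin(dpn_genes)]
    if len(cluster_rows) >= config.k:
        sub = gene_context.MetaProfileMatrix(
            cluster_rows.index.tolist(),
            dmp.positions,
            cluster_rows.to_numpy(),
            dmp.bin_size,
        )
        clusters = gene_context.cluster_profiles(sub, config.k, config.seed)
        clusters.assignments.rename_axis("gene_id").to_frame().to_csv(
            out / "clusters.tsv", sep="\t"
        )
        sizes = clusters.assignments.value_counts().sort_index().to_dict()
    else:
        sizes = {}
        log.warning("clustering skipped: only %d DPN genes", len(cluster_rows))
    _stage_done(manifest, "clustering", {"cluster_sizes": {str(k): v for k, v in sizes.items()}})

    # --- de -----------------------------------------------------------------
    counts = expression.read_counts(config.counts)
    cond_labels = [c.rsplit("_", 1)[0] for c in counts.columns]
    de = expression.test_de(counts, cond_labels, config.padj, config.fc, reference=ref)
    de.table.to_csv(out / "de.tsv", sep="\t")
    _stage_done(
        manifest, "de",
        {"n_induced": len(de.induced), "n_repressed": len(de.repressed),
         "n_excluded": de.n_excluded},
    )

    # --- overlap ------------------------------------------------------------
    universe = config.universe_size or len(genes)
    res = {}
    for label, deg in (("induced", de.induced), ("repressed", de.repressed)):
        ov = expression.classify_overlap(deg, dpn_genes, universe)
        res[label] = {
            "universe": ov.universe, "degs": ov.set_size, "dpn_genes": ov.draw_size,
            "overlap": ov.overlap, "expected": ov.expected, "p": ov.p_value,
        }
    if config.term_map:
        term_map = pd.read_csv(config.term_map, sep="\t")
        enr = expression.term_enrichment(
            de.induced, genes["gene_id"], term_map
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    with open(out / "overlap.json", "w") as fh:
        json.dump(res, fh, indent=1)
    _stage_done(manifest, "overlap", {k: v["overlap"] for k, v in res.items()})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stage_done(manifest: dict, stage: str, counts: dict) -> None:
    manifest["stages"].append(stage)
    manifest["counts_records"][stage] = counts
    log.info("stage %-13s %s", stage, counts)
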