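"""End-to-end orchestration: simulate or load inputs, run every analysis
stage in dependency order, and write artifacts plus a machine-readable
manifest.

Defaults reproduce the reference analysis protocol: scan cutoff >= 80 bp with unmapped
contigs excluded, nine MCMC chains of 1e5 iterations thinned by ten, 100
dinucleotide shuffles per element, 60 bp core/flank composition windows,
and 1 kb selection flanks. One seed controls the full run; rerunning with
the same config reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment_scan import (
    elements_to_bed,
    elements_to_fasta,
    elements_to_table,
    filter_unmapped,
    length_summary,
    name_elements,
    scan_ultraconserved,
)
from .composition import at_profile, classify_overlap, genic_table, wilcoxon_rank_sum
from .maf import read_maf, write_maf
from .phylo import deceleration_lrt, fit_background_model
from .rna import length_zscore_correlation, mfe_zscore
from .selection import (
    McmcConfig,
    observations_to_frame,
    read_sfs_table,
    run_mcmc,
    summarize_posterior,
)
from .simulate import (
    SfsClassConfig,
    SimulationConfig,
    default_model,
    simulate_alignment,
    simulate_sfs,
    toy_annotation_generator,
)

log = logging.getLogger("ucekit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "report_summary"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the reference protocol settings."""

    seed: int = 0
    simulate: bool = True
    # inputs for non-simulated runs
    maf_path: str | None = None
    sfs_path: str | None = None
    ref_species: str = "dm3"
    # scan
    min_len: int = 80
    exclude_chroms: tuple[str, ...] = ("chrU*",)
    # selection MCMC
    chains: int = 9
    iters: int = 100_000
    thin: int = 10
    ascertained: tuple[str, ...] = ("UCE",)
    div_intensity: float = 0.0
    # RNA
    shuffles: int = 100
    # composition
    core_width: int = 60
    flank_width: int = 60
    selection_flank: int = 1000
    # phylo
    phylo_fit_columns: int = 5000
    # simulation sizes (scaled-down defaults; see docs/methods.md)
    sim_genome_length: int = 50_000
    sim_n_planted: int = 5
    sim_planted_lengths: tuple[int, ...] = (80, 90, 100, 120, 192)
    sim_sfs_classes: tuple = (
        ("UCE", -20.0, 4.0, 137, 130),
        ("flanking", -1.9, 1.0, 1000, 130),
        ("nonsynonymous", -2.6, 1.0, 1000, 130),
    )
    sim_annotation_genes: int = 8
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate",
        "scan",
        "phylo",
        "selection",
        "rna",
        "composition",
        "annotation",
    )


def _plant_positions(config: PipelineConfig, rng: np.random.Generator,
                     block_width: int = 1000):
    lengths = list(config.sim_planted_lengths)[: config.sim_n_planted]
    while len(lengths) < config.sim_n_planted:
        lengths.append(int(rng.integers(80, 200)))
    gap = config.sim_genome_length // (len(lengths) + 1)
    planted = []
    for k, L in enumerate(lengths):
        start = (k + 1) * gap + int(rng.integers(-gap // 4, gap // 4))
        # keep the interval inside a single emitted block (the scan does not
        # stitch runs across block boundaries)
        block = start // block_width
        if start + L > (block + 1) * block_width:
            start = (block + 1) * block_width - L
        start = max(start, block * block_width)
        planted.append((start, L, 0.0))
    return planted


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the configured stages and return the manifest (also written).

    Missing inputs abort before any stage runs; a stage failure leaves a
    partial manifest marking the completed stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        for path, stage in ((config.maf_path, "scan"), (config.sfs_path, "selection")):
            if stage in config.stages and (path is None or not Path(path).exists()):
                raise FileNotFoundError(
                    f"stage {stage!r} requires an input file; got {path!r}"
                )
    manifest = {
        "ucekit_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "artifacts": {},
    }

    def record(stage, status, **artifacts):
        manifest["stages"][stage] = status
        for key, path in artifacts.items():
            manifest["artifacts"][key] = str(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    rng = np.random.default_rng(config.seed)
    ref_genome = None
    truth = None
    toy = None
    elements = []
    sfs_data = None

    try:
        if "simulate" in config.stages and config.simulate:
            log.info("simulate: genome %d bp", config.sim_genome_length)
            planted = _plant_positions(config, rng)
            sim = SimulationConfig(
                seed=config.seed,
                genome_length=config.sim_genome_length,
                planted=planted,
                ref_species=config.ref_species,
            )
            blocks, truth = simulate_alignment(sim, rng)
            maf_path = out / "alignment.maf"
            write_maf(blocks, maf_path)
            truth_bed = out / "truth.bed"
            truth_bed.write_text(
                "".join(f"{c}\t{s}\t{e}\tplanted.{k + 1}\t{e - s}\t+\n"
                        for k, (c, s, e) in enumerate(truth))
            )
            ref_genome = "".join(b.rows[config.ref_species].text for b in blocks)
            class_cfgs = [
                SfsClassConfig(lab, mu, s2, n_sites, n)
                for lab, mu, s2, n_sites, n in config.sim_sfs_classes
            ]
            sfs_data, sfs_truth = simulate_sfs(class_cfgs, rng)
            sfs_path = out / "sfs.tsv"
            observations_to_frame(sfs_data).to_csv(sfs_path, sep="\t", index=False)
            (out / "sfs_truth.json").write_text(json.dumps(sfs_truth))
            toy = toy_annotation_generator(config.sim_annotation_genes, rng)
            (out / "annotations.gff3").write_text(toy.gff3)
            config = dataclasses.replace(config, maf_path=str(maf_path),
                                         sfs_path=str(sfs_path))
            record("simulate", "done", maf=maf_path, truth_bed=truth_bed,
                   sfs=sfs_path, gff3=out / "annotations.gff3")

        if "scan" in config.stages:
            blocks = list(read_maf(config.maf_path, config.ref_species))
            raw = scan_ultraconserved(blocks, min_len=config.min_len)
            kept, n_removed = filter_unmapped(raw, list(config.exclude_chroms))
            elements = name_elements(kept)
            (out / "elements.bed").write_text(elements_to_bed(elements))
            (out / "elements.fa").write_text(elements_to_fasta(elements))
            (out / "elements.tsv").write_text(elements_to_table(elements))
            summary = length_summary(elements)
            summary["n_removed_unmapped"] = n_removed
            (out / "length_summary.json").write_text(json.dumps(summary))
            record("scan", "done", elements_bed=out / "elements.bed",
                   elements_fasta=out / "elements.fa",
                   length_summary=out / "length_summary.json")

        if "phylo" in config.stages and elements:
            blocks = list(read_maf(config.maf_path, config.ref_species))
            tree = default_model().tree
            cols = _sample_columns(blocks, tree, config.phylo_fit_columns, config.seed)
            model = fit_background_model(cols, tree, model_kind="HKY")
            (out / "phylo_model.txt").write_text(model.to_text())
            rows = []
            for e in elements:
                ecols = _element_columns(blocks, tree, e)
                res = deceleration_lrt(ecols, model, element_name=e.name or "")
                rows.append(dataclasses.asdict(res))
            pd.DataFrame(rows).to_csv(out / "phylo_tests.tsv", sep="\t", index=False)
            record("phylo", "done", model=out / "phylo_model.txt",
                   phylo_tests=out / "phylo_tests.tsv")

        if "selection" in config.stages:
            data = sfs_data if sfs_data is not None else read_sfs_table(config.sfs_path)
            mcfg = McmcConfig(
                n_chains=config.chains, n_iters=config.iters, thin=config.thin,
                seed=config.seed,
                ascertained=frozenset(config.ascertained) & set(data),
                div_intensity=config.div_intensity,
            )
            result = run_mcmc(data, mcfg)
            summary = summarize_posterior(result)
            summary.to_frame().to_csv(out / "selection_summary.tsv", sep="\t",
                                      index=False)
            flat = result.samples.reshape(-1, result.samples.shape[-1])
            cols = [f"{lab}_{p}" for lab in result.class_labels
                    for p in ("mu", "log_sigma")]
            pd.DataFrame(flat, columns=cols).to_csv(out / "selection_chains.tsv",
                                                    sep="\t", index=False)
            (out / "selection_psrf.json").write_text(json.dumps(
                {"psrf": summary.psrf,
                 "acceptance": result.acceptance.tolist(),
                 "flagged_chains": result.flagged_chains}))
            record("selection", "done", selection_summary=out / "selection_summary.tsv",
                   selection_chains=out / "selection_chains.tsv",
                   selection_psrf=out / "selection_psrf.json")

        if "rna" in config.stages and elements:
            rna_rng = np.random.default_rng([config.seed, 7])
            rows = []
            for e in elements:
                zr = mfe_zscore(e.sequence, n_shuffles=config.shuffles, rng=rna_rng)
                rows.append({"name": e.name, "length": e.length,
                             "mfe": zr.observed_mfe, "shuffle_mean": zr.shuffle_mean,
                             "shuffle_sd": zr.shuffle_sd, "z": zr.z})
            df = pd.DataFrame(rows)
            df.to_csv(out / "rna_zscores.tsv", sep="\t", index=False)
            corr = None
            finite = df["z"].notna().sum()
            if finite >= 3 and df.loc[df["z"].notna(), "z"].nunique() > 1:
                corr = length_zscore_correlation(df.to_dict("records"))
            (out / "rna_correlation.json").write_text(json.dumps(corr))
            record("rna", "done", rna_zscores=out / "rna_zscores.tsv",
                   rna_correlation=out / "rna_correlation.json")

        if "composition" in config.stages and elements and ref_genome is not None:
            rows = []
            for e in elements:
                if (e.length < config.core_width
                        or e.start < config.flank_width
                        or e.end + config.flank_width > len(ref_genome)):
                    continue
                rec = at_profile(
                    e.sequence,
                    ref_genome[e.start - config.flank_width : e.start],
                    ref_genome[e.end : e.end + config.flank_width],
                    core_width=config.core_width, flank_width=config.flank_width,
                    name=e.name or "",
                )
                rows.append(dataclasses.asdict(rec))
            comp = pd.DataFrame(rows)
            result = {"n_elements": len(comp)}
            if len(comp) >= 2:
                test = wilcoxon_rank_sum(comp["core_at"], comp["flank_at"])
                result.update(
                    mean_core_at=float(comp["core_at"].mean()),
                    mean_flank_at=float(comp["flank_at"].mean()), **test)
            comp.to_csv(out / "composition.tsv", sep="\t", index=False)
            (out / "composition_test.json").write_text(json.dumps(result))
            record("composition", "done", composition=out / "composition.tsv",
                   composition_test=out / "composition_test.json")

        if "annotation" in config.stages and elements and toy is not None:
            overlap = classify_overlap(elements, toy.annotations)
            (out / "annotation_fractions.json").write_text(
                json.dumps({"fractions": overlap["fractions"],
                            "total_bases": overlap["total_bases"]}))
            gt = genic_table(elements, toy.genes)
            gt.to_csv(out / "genic_table.tsv", sep="\t", index=False)
            record("annotation", "done",
                   annotation_fractions=out / "annotation_fractions.json",
                   genic_table=out / "genic_table.tsv")
    except Exception:
        record("FAILED", "error")
        raise
    return manifest


def _sample_columns(blocks, tree, n_columns, seed):
    """Random alignment columns (tree leaf order) for background fitting."""
    from .phylo import MISSING, _BASE_INDEX

    mats = []
    for block in blocks:
        rows = []
        for name in tree.leaf_names:
            if name in block.rows:
                text = block.rows[name].text.upper()
                rows.append([_BASE_INDEX.get(c, MISSING) for c in text])
            else:
                rows.append([MISSING] * block.width)
        mats.append(np.array(rows, dtype=np.int8))
    full = np.concatenate(mats, axis=1)
    rng = np.random.default_rng([seed, 13])
    idx = rng.choice(full.shape[1], size=min(n_columns, full.shape[1]), replace=False)
    return full[:, idx]


def _element_columns(blocks, tree, element):
    """Alignment columns covering one element (ungapped reference assumed)."""
    from .phylo import MISSING, _BASE_INDEX

    cols = []
    for block in blocks:
        ref = block.ref_row
        if ref.chrom != element.chrom:
            continue
        b_start, b_end = ref.start, ref.start + ref.size
        lo, hi = max(b_start, element.start), min(b_end, element.end)
        if lo >= hi:
            continue
        # map reference coordinates to alignment columns
        text = ref.text
        ref_positions = np.cumsum([c != "-" for c in text]) - 1 + b_start
        mask = np.zeros(len(text), dtype=bool)
        gapless = np.array([c != "-" for c in text])
        mask[gapless] = (ref_positions[gapless] >= lo) & (ref_positions[gapless] < hi)
        sub = []
        for name in tree.leaf_names:
            row = block.rows.get(name)
            if row is None:
                sub.append([MISSING] * int(mask.sum()))
            else:
                chars = np.array(list(row.text.upper()))[mask]
                sub.append([_BASE_INDEX.get(c, MISSING) for c in chars])
        cols.append(np.array(sub, dtype=np.int8))
    mats = [c for c in cols if isinstance(c, np.ndarray)]
    if not mats:
        raise ValueError(f"element {element.name} not covered by any block")
    return np.concatenate(mats, axis=1)


def report_summary(run_dir) -> str:
    """Human-readable report assembled from a run directory's artifacts."""
    run = Path(run_dir)
    lines = ["# ucekit run report", ""]
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        return "\n".join(lines + ["(no manifest found; all sections unavailable)"])
    manifest = json.loads(manifest_path.read_text())
    lines.append(f"ucekit version: {manifest.get('ucekit_version')}")
    lines.append(f"seed: {manifest.get('seed')}")
    lines.append("")

    def section(title, path, render):
        lines.append(f"## {title}")
        full = run / path
        if not full.exists():
            lines.append("(unavailable)")
        else:
            try:
                lines.extend(render(full))
            except Exception as exc:  # a bad artifact should not kill the report
                lines.append(f"(unreadable: {exc})")
        lines.append("")

    def render_lengths(p):
        d = json.loads(p.read_text())
        out = [f"elements: {d['count']}  min: {d['min']}  max: {d['max']}"]
        for length, count in sorted(d["histogram"].items(), key=lambda kv: int(kv[0])):
            out.append(f"  {length} bp: {'#' * count} ({count})")
        return out

    def render_selection(p):
        df = pd.read_csv(p, sep="\t")
        out = [df.to_string(index=False)]
        truth_path = run / "sfs_truth.json"
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())
            out.append("truth (mu, sigma2): " + json.dumps(truth))
        psrf_path = run / "selection_psrf.json"
        if psrf_path.exists():
            out.append(f"PSRF: {json.loads(psrf_path.read_text())['psrf']:.4f}")
        return out

    def render_tsv(p):
        return [pd.read_csv(p, sep="\t").to_string(index=False)]

    def render_json(p):
        return [json.dumps(json.loads(p.read_text()), indent=2)]

    section("Element length distribution", "length_summary.json", render_lengths)
    section("Selection coefficients (2Ns) by site class",
            "selection_summary.tsv", render_selection)
    section("Phylogenetic conservation tests", "phylo_tests.tsv", render_tsv)
    section("RNA structure z-scores", "rna_zscores.tsv", render_tsv)
    section("Annotation overlap fractions", "annotation_fractions.json", render_json)
    section("Core/flank A+T composition", "composition_test.json", render_json)
    return "\n".join(lines)
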