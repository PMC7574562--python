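"""End-to-end pipeline runner: simulate -> QC -> karyotype -> titrate ->
DMR -> enrichment -> fetal fraction, with a provenance manifest.

Stages run in the order the analyses depend on one another; any stage
failure aborts the run with the stage name while keeping the artifacts
already written. A fixed seed makes the whole run (and its output TSVs)
byte-identical across repeats.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .coverage import chrom_stats, hellinger, window_stats
from .dmr import bh_fdr, dmr_lrt, normalize_window_features
from .enrichment import probe_dmr_enrichment, site_enrichment, top_signal_windows
from .fetal_fraction import bin_counts, fit_ff, predict_ff
from .karyotyping import (DEFAULT_REFERENCE, classify_cohort,
                          chrom_ratio_zscores, depth_titration)
from .ordination_qc import bray_curtis, flag_outliers, nmds
from .synthetic_data import (CohortConfig, GenomeConfig, build_genome,
                             simulate_cohort)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (one assay)."""

    out_dir: str = "epinipt_out"
    seed: int = 0
    assay: str = "uCG"
    target_chrom: str = "chr21a"
    ref_chrom: str | None = None           # default per-assay reference
    dmr_window: int = 100
    enrichment_window: int = 1000
    q_threshold: float = 0.05
    nominal_threshold: float = 0.05
    use_nominal_p: bool = False            # nominal-p DMR calling switch
    outlier_k: float = 2.0
    titration_human_depths: tuple[float, ...] = (1e6, 3e6, 5e6)
    titration_reps: int = 30
    ff_bin_width: int = 50_000
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        for thr in (self.q_threshold, self.nominal_threshold):
            if not 0.0 < thr < 1.0:
                raise ValueError("significance thresholds must lie in (0, 1)")
        for w in (self.dmr_window, self.enrichment_window, self.ff_bin_width):
            if w <= 0:
                raise ValueError("window widths must be positive")
        if self.seed is None:
            raise ValueError("a seed is required")
        self.genome.validate()
        self.cohort.validate()
        chrom_names = [c[0] for c in self.genome.chroms]
        if self.target_chrom not in chrom_names:
            raise ValueError(f"target chromosome {self.target_chrom!r} not in genome")
        ref = self.resolved_ref()
        if ref not in chrom_names:
            raise ValueError(f"reference chromosome {ref!r} not in genome")
        if ref == self.target_chrom:
            raise ValueError("reference chromosome must differ from the target")

    def resolved_ref(self) -> str:
        return self.ref_chrom or DEFAULT_REFERENCE.get(self.assay, "chr16a")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genome = raw.pop("genome", {})
        if "chroms" in genome:
            genome["chroms"] = tuple((str(n), int(l)) for n, l in genome["chroms"])
        cohort = raw.pop("cohort", {})
        if "ff_range" in cohort:
            cohort["ff_range"] = tuple(cohort["ff_range"])
        if "titration_human_depths" in raw:
            raw["titration_human_depths"] = tuple(raw["titration_human_depths"])
        return cls(genome=GenomeConfig(**genome), cohort=CohortConfig(**cohort), **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ["genome", "cohort", "nmds", "titration"], ss.spawn(4))}
    manifest: dict = {
        "seed": config.seed,
        "assay": config.assay,
        "target_chrom": config.target_chrom,
        "ref_chrom": config.resolved_ref(),
        "outlier_k": config.outlier_k,
        "q_threshold": config.q_threshold,
        "rng": "numpy PCG64 via SeedSequence",
        "outputs": {},
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, assay=config.assay)
        genome = build_genome(
            config.genome, int(seeds["genome"].generate_state(1)[0] % 2**31)
        )
        matrix, meta, truth = simulate_cohort(genome, cohort_cfg, seeds["cohort"])
        eio.write_cg_catalog(genome.sites, out / "cg_catalog.bed"); emit("cg_catalog", out / "cg_catalog.bed")
        eio.write_counts(matrix, out / "counts.tsv"); emit("counts", out / "counts.tsv")
        eio.write_metadata(meta, out / "metadata.tsv"); emit("metadata", out / "metadata.tsv")
        eio.write_truth(truth, out / "truth.json"); emit("truth", out / "truth.json")
        eio.write_annotations(genome, out / "annotations.bed"); emit("annotations", out / "annotations.bed")

        stage = "qc"
        h = hellinger(matrix.counts, matrix.sample_ids)
        d = bray_curtis(h, matrix.sample_ids)
        ord_res = nmds(d, restarts=10,
                       seed=int(seeds["nmds"].generate_state(1)[0] % 2**31))
        groups = [m.group for m in meta]
        flags = flag_outliers(ord_res.embedding, groups, k=config.outlier_k,
                              sample_ids=matrix.sample_ids)
        emb = pd.DataFrame(ord_res.embedding, columns=["nMDS1", "nMDS2"])
        emb.insert(0, "sample_id", matrix.sample_ids)
        emb["stress"] = ord_res.stress
        eio.write_table(emb, out / "nmds_embedding.tsv"); emit("embedding", out / "nmds_embedding.tsv")
        eio.write_table(flags, out / "outliers.tsv"); emit("outliers", out / "outliers.tsv")
        keep_ids = flags.loc[~flags["outlier"], "sample_id"].tolist()
        matrix = matrix.subset_samples(keep_ids)
        meta = [m for m in meta if m.sample_id in set(keep_ids)]

        stage = "karyotype"
        ref = config.resolved_ref()
        cs = chrom_stats(matrix)
        eio.write_table(cs, out / "chrom_stats.tsv"); emit("chrom_stats", out / "chrom_stats.tsv")
        healthy_ids = [m.sample_id for m in meta if m.group == "pregnant_healthy"]
        ztabs = []
        for kind in ("coverage", "fraction"):
            zt = chrom_ratio_zscores(cs, config.target_chrom, ref, healthy_ids,
                                     signal_kind=kind)
            ztabs.append(zt)
        eio.write_table(pd.concat(ztabs), out / "zscores.tsv"); emit("zscores", out / "zscores.tsv")
        plasma = [m for m in meta
                  if m.group in ("NPC", "pregnant_healthy", "pregnant_T21")]
        plasma_ids = [m.sample_id for m in plasma]
        is_t21 = np.array([m.group == "pregnant_T21" for m in plasma])
        eval_mask = np.array([m.group != "NPC" for m in plasma])
        plasma_matrix = matrix.subset_samples(plasma_ids)
        cv = classify_cohort(plasma_matrix, is_t21, ~is_t21,
                             config.target_chrom, ref, "fraction",
                             eval_mask=eval_mask)
        manifest["loocv_auc_fraction"] = cv.auc
        manifest["loocv_accuracy_fraction"] = cv.accuracy

        stage = "titrate"
        depths = sorted({genome.scale_depth(p) for p in config.titration_human_depths})
        depths = [d for d in depths if d <= plasma_matrix.totals().min()]
        if depths:
            curve = depth_titration(
                plasma_matrix, is_t21, depths, config.target_chrom, ref,
                "fraction", eval_mask=eval_mask,
                n_reps=config.titration_reps,
                seed=int(seeds["titration"].generate_state(1)[0] % 2**31),
            )
            eio.write_table(curve.table, out / "titration.tsv"); emit("titration", out / "titration.tsv")

        stage = "dmr"
        ws = window_stats(matrix, width=config.dmr_window)
        feats = normalize_window_features(ws, cs, ref).subset_chrom(config.target_chrom)
        labels = np.array([m.group != "NPC" for m in meta])  # pregnancy contrast
        npc_or_preg = np.array([m.group in ("NPC", "pregnant_healthy") for m in meta])
        sub_ids = [m.sample_id for m, keep in zip(meta, npc_or_preg) if keep]
        sub_feats = feats.subset_samples(sub_ids)
        sub_labels = labels[npc_or_preg]
        table = dmr_lrt(sub_feats, sub_labels)
        table["q"] = bh_fdr(table["p"].to_numpy())
        thr_col, thr = (("p", config.nominal_threshold) if config.use_nominal_p
                        else ("q", config.q_threshold))
        table["significant"] = table[thr_col] < thr
        eio.write_table(table, out / "dmr.tsv"); emit("dmr", out / "dmr.tsv")

        stage = "enrich"
        tops = top_signal_windows(matrix, [m.group for m in meta],
                                  width=config.enrichment_window)
        rows = []
        group0 = sorted(tops)[0]
        for name, by_chrom in genome.annotations.items():
            res = site_enrichment(tops[group0], by_chrom, genome.sites, name=name)
            rows.append({"annotation": name, "group": group0,
                         "odds_ratio": res.odds_ratio, "p": res.p,
                         "overlap_fraction": res.overlap_fraction})
        sig = table[table["significant"]]
        dmr_iv = {
            c: grp[["start", "end"]].to_numpy()
            for c, grp in sig.groupby("chrom")
        }
        if dmr_iv:
            pres = probe_dmr_enrichment(genome.mqtl_probes, dmr_iv)
            rows.append({"annotation": "mQTL_probes", "group": "DMR",
                         "odds_ratio": pres.odds_ratio, "p": pres.p,
                         "overlap_fraction": pres.overlap_fraction})
        eio.write_table(pd.DataFrame(rows), out / "enrichment.tsv"); emit("enrichment", out / "enrichment.tsv")

        stage = "ff"
        bins, bin_table = bin_counts(matrix, width=config.ff_bin_width)
        train_mask = np.array([m.group != "CVS" for m in meta])
        true_ff = np.array([truth.ff[m.sample_id] for m in meta])
        if train_mask.sum() >= 10 and true_ff[train_mask].std() > 0:
            model = fit_ff(bins[train_mask], bin_table, true_ff[train_mask])
            pred = predict_ff(model, bins, bin_table)
            ff_out = pd.DataFrame(
                {"sample_id": [m.sample_id for m in meta],
                 "reference_ff": true_ff, "predicted_ff": pred}
            )
            eio.write_table(ff_out, out / "fetal_fraction.tsv"); emit("fetal_fraction", out / "fetal_fraction.tsv")
            (out / "ff_model.json").write_text(model.to_json()); emit("ff_model", out / "ff_model.json")
    except Exception as exc:                      # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
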