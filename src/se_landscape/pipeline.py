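"""End-to-end orchestration: peaks -> SEs -> consensus -> differential ->
targets -> survival screen -> TF screen -> motif scan.

Mirrors the discovery funnel of the study design: per-sample ROSE-style SE
calls are merged into a consensus universe, quantified and tested for
tumor/normal differential activity; up-SE target genes are intersected
with up-DEGs and screened for association with poor survival; the top
flagged gene becomes the focal target, whose SE constituents and promoter
define the TF-occupancy funnel; candidate TFs are ranked by expression
correlation with the focal gene, and the focal TF's motif is localized in
the provided sequences.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .differential import (
    ConsensusRegionSet,
    DiffParams,
    call_differential,
    differential_to_frame,
    merge_regions_across_samples,
    pca_scores,
    quantify_rpkm,
)
from .intervals import GenomicInterval, filter_blacklist, overlaps
from .motifs import pwm_from_counts, scan_motif
from .rose import RoseParams, call_superenhancers
from .survival import screen_candidates, screen_to_frame
from .targets import (
    assign_targets,
    intersect_se_targets_with_degs,
    rank_tf_candidates,
    tf_occupancy_funnel,
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``peak_files`` maps sample_id -> narrowPeak path; ``groups`` maps
    sample_id -> 'tumor' | 'normal'.
    """

    peak_files: dict[str, str]
    groups: dict[str, str]
    blacklist: str
    tss: str
    counts: str
    library_sizes: str
    count_regions: str  # BED naming the regions of the counts matrix
    expression: str
    deg_table: str
    survival: str
    cohort_expression: str
    tf_sites_dir: str
    sequences: str
    pfm: str
    out_dir: str
    rose: RoseParams = field(default_factory=RoseParams)
    diff: DiffParams = field(default_factory=DiffParams)
    survival_alpha: float = 0.05
    motif_min_fraction: float = 0.8
    strip_chr_prefix: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rose = RoseParams(**raw.pop("rose", {}))
        diff = DiffParams(**raw.pop("diff", {}))
        return cls(rose=rose, diff=diff, **raw)

    @classmethod
    def for_simulated(cls, data_dir: str, out_dir: str, **overrides) -> "PipelineConfig":
        """Config pointing at a simulate_dataset() output directory."""
        d = Path(data_dir)
        groups = pd.read_csv(d / "groups.tsv", sep="\t")
        peak_files = {
            s: str(d / "peaks" / f"{s}.narrowPeak") for s in groups["sample_id"]
        }
        return cls(
            peak_files=peak_files,
            groups=dict(zip(groups["sample_id"], groups["group"])),
            blacklist=str(d / "blacklist.bed"),
            tss=str(d / "tss.tsv"),
            counts=str(d / "counts.tsv"),
            library_sizes=str(d / "library_sizes.tsv"),
            count_regions=str(d / "loci.bed"),
            expression=str(d / "expression.tsv"),
            deg_table=str(d / "deg.tsv"),
            survival=str(d / "survival.tsv"),
            cohort_expression=str(d / "cohort_expression.tsv"),
            tf_sites_dir=str(d / "tf_sites"),
            sequences=str(d / "sequences.fasta"),
            pfm=str(d / "motif.pfm"),
            out_dir=out_dir,
            **overrides,
        )

    def validate(self) -> None:
        paths = [self.blacklist, self.tss, self.counts, self.library_sizes,
                 self.count_regions, self.expression, self.deg_table,
                 self.survival, self.cohort_expression, self.sequences,
                 self.pfm, *self.peak_files.values()]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError("validate", f"missing input files: {missing}")
        if not Path(self.tf_sites_dir).is_dir():
            raise PipelineError("validate", f"not a directory: {self.tf_sites_dir}")
        if set(self.groups) != set(self.peak_files):
            raise PipelineError("validate", "groups and peak_files name different samples")


@dataclass
class RunReport:
    """Machine-readable per-stage record counts and parameters."""

    counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    focal_gene: str | None = None
    focal_tf: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "counts": self.counts,
                    "params": self.params,
                    "stage_seconds": self.stage_seconds,
                    "focal_gene": self.focal_gene,
                    "focal_tf": self.focal_tf,
                },
                fh, indent=1, sort_keys=True,
            )


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; returns the run report (also written to
    out_dir/report.json along with all stage outputs)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.params = {
        "stitch_window_bp": config.rose.stitch_window_bp,
        "tss_exclusion_bp": config.rose.tss_exclusion_bp,
        "tss_mode": config.rose.tss_mode,
        "fc_up": config.diff.fc_up,
        "fc_down": config.diff.fc_down,
        "alpha": config.diff.alpha,
        "require_fdr": config.diff.require_fdr,
        "survival_alpha": config.survival_alpha,
        "motif_min_fraction": config.motif_min_fraction,
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            report.stage_seconds[name] = round(time.perf_counter() - t0, 3)

        return done

    # --- per-sample SE calling ---------------------------------------
    done = stage("call-se")
    try:
        blacklist = sio.read_bed(config.blacklist, strip_chr_prefix=config.strip_chr_prefix)
        tss = sio.read_tss(config.tss)
        per_sample_ses: dict[str, list[GenomicInterval]] = {}
        per_sample_regions = {}
        n_peaks_in = n_peaks_bl = 0
        for sample_id in sorted(config.peak_files):
            peaks = sio.read_peaks(
                config.peak_files[sample_id], format="narrowPeak",
                sample_id=sample_id, strip_chr_prefix=config.strip_chr_prefix,
            )
            n_peaks_in += len(peaks)
            peaks = filter_blacklist(peaks, blacklist)
            n_peaks_bl += len(peaks)
            regions = call_superenhancers(peaks, tss, config.rose)
            per_sample_regions[sample_id] = regions
            per_sample_ses[sample_id] = [
                GenomicInterval(
                    r.interval.chrom, r.interval.start, r.interval.end,
                    name=f"{sample_id}_SE{r.rank}", score=r.signal,
                )
                for r in regions if r.is_super
            ]
        report.counts["peaks_total"] = n_peaks_in
        report.counts["peaks_after_blacklist"] = n_peaks_bl
        report.counts["ses_per_sample"] = {
            s: len(v) for s, v in sorted(per_sample_ses.items())
        }
        report.counts["stitched_regions_per_sample"] = {
            s: len(v) for s, v in sorted(per_sample_regions.items())
        }
        _log("call-se", f"{n_peaks_in} peaks in, {n_peaks_bl} after blacklist")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("call-se", str(exc)) from exc
    done()

    # --- consensus merge ---------------------------------------------
    done = stage("merge")
    try:
        consensus = merge_regions_across_samples(per_sample_ses)
        sio.write_bed(consensus.regions, out / "consensus_se.bed")
        report.counts["consensus_regions"] = len(consensus.regions)
        _log("merge", f"{len(consensus.regions)} consensus regions")
    except Exception as exc:
        raise PipelineError("merge", str(exc)) from exc
    done()

    # --- quantify + PCA + differential -------------------------------
    done = stage("diff-se")
    try:
        cm = sio.read_counts(config.counts, config.library_sizes)
        count_regions = {
            r.name: r for r in sio.read_bed(config.count_regions,
                                            strip_chr_prefix=config.strip_chr_prefix)
        }
        # restrict the counts universe to regions overlapping a consensus SE
        region_to_consensus: dict[str, str] = {}
        for cons in consensus.regions:
            for rid, riv in count_regions.items():
                if overlaps(cons, riv):
                    region_to_consensus[rid] = cons.name  # type: ignore[assignment]
        keep_idx = [i for i, r in enumerate(cm.region_ids) if r in region_to_consensus]
        cm_sub = sio.CountsMatrix(
            region_ids=[cm.region_ids[i] for i in keep_idx],
            sample_ids=cm.sample_ids,
            counts=cm.counts[keep_idx],
            library_sizes=cm.library_sizes,
        )
        lengths = {r: count_regions[r].length for r in cm_sub.region_ids}
        matrix = quantify_rpkm(cm_sub, lengths)
        matrix.to_frame().to_csv(out / "rpkm.tsv", sep="\t", float_format="%.6g")
        scores, varexp = pca_scores(matrix)
        scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame({"component": scores.columns, "variance_explained": varexp}).to_csv(
            out / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g"
        )
        tumor_ids = sorted(s for s, g in config.groups.items() if g == "tumor")
        normal_ids = sorted(s for s, g in config.groups.items() if g == "normal")
        diff = call_differential(matrix, tumor_ids, normal_ids, config.diff)
        diff_df = differential_to_frame(diff)
        diff_df.to_csv(out / "differential_se.tsv", sep="\t", float_format="%.6g")
        n_up = int((diff_df["call"] == "up").sum())
        n_down = int((diff_df["call"] == "down").sum())
        report.counts["tested_regions"] = len(diff_df)
        report.counts["diff_up"] = n_up
        report.counts["diff_down"] = n_down
        report.counts["diff_ns"] = len(diff_df) - n_up - n_down
        _log("diff-se", f"{len(diff_df)} tested: {n_up} up, {n_down} down")
    except Exception as exc:
        raise PipelineError("diff-se", str(exc)) from exc
    done()

    # --- target genes and DEG intersection ---------------------------
    done = stage("targets")
    try:
        up_ids = set(diff_df.index[diff_df["call"] == "up"])
        down_ids = set(diff_df.index[diff_df["call"] == "down"])
        assignments = assign_targets(
            [count_regions[r] for r in cm_sub.region_ids], tss
        )
        gene_of = {a.region_id: a.gene_id for a in assignments}
        pd.DataFrame(
            {
                "region_id": [a.region_id for a in assignments],
                "gene_id": [a.gene_id for a in assignments],
                "distance": [a.distance for a in assignments],
            }
        ).to_csv(out / "target_genes.tsv", sep="\t", index=False)
        up_genes = {gene_of[r] for r in up_ids if gene_of.get(r)}
        down_genes = {gene_of[r] for r in down_ids if gene_of.get(r)}
        degs = pd.read_csv(config.deg_table, sep="\t")
        inter_up, inter_down = intersect_se_targets_with_degs(up_genes, down_genes, degs)
        report.counts["se_genes_up"] = len(up_genes)
        report.counts["se_genes_down"] = len(down_genes)
        report.counts["intersect_up"] = len(inter_up)
        report.counts["intersect_down"] = len(inter_down)
        _log("targets", f"{len(inter_up)} up / {len(inter_down)} down SE-regulated genes")
    except Exception as exc:
        raise PipelineError("targets", str(exc)) from exc
    done()

    # --- survival screen on up candidates -----------------------------
    done = stage("survival")
    try:
        cohort_expr = sio.read_matrix(config.cohort_expression)
        surv = sio.read_survival(config.survival)
        screen = screen_candidates(inter_up, cohort_expr, surv, alpha=config.survival_alpha)
        screen_df = screen_to_frame(screen)
        screen_df.to_csv(out / "survival_screen.tsv", sep="\t", float_format="%.6g")
        flagged = [r.gene_id for r in screen if r.flagged]
        report.counts["survival_flagged"] = len(flagged)
        report.focal_gene = flagged[0] if flagged else None
        _log("survival", f"{len(flagged)} of {len(inter_up)} candidates flagged")
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc
    done()

    # --- TF occupancy funnel + ranking on the focal gene ---------------
    done = stage("tf-screen")
    try:
        if report.focal_gene is None:
            report.counts["tf_hits_any"] = 0
            report.counts["tf_hits_all"] = 0
            _log("tf-screen", "no focal gene; skipped")
        else:
            focal_gene = report.focal_gene
            focal_region = next(
                r for r in cm_sub.region_ids if gene_of.get(r) == focal_gene
            )
            # constituents of the focal SE: first/last peaks of any sample's
            # stitched region overlapping it (peak coordinates are shared)
            focal_iv = count_regions[focal_region]
            constituents = None
            for sample_id in sorted(per_sample_regions):
                for sr in per_sample_regions[sample_id]:
                    if sr.is_super and overlaps(sr.interval, focal_iv):
                        peaks_here = sio.read_peaks(
                            config.peak_files[sample_id], format="narrowPeak",
                            sample_id=sample_id,
                            strip_chr_prefix=config.strip_chr_prefix,
                        )
                        by_name = {p.name: p.interval for p in peaks_here}
                        ivs = sorted(by_name[n] for n in sr.constituent_names)
                        constituents = (ivs[0], ivs[-1])
                        break
                if constituents:
                    break
            if constituents is None:
                raise RuntimeError(f"no SE constituents found for {focal_gene}")
            tss_pos = next(t.pos for t in tss if t.gene_id == focal_gene)
            tss_chrom = next(t.chrom for t in tss if t.gene_id == focal_gene)
            queries = {
                "E1": constituents[0],
                "E2": constituents[1],
                "promoter": GenomicInterval(tss_chrom, max(0, tss_pos - 1000), tss_pos + 1000),
            }
            tf_sites = {
                p.stem: sio.read_bed(p, strip_chr_prefix=config.strip_chr_prefix)
                for p in sorted(Path(config.tf_sites_dir).glob("*.bed"))
            }
            funnel = tf_occupancy_funnel(tf_sites, queries)
            funnel.to_csv(out / "tf_funnel.tsv", sep="\t")
            hits_all = sorted(funnel.index[funnel["hits_all"]])
            expr = sio.read_matrix(config.expression)
            tumor_ids = sorted(s for s, g in config.groups.items() if g == "tumor")
            rankable = [t for t in hits_all if t in expr.index and t != focal_gene]
            ranking = rank_tf_candidates(rankable, expr, focal_gene, sample_ids=tumor_ids)
            pd.DataFrame(ranking, columns=["tf_id", "r", "p"]).to_csv(
                out / "tf_ranking.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report.counts["tf_hits_any"] = int(funnel["hits_any"].sum())
            report.counts["tf_hits_all"] = len(hits_all)
            report.focal_tf = ranking[0][0] if ranking else None
            _log("tf-screen",
                 f"{int(funnel['hits_any'].sum())} TFs hit any region, "
                 f"{len(hits_all)} hit all; top: {report.focal_tf}")
    except Exception as exc:
        raise PipelineError("tf-screen", str(exc)) from exc
    done()

    # --- motif scan ----------------------------------------------------
    done = stage("motif-scan")
    try:
        pwm = pwm_from_counts(sio.read_pfm(config.pfm))
        seqs = sio.read_fasta(config.sequences)
        hits = []
        for seq_id, seq in seqs.items():
            hits.extend(scan_motif(pwm, seq, config.motif_min_fraction, sequence_id=seq_id))
        pd.DataFrame(
            {
                "sequence_id": [h.sequence_id for h in hits],
                "position": [h.position for h in hits],
                "strand": [h.strand for h in hits],
                "score": [h.score for h in hits],
                "score_fraction": [h.score_fraction for h in hits],
            }
        ).to_csv(out / "motif_hits.tsv", sep="\t", index=False, float_format="%.6g")
        report.counts["motif_hits"] = len(hits)
        _log("motif-scan", f"{len(hits)} hits in {len(seqs)} sequences")
    except Exception as exc:
        raise PipelineError("motif-scan", str(exc)) from exc
    done()

    report.to_json(out / "report.json")
    return report
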