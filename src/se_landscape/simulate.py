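"""Ground-truthed synthetic data emulating a matched tumor/normal SE study.

The generator lays out candidate enhancer loci on a small synthetic genome
(2 chromosomes x 10 Mb by default), plants tumor-enriched and
normal-enriched loci among them, and writes every input the pipeline
consumes: per-sample narrowPeak files, a blacklist, a TSS annotation,
per-region counts with library sizes, expression coupled to SE activity, a
DEG table, a survival cohort whose hazard is tied to a designated driver
gene, per-TF binding-site BEDs, motif-planted FASTA sequences with the
matching PFM, and a JSON truth manifest for recovery scoring.

Counts are negative binomial in the mean-dispersion parameterization
(variance = mu + mu^2 / dispersion) to capture ChIP-seq overdispersion.
Matched pairs share a per-locus random baseline, so the unpaired test used
downstream remains conservative.  Each file type draws from its own RNG
stream spawned from the master seed, so adding a file type does not
perturb existing outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .differential import simple_deg_table
from .intervals import GenomicInterval
from .motifs import pfm_from_consensus, reverse_complement

_STREAMS = [
    "genome", "library", "counts", "expression", "survival", "tfsites", "motifs",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the design under study: 9 matched tumor/normal pairs,
    500 candidate enhancer loci with 50 planted tumor-enriched and 50
    normal-enriched, a 4-fold planted count effect, expression coupled to
    SE activity at r ~ 0.8, and a survival cohort whose log-hazard rises
    by 0.7 per SD of driver-gene expression.
    """

    seed: int = 0
    n_pairs: int = 9
    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    n_regions: int = 500
    n_planted_up: int = 50
    n_planted_down: int = 50
    signal_fc: float = 4.0
    nb_dispersion: float = 20.0
    base_mean_count: float = 200.0
    library_size_range: tuple[int, int] = (8_000_000, 12_000_000)
    peaks_per_locus_range: tuple[int, int] = (3, 8)
    locus_sigma: float = 0.6
    pair_sigma: float = 0.3
    n_decoy_genes: int = 50
    expr_coupling: float = 0.8
    driver_beta: float = 0.7
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    n_subjects: int = 300
    n_tfs: int = 30
    n_tf_decoy_hits_all: int = 3
    sites_per_tf: int = 40
    motif_consensus: str = "ATGACTCATC"
    n_motif_sequences: int = 100
    motif_sequence_length: int = 500
    n_blacklist: int = 5

    def __post_init__(self) -> None:
        if self.n_planted_up + self.n_planted_down > self.n_regions:
            raise ValueError("planted loci exceed n_regions")
        if self.signal_fc <= 1:
            raise ValueError("signal_fc must be > 1")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass
class TruthManifest:
    """Serializable ground truth for scoring pipeline recovery."""

    planted_up: list[str]
    planted_down: list[str]
    region_coords: dict[str, tuple[str, int, int]]
    region_gene: dict[str, str]
    driver_region: str
    driver_gene: str
    driver_tf: str
    hits_all_tfs: list[str]
    driver_queries: dict[str, tuple[str, int, int]]
    motif_plants: list[tuple[str, int, str]]
    motif_consensus: str
    tumor_samples: list[str]
    normal_samples: list[str]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        raw["region_coords"] = {k: tuple(v) for k, v in raw["region_coords"].items()}
        raw["driver_queries"] = {k: tuple(v) for k, v in raw["driver_queries"].items()}
        raw["motif_plants"] = [tuple(t) for t in raw["motif_plants"]]
        return cls(**raw)


@dataclass
class _Locus:
    region_id: str
    chrom: str
    peaks: list[tuple[int, int]]  # (start, end) per constituent
    gene_id: str
    tss_pos: int

    @property
    def start(self) -> int:
        return self.peaks[0][0]

    @property
    def end(self) -> int:
        return self.peaks[-1][1]


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial with mean ``mean`` and size ``dispersion``."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _layout_genome(cfg: SimConfig, rng: np.random.Generator):
    """Place loci, their peak geometries, gene TSSs, and the blacklist."""
    reserve = 500_000  # telomeric zone holding TF/decoy gene TSSs
    per_chrom = [cfg.n_regions // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_regions % cfg.n_chroms):
        per_chrom[i] += 1
    loci: list[_Locus] = []
    blacklist: list[GenomicInterval] = []
    extra_tss: list[tuple[str, str, int]] = []
    kmin, kmax = cfg.peaks_per_locus_range
    idx = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n_loci = per_chrom[c]
        spacing = (cfg.chrom_length_bp - reserve) // (n_loci + 1)
        for slot in range(n_loci):
            idx += 1
            region_id = f"R{idx:04d}"
            anchor = spacing * (slot + 1) + int(rng.integers(0, 2001))
            k = int(rng.integers(kmin, kmax + 1))
            widths = rng.integers(400, 1201, size=k)
            gaps = rng.integers(200, 1201, size=max(0, k - 1))
            peaks = []
            pos = anchor
            for j in range(k):
                peaks.append((pos, pos + int(widths[j])))
                pos += int(widths[j]) + (int(gaps[j]) if j < k - 1 else 0)
            tss_pos = peaks[-1][1] + 3000
            loci.append(_Locus(region_id, chrom, peaks, f"G{idx:04d}", tss_pos))
        if chrom == "chr1":
            # blacklist intervals midway through inter-locus gaps
            for b in range(cfg.n_blacklist):
                slot = 2 * b + 1
                # inter-locus gap: loci extend at most ~23 kb past their anchor
                start = spacing * (slot + 1) + 24_000
                blacklist.append(
                    GenomicInterval(chrom, start, start + 3000, name=f"bl_{b + 1}")
                )
        # TF and decoy gene TSSs live in the reserved zone
        zone = cfg.chrom_length_bp - reserve + 10_000
        if c == 0:
            for t in range(cfg.n_tfs):
                extra_tss.append((f"TF{t + 1:02d}", chrom, zone + 2000 * t))
        else:
            for d in range(cfg.n_decoy_genes):
                extra_tss.append((f"DEC{d + 1:03d}", chrom, zone + 2000 * d))
    return loci, blacklist, extra_tss


def simulate_dataset(config: SimConfig, out_dir: str | os.PathLike) -> TruthManifest:
    """Generate the full synthetic study into ``out_dir``.

    Returns the truth manifest (also serialized as truth.json).  Output is
    byte-identical for a fixed config and seed.
    """
    cfg = config
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tf_sites").mkdir(exist_ok=True)
    rngs = _spawn_streams(cfg.seed)

    loci, blacklist, extra_tss = _layout_genome(cfg, rngs["genome"])
    n_loci = len(loci)
    g_rng = rngs["genome"]

    # planted direction assignment
    order = g_rng.permutation(n_loci)
    up_idx = sorted(order[: cfg.n_planted_up])
    down_idx = sorted(order[cfg.n_planted_up : cfg.n_planted_up + cfg.n_planted_down])
    direction = np.zeros(n_loci, dtype=int)
    direction[up_idx] = 1
    direction[down_idx] = -1

    # per-locus activity (mean-normalized lognormal) and constituent weights
    a = g_rng.lognormal(-cfg.locus_sigma**2 / 2, cfg.locus_sigma, size=n_loci)
    peak_weights = [g_rng.dirichlet(np.full(len(l.peaks), 5.0)) for l in loci]

    # the driver is the most active tumor-enriched locus: a strong enhancer
    # whose SE status is robust across samples
    driver_i = max(up_idx, key=lambda i: a[i])
    driver = loci[driver_i]

    # samples and library sizes
    tumor_ids = [f"T{p + 1:02d}" for p in range(cfg.n_pairs)]
    normal_ids = [f"N{p + 1:02d}" for p in range(cfg.n_pairs)]
    samples = tumor_ids + normal_ids
    lib_lo, lib_hi = cfg.library_size_range
    libs = rngs["library"].integers(lib_lo, lib_hi + 1, size=len(samples))
    mean_lib = libs.mean()

    # expected counts: base * locus activity * shared pair baseline * fc
    c_rng = rngs["counts"]
    pair_base = c_rng.lognormal(
        -cfg.pair_sigma**2 / 2, cfg.pair_sigma, size=(n_loci, cfg.n_pairs)
    )
    mu = np.empty((n_loci, len(samples)))
    for s, sid in enumerate(samples):
        pair = int(sid[1:]) - 1
        is_tumor = sid.startswith("T")
        fc = np.where(
            (direction == 1) & is_tumor, cfg.signal_fc,
            np.where((direction == -1) & (not is_tumor), cfg.signal_fc, 1.0),
        )
        mu[:, s] = cfg.base_mean_count * a * pair_base[:, pair] * fc * (libs[s] / mean_lib)
    counts = _nb_draw(c_rng, mu, cfg.nb_dispersion)

    # per-sample narrowPeak files (locus peaks + promoter peaks + blacklist junk)
    for s, sid in enumerate(samples):
        lines = []
        pk = 0
        for i, locus in enumerate(loci):
            shares = np.round(counts[i, s] * peak_weights[i]).astype(int)
            for (pstart, pend), sig in zip(locus.peaks, shares):
                pk += 1
                lines.append(_np_line(locus.chrom, pstart, pend, f"{sid}_pk{pk}", float(sig)))
            # promoter peak: inside the TSS-exclusion zone, dropped pre-stitch
            pk += 1
            prom_sig = float(_nb_draw(c_rng, 30.0, cfg.nb_dispersion))
            lines.append(
                _np_line(locus.chrom, locus.tss_pos - 400, locus.tss_pos + 400,
                         f"{sid}_pk{pk}", prom_sig)
            )
        for b in blacklist:
            pk += 1
            junk = float(_nb_draw(c_rng, 50.0, cfg.nb_dispersion))
            lines.append(_np_line(b.chrom, b.start + 500, b.start + 1500, f"{sid}_pk{pk}", junk))
        with open(out / "peaks" / f"{sid}.narrowPeak", "w") as fh:
            fh.write("".join(lines))

    sio.write_bed(blacklist, out / "blacklist.bed")
    sio.write_bed(
        [GenomicInterval(l.chrom, l.start, l.end, name=l.region_id) for l in loci],
        out / "loci.bed",
    )
    cm = sio.CountsMatrix(
        region_ids=[l.region_id for l in loci],
        sample_ids=samples,
        counts=counts,
        library_sizes=libs,
    )
    sio.write_counts(cm, out / "counts.tsv", out / "library_sizes.tsv")

    # TSS table: one gene per locus plus TF and decoy genes
    tss_rows = [(l.gene_id, l.chrom, l.tss_pos, "+") for l in loci]
    tss_rows += [(g, chrom, pos, "+") for g, chrom, pos in extra_tss]
    pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"]).to_csv(
        out / "tss.tsv", sep="\t", index=False
    )
    pd.DataFrame({"sample_id": samples, "group": ["tumor"] * len(tumor_ids) + ["normal"] * len(normal_ids)}).to_csv(
        out / "groups.tsv", sep="\t", index=False
    )

    # expression coupled to SE activity
    e_rng = rngs["expression"]
    log_mu = np.log(mu / libs[None, :])  # library effect removed
    z_act = (log_mu - log_mu.mean(axis=1, keepdims=True)) / np.maximum(
        log_mu.std(axis=1, keepdims=True), 1e-12
    )
    c = cfg.expr_coupling
    locus_expr = 8.0 + c * z_act + np.sqrt(1 - c**2) * e_rng.normal(size=z_act.shape)
    genes = [l.gene_id for l in loci] + [g for g, _, _ in extra_tss]
    expr = np.empty((len(genes), len(samples)))
    expr[:n_loci] = locus_expr
    expr[n_loci:] = e_rng.normal(8.0, 1.0, size=(len(genes) - n_loci, len(samples)))
    # the driver TF's expression tracks the driver gene
    t_rng = rngs["tfsites"]
    tf_ids = [f"TF{t + 1:02d}" for t in range(cfg.n_tfs)]
    driver_tf = tf_ids[int(t_rng.integers(0, cfg.n_tfs))]
    expr[genes.index(driver_tf)] = expr[driver_i] + e_rng.normal(0, 0.15, size=len(samples))
    expr_df = pd.DataFrame(2.0**expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    expr_df.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")

    deg = simple_deg_table(expr_df, tumor_ids, normal_ids)
    deg.to_csv(out / "deg.tsv", sep="\t", index=False, float_format="%.6g")

    # survival cohort driven by the driver gene
    s_rng = rngs["survival"]
    subjects = [f"S{i + 1:04d}" for i in range(cfg.n_subjects)]
    cohort = s_rng.normal(8.0, 1.0, size=(len(genes), cfg.n_subjects))
    zdrv = (cohort[driver_i] - cohort[driver_i].mean()) / cohort[driver_i].std()
    hazard = cfg.baseline_hazard * np.exp(cfg.driver_beta * zdrv)
    times = s_rng.exponential(1.0 / hazard)
    censored = s_rng.random(cfg.n_subjects) < cfg.censor_rate
    times = np.where(censored, times * s_rng.random(cfg.n_subjects), times)
    times = np.maximum(times, 1e-6)
    pd.DataFrame(
        {"subject_id": subjects, "time": times, "event": (~censored).astype(int)}
    ).to_csv(out / "survival.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        2.0**cohort, index=pd.Index(genes, name="gene_id"), columns=subjects
    ).to_csv(out / "cohort_expression.tsv", sep="\t", float_format="%.6g")

    # TF binding sites; the driver TF (and a few decoys) occupy the driver
    # locus's first/last constituents (E1/E2) and the target promoter
    e1 = driver.peaks[0]
    e2 = driver.peaks[-1]
    promoter = (driver.tss_pos - 1000, driver.tss_pos + 1000)
    decoy_pool = [t for t in tf_ids if t != driver_tf]
    hits_all = [driver_tf] + sorted(
        t_rng.choice(decoy_pool, size=cfg.n_tf_decoy_hits_all, replace=False).tolist()
    )
    for tf in tf_ids:
        sites = []
        if tf in hits_all:
            for lo, hi in (e1, e2, promoter):
                mid = (lo + hi) // 2
                sites.append(GenomicInterval(driver.chrom, mid - 100, mid + 100))
        n_rand = cfg.sites_per_tf - len(sites)
        chroms = t_rng.integers(1, cfg.n_chroms + 1, size=n_rand)
        starts = t_rng.integers(0, cfg.chrom_length_bp - 200, size=n_rand)
        for ch, st in zip(chroms, starts):
            sites.append(GenomicInterval(f"chr{ch}", int(st), int(st) + 200))
        sio.write_bed(sorted(sites), out / "tf_sites" / f"{tf}.bed")

    # motif-planted sequences: backgrounds are rejection-sampled so the
    # planted occurrence is the only one on either strand
    m_rng = rngs["motifs"]
    consensus = cfg.motif_consensus.upper()
    rc = reverse_complement(consensus)
    seqs: dict[str, str] = {}
    plants: list[tuple[str, int, str]] = []
    for i in range(cfg.n_motif_sequences):
        seq_id = f"seq_{i + 1:04d}"
        while True:
            bases = m_rng.integers(0, 4, size=cfg.motif_sequence_length)
            seq = "".join("ACGT"[b] for b in bases)
            pos = int(m_rng.integers(0, cfg.motif_sequence_length - len(consensus) + 1))
            strand = "+" if m_rng.random() < 0.5 else "-"
            planted = consensus if strand == "+" else rc
            seq = seq[:pos] + planted + seq[pos + len(consensus):]
            if seq.count(consensus) + seq.count(rc) == 1:
                break
        seqs[seq_id] = seq
        plants.append((seq_id, pos, strand))
    sio.write_fasta(seqs, out / "sequences.fasta")
    sio.write_pfm(pfm_from_consensus(consensus), out / "motif.pfm", name="driver_tf_motif")

    manifest = TruthManifest(
        planted_up=[loci[i].region_id for i in up_idx],
        planted_down=[loci[i].region_id for i in down_idx],
        region_coords={l.region_id: (l.chrom, l.start, l.end) for l in loci},
        region_gene={l.region_id: l.gene_id for l in loci},
        driver_region=driver.region_id,
        driver_gene=driver.gene_id,
        driver_tf=driver_tf,
        hits_all_tfs=hits_all,
        driver_queries={
            "E1": (driver.chrom, e1[0], e1[1]),
            "E2": (driver.chrom, e2[0], e2[1]),
            "promoter": (driver.chrom, promoter[0], promoter[1]),
        },
        motif_plants=plants,
        motif_consensus=consensus,
        tumor_samples=tumor_ids,
        normal_samples=normal_ids,
    )
    manifest.to_json(out / "truth.json")
    return manifest


def _np_line(chrom: str, start: int, end: int, name: str, signal: float) -> str:
    score = int(min(1000, signal))
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\t{signal:g}\t-1\t-1\t{(end - start) // 2}\n"
    )


def truth_score(calls: dict[str, object], truth: TruthManifest) -> dict[str, dict]:
    """Score pipeline outputs against the planted ground truth.

    ``calls`` may contain any of: ``diff_up``/``diff_down`` (sets of
    region ids), ``target_genes_up`` (set of gene ids), ``flagged_genes``
    (set), ``tf_ranking`` (ordered list of tf ids), ``motif_hits`` (list
    of (sequence_id, position, strand)).  Returns per-stage dicts with
    sensitivity and precision (None where undefined, e.g. empty calls).
    """
    scores: dict[str, dict] = {}

    def sp(called: set, planted: set) -> dict:
        tp = len(called & planted)
        return {
            "sensitivity": tp / len(planted) if planted else None,
            "precision": tp / len(called) if called else None,
            "n_called": len(called),
            "n_planted": len(planted),
        }

    if "diff_up" in calls or "diff_down" in calls:
        up = set(calls.get("diff_up", set()))  # type: ignore[arg-type]
        down = set(calls.get("diff_down", set()))  # type: ignore[arg-type]
        scores["differential"] = sp(up | down, set(truth.planted_up) | set(truth.planted_down))
        scores["differential_up"] = sp(up, set(truth.planted_up))
        scores["differential_down"] = sp(down, set(truth.planted_down))
    if "target_genes_up" in calls:
        planted_genes = {truth.region_gene[r] for r in truth.planted_up}
        scores["target_genes"] = sp(set(calls["target_genes_up"]), planted_genes)  # type: ignore[arg-type]
    if "flagged_genes" in calls:
        flagged = set(calls["flagged_genes"])  # type: ignore[arg-type]
        scores["driver_flagging"] = {
            "driver_recovered": truth.driver_gene in flagged,
            "n_flagged": len(flagged),
        }
    if "tf_ranking" in calls:
        ranking = list(calls["tf_ranking"])  # type: ignore[arg-type]
        scores["tf_ranking"] = {
            "driver_rank": (ranking.index(truth.driver_tf) + 1)
            if truth.driver_tf in ranking else None,
            "driver_is_top": bool(ranking) and ranking[0] == truth.driver_tf,
        }
    if "motif_hits" in calls:
        called = {(s, int(p), st) for s, p, st in calls["motif_hits"]}  # type: ignore[union-attr]
        planted = {(s, int(p), st) for s, p, st in truth.motif_plants}
        scores["motif"] = sp(called, planted)
    return scores
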