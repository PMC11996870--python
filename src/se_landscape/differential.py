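"""Cross-sample consensus super-enhancer universe and differential calls.

Per-sample SEs are merged into a non-overlapping consensus set, quantified
as RPKM from per-region read counts, inspected by PCA, and tested for
differential activity between tumor and matched-normal groups with the
Wilcoxon rank-sum test, Benjamini-Hochberg FDR adjustment, and fold-change
gates (> 1.5 up, < 0.67 down by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals, overlaps, span
from .io import CountsMatrix


@dataclass
class ConsensusRegionSet:
    """Merged, non-overlapping SE universe with per-region provenance.

    ``provenance`` maps each consensus region id to the (sample_id,
    source interval) pairs that contributed to it.
    """

    regions: list[GenomicInterval]
    provenance: dict[str, list[tuple[str, str]]]

    @property
    def region_ids(self) -> list[str]:
        return [r.name for r in self.regions]  # type: ignore[misc]

    def lengths(self) -> dict[str, int]:
        return {r.name: r.length for r in self.regions}  # type: ignore[misc]


@dataclass
class SignalMatrix:
    """Regions x samples RPKM values."""

    region_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("RPKM values must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class DiffParams:
    """Thresholds for differential SE calling.

    ``fc_up``/``fc_down`` gate the ratio of group means (tumor over
    normal, computed on RPKM plus ``pseudocount``); ``alpha`` is the FDR
    level applied to BH-adjusted q-values when ``require_fdr`` is true.
    """

    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    pseudocount: float = 0.01
    require_fdr: bool = True
    paired: bool = False

    def __post_init__(self) -> None:
        if not (self.fc_up > 1 > self.fc_down > 0):
            raise ValueError("require fc_up > 1 > fc_down > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class DifferentialResult:
    region_id: str
    mean_tumor: float
    mean_normal: float
    fold_change: float
    p: float
    q: float
    call: str  # up / down / ns


def merge_regions_across_samples(
    per_sample_ses: dict[str, list[GenomicInterval]],
) -> ConsensusRegionSet:
    """Merge SEs from all samples into a consensus region set.

    Regions that overlap by >= 1 bp or are book-ended (gap 0) merge
    transitively.  Consensus ids are assigned deterministically in
    coordinate order as SE_0001, SE_0002, ...
    """
    tagged: list[tuple[GenomicInterval, str]] = []
    for sample_id in sorted(per_sample_ses):
        for i, iv in enumerate(per_sample_ses[sample_id]):
            tagged.append((iv, sample_id))
    groups = merge_intervals([iv for iv, _ in tagged], max_gap=0)
    source = {}
    for iv, sample_id in tagged:
        source.setdefault(iv, []).append((sample_id, iv.name or str(iv)))
    regions: list[GenomicInterval] = []
    provenance: dict[str, list[tuple[str, str]]] = {}
    for i, group in enumerate(groups):
        region_id = f"SE_{i + 1:04d}"
        regions.append(span(group, name=region_id))
        prov: list[tuple[str, str]] = []
        for iv in dict.fromkeys(group):  # unique, order-preserving
            prov.extend(source[iv])
        provenance[region_id] = sorted(prov)
    return ConsensusRegionSet(regions=regions, provenance=provenance)


def quantify_rpkm(
    counts: CountsMatrix, region_lengths: dict[str, int]
) -> SignalMatrix:
    """Reads per kilobase per million mapped reads:
    ``rpkm = count * 1e9 / (length_bp * library_size)``."""
    try:
        lengths = np.array([region_lengths[r] for r in counts.region_ids], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no length for region {exc.args[0]!r}") from exc
    if np.any(lengths <= 0):
        raise ValueError("region lengths must be positive")
    values = counts.counts * 1e9 / (lengths[:, None] * counts.library_sizes[None, :])
    return SignalMatrix(list(counts.region_ids), list(counts.sample_ids), values)


def pca_scores(
    matrix: SignalMatrix, center: bool = True, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over regions (samples are observations).

    Returns (scores, variance_explained) with components ordered by
    decreasing variance; variance_explained sums to 1 over all non-null
    components.
    """
    X = matrix.values.T.astype(float)  # samples x regions
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale zero-variance regions")
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    keep = S > S[0] * 1e-12 if S[0] > 0 else S > 0
    U, S = U[:, keep], S[keep]
    scores = U * S
    varexp = S**2 / np.sum(S**2) if S.size else np.array([])
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.sample_ids, columns=cols), varexp


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Exact p by enumeration of all labelings when both groups have <= 10
    observations and there are no ties; otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    matrix: SignalMatrix,
    tumor_ids: list[str],
    normal_ids: list[str],
    params: DiffParams = DiffParams(),
) -> list[DifferentialResult]:
    """Per-region differential activity calls, tumor versus normal.

    fold_change = (mean_tumor + pc) / (mean_normal + pc); p from the
    rank-sum test (or the paired signed-rank test when ``params.paired``);
    q from BH over all regions.  call = up iff fold_change > fc_up, down
    iff fold_change < fc_down, additionally requiring q < alpha when
    ``require_fdr``.
    """
    if set(tumor_ids) & set(normal_ids):
        raise ValueError("tumor and normal groups must be disjoint")
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    df = matrix.to_frame()
    T = df[tumor_ids].to_numpy()
    N = df[normal_ids].to_numpy()
    pc = params.pseudocount
    mean_t = T.mean(axis=1)
    mean_n = N.mean(axis=1)
    fc = (mean_t + pc) / (mean_n + pc)
    pvals = np.empty(len(df))
    for i in range(len(df)):
        if params.paired:
            d = T[i] - N[i]
            if np.allclose(d, 0):
                pvals[i] = 1.0
            else:
                pvals[i] = float(stats.wilcoxon(T[i], N[i]).pvalue)
        else:
            pvals[i] = wilcoxon_rank_sum(T[i], N[i])[1]
    qvals = bh_fdr(pvals)
    results = []
    for i, region_id in enumerate(matrix.region_ids):
        passes_fdr = (qvals[i] < params.alpha) or not params.require_fdr
        if fc[i] > params.fc_up and passes_fdr:
            call = "up"
        elif fc[i] < params.fc_down and passes_fdr:
            call = "down"
        else:
            call = "ns"
        results.append(
            DifferentialResult(
                region_id=region_id,
                mean_tumor=float(mean_t[i]),
                mean_normal=float(mean_n[i]),
                fold_change=float(fc[i]),
                p=float(pvals[i]),
                q=float(qvals[i]),
                call=call,
            )
        )
    return results


def differential_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in results],
            "mean_tumor": [r.mean_tumor for r in results],
            "mean_normal": [r.mean_normal for r in results],
            "fold_change": [r.fold_change for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "call": [r.call for r in results],
        }
    ).set_index("region_id")


def locus_prevalence(
    per_sample_ses: dict[str, list[GenomicInterval]], locus: GenomicInterval
) -> float:
    """Fraction of samples with at least one SE overlapping the locus by
    >= 1 bp (book-ended regions do not count)."""
    if not per_sample_ses:
        raise ValueError("need at least one sample")
    hit = sum(
        1
        for ses in per_sample_ses.values()
        if any(overlaps(se, locus) for se in ses)
    )
    return hit / len(per_sample_ses)


def simple_deg_table(
    expression: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """A minimal DEG caller for synthetic tests: rank-sum p, BH q, and a
    fold-change gate on group means of (linear-scale) expression.

    Real analyses should supply their own DEG table; this helper only
    provides a self-contained stand-in with the same schema
    (gene_id, log2fc, q, direction).
    """
    T = expression[tumor_ids].to_numpy()
    N = expression[normal_ids].to_numpy()
    pc = 1e-9
    log2fc = np.log2((T.mean(axis=1) + pc) / (N.mean(axis=1) + pc))
    pvals = np.array([wilcoxon_rank_sum(T[i], N[i])[1] for i in range(len(expression))])
    qvals = bh_fdr(pvals)
    direction = np.where(log2fc > 0, "up", "down")
    sig = (qvals < alpha) & (np.abs(log2fc) > np.log2(fc_threshold))
    out = pd.DataFrame(
        {
            "gene_id": expression.index,
            "log2fc": log2fc,
            "q": qvals,
            "direction": direction,
        }
    )[sig]
    return out.reset_index(drop=True)
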