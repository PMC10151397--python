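"""Single-marker eQTL mapping, permutation FDR thresholds, peak calling,
confidence intervals, cis/trans classification and dataset comparison.

The mapping model regresses, per spot and per marker, the log2 intensity
on a 0/1 allele indicator (reference vs alternative parent). The slope t
test is equivalent to the pooled two-sample t test between genotype
classes. Genome-wide significance is set by permuting expression columns
across strains and comparing false discoveries in permuted data (FDS)
with real discoveries (RDS) over a grid of -log10(p) thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, ValidationError
from .io_core import ALT, MISSING, EQTLRecord, ExpressionMatrix, GenotypeMatrix, MarkerMap, SpotAnnotation

P_FLOOR = 1e-300  # avoids infinite -log10(p)
CIS_WINDOW_BP = 1_000_000


@dataclass
class AssociationProfile:
    """Per-marker association statistics for one spot."""

    spot_id: str
    neg_log10_p: np.ndarray  # len n_markers
    effect: np.ndarray  # ALT mean - REF mean, len n_markers


@dataclass
class Peak:
    marker_id: str
    marker_index: int
    chromosome: str
    position_bp: int
    neg_log10_p: float
    effect: float


@dataclass
class ThresholdResult:
    q: float
    m: int  # hypotheses (spots) tested
    grid: np.ndarray  # candidate thresholds, -log10(p)
    fds: np.ndarray  # mean false discoveries per permutation at each grid point
    rds: np.ndarray  # real discoveries at each grid point
    m0: np.ndarray  # estimated true nulls, m - RDS
    threshold: float  # chosen genome-wide threshold
    n_permutations: int
    corrected: bool  # whether the (m0/m)*log(m) factor was applied


def _scan_matrices(Y: np.ndarray, X: np.ndarray, df_offset: int = 2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-(row of Y, column of X) OLS slope test.

    Y: traits x samples; X: samples x markers (0/1 floats, no missing).
    Returns (neg_log10_p, effect) each traits x markers. Markers whose
    allele indicator is constant get p = 1, effect 0.
    """
    n = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    sy = np.sqrt((Yc**2).sum(axis=1))
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ Xc) / np.outer(sy, sx)
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    df = n - df_offset
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-30))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    bad = (sx == 0) | (sy[:, None] == 0)
    p = np.where(bad if bad.ndim == 2 else bad[None, :], 1.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(sx > 0, (Yc @ Xc) / (Xc**2).sum(axis=0), 0.0)
    return -np.log10(p), effect


def _align_genotypes(expr: ExpressionMatrix, geno: GenotypeMatrix) -> np.ndarray:
    """Genotype call matrix aligned to expression samples (samples x markers)."""
    rows = geno.strain_index(expr.metadata["strain"].tolist())
    return geno.calls[rows]


def map_single_marker(
    expr: ExpressionMatrix, geno: GenotypeMatrix, min_class_size: int = 2
) -> list[AssociationProfile]:
    """Per spot x marker OLS of expression on the 0/1 allele indicator.

    Samples with a missing call at a marker are excluded from that
    marker's regression only. Markers ending up with fewer than
    ``min_class_size`` strains per genotype class get p = 1 with a warning.
    """
    calls = _align_genotypes(expr, geno)
    Y = expr.values
    n_spots, n_markers = Y.shape[0], calls.shape[1]
    nlp = np.zeros((n_spots, n_markers))
    eff = np.zeros((n_spots, n_markers))

    obs = calls != MISSING
    counts1 = np.where(obs, calls == ALT, 0).sum(axis=0)
    counts0 = obs.sum(axis=0) - counts1
    degenerate = (counts0 < min_class_size) | (counts1 < min_class_size)
    if degenerate.any():
        names = [geno.markers.marker_ids[j] for j in np.flatnonzero(degenerate)]
        warnings.warn(
            f"markers with < {min_class_size} strains per genotype class set to p=1: "
            + ", ".join(names),
            stacklevel=2,
        )

    complete = obs.all(axis=0) & ~degenerate
    if complete.any():
        X = (calls[:, complete] == ALT).astype(float)
        nlp[:, complete], eff[:, complete] = _scan_matrices(Y, X)
    for j in np.flatnonzero(~complete & ~degenerate):
        keep = obs[:, j]
        X = (calls[keep, j] == ALT).astype(float)[:, None]
        nlp[:, j : j + 1], eff[:, j : j + 1] = _scan_matrices(Y[:, keep], X)

    return [
        AssociationProfile(spot_id=s, neg_log10_p=nlp[i], effect=eff[i])
        for i, s in enumerate(expr.spots)
    ]


def _scan_max_nlp(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-trait maximum -log10(p) over all markers (complete data fast path)."""
    nlp, _ = _scan_matrices(Y, X)
    return nlp.max(axis=1)


def permutation_threshold(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    n_permutations: int = 10,
    q: float = 0.05,
    grid_step: float = 0.1,
    grid_start: float = 1.0,
    corrected: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ThresholdResult:
    """Permutation-based genome-wide -log10(p) threshold at target FDR q.

    Expression columns are shuffled across strains (whole-column
    permutation, preserving spot-spot correlation) and re-mapped; at each
    candidate threshold T the mean number of spots with any passing marker
    in permuted data (FDS) is compared with the count in real data (RDS).
    The chosen threshold is the smallest grid T with

        FDS(T)/RDS(T) <= q                      (default), or
        FDS(T)/RDS(T) <= q * (m0/m) * log(m)    (``corrected=True``),

    with m the number of spots tested and m0 = m - RDS(T) the estimated
    true nulls.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    calls = _align_genotypes(expr, geno)
    if (calls == MISSING).any():
        raise ParameterError("permutation threshold requires complete genotypes")
    X = (calls == ALT).astype(float)
    Y = expr.values
    m = Y.shape[0]

    real_max = _scan_max_nlp(Y, X)
    perm_max = np.empty((n_permutations, m))
    for b in range(n_permutations):
        perm = rng.permutation(Y.shape[1])
        perm_max[b] = _scan_max_nlp(Y[:, perm], X)

    top = max(real_max.max(), perm_max.max()) + grid_step
    grid = np.round(np.arange(grid_start, top, grid_step), 10)
    rds = (real_max[None, :] >= grid[:, None]).sum(axis=1).astype(float)
    fds = (perm_max[None, :, :] >= grid[:, None, None]).sum(axis=2).mean(axis=1)
    m0 = m - rds

    if not (rds > 0).any():
        raise ValidationError("no discoveries at any candidate threshold")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rds > 0, fds / rds, np.inf)
    bound = q * (m0 / m) * np.log(m) if corrected else np.full_like(grid, q)
    ok = (ratio <= bound) & (rds > 0)
    if not ok.any():
        raise ValidationError("no candidate threshold satisfies the FDR bound")
    chosen = float(grid[np.argmax(ok)])  # smallest qualifying T

    return ThresholdResult(
        q=q, m=m, grid=grid, fds=fds, rds=rds, m0=m0,
        threshold=chosen, n_permutations=n_permutations, corrected=corrected,
    )


def call_peaks(
    profile: AssociationProfile, threshold: float, marker_map: MarkerMap
) -> list[Peak]:
    """At most one peak per chromosome: the maximal marker above threshold.

    Ties go to the leftmost marker of the chromosome.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    peaks = []
    chrom = marker_map.chromosome
    for c in marker_map.chromosomes:
        cols = np.flatnonzero(chrom == c)
        vals = profile.neg_log10_p[cols]
        jmax = cols[int(np.argmax(vals))]  # argmax is leftmost on ties
        if profile.neg_log10_p[jmax] > threshold:
            peaks.append(
                Peak(
                    marker_id=marker_map.marker_ids[jmax],
                    marker_index=int(jmax),
                    chromosome=str(c),
                    position_bp=int(marker_map.position_bp[jmax]),
                    neg_log10_p=float(profile.neg_log10_p[jmax]),
                    effect=float(profile.effect[jmax]),
                )
            )
    return peaks


def confidence_interval(
    profile: AssociationProfile,
    peak: Peak,
    marker_map: MarkerMap,
    drop: float = 1.5,
) -> tuple[int, int]:
    """Drop-based confidence interval around a called peak.

    Extends marker-by-marker from the peak in both directions while
    -log10(p) stays >= peak value - ``drop``; returns bp positions of the
    outermost markers still inside. Never crosses a chromosome boundary.
    """
    cols = np.flatnonzero(marker_map.chromosome == peak.chromosome)
    vals = profile.neg_log10_p[cols]
    k = int(np.flatnonzero(cols == peak.marker_index)[0])
    floor = peak.neg_log10_p - drop
    left = k
    while left > 0 and vals[left - 1] >= floor:
        left -= 1
    right = k
    while right < len(cols) - 1 and vals[right + 1] >= floor:
        right += 1
    return (
        int(marker_map.position_bp[cols[left]]),
        int(marker_map.position_bp[cols[right]]),
    )


def classify_cis_trans(
    peak: Peak, gene_chromosome: str, gene_bp: int, window_bp: int = CIS_WINDOW_BP
) -> str:
    """cis iff the peak is on the gene's chromosome within ``window_bp``."""
    if gene_chromosome is None or gene_bp is None:
        raise ValidationError("gene position unknown")
    same = str(peak.chromosome) == str(gene_chromosome)
    return "cis" if same and abs(peak.position_bp - int(gene_bp)) <= window_bp else "trans"


def variance_explained(expr_row: np.ndarray, genotype_column: np.ndarray) -> float:
    """One-way ANOVA R^2 of expression over the genotype classes at a marker."""
    y = np.asarray(expr_row, dtype=float)
    g = np.asarray(genotype_column)
    keep = g != MISSING
    y, g = y[keep], g[keep]
    classes = np.unique(g)
    if len(classes) < 2:
        raise ParameterError("need >= 2 genotype classes")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = sum(
        (g == c).sum() * (y[g == c].mean() - grand) ** 2 for c in classes
    )
    return float(ss_between / ss_total)


def call_eqtl(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    annotation: SpotAnnotation,
    threshold: float,
    treatment: str = "",
    drop: float = 1.5,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> list[EQTLRecord]:
    """Full per-treatment eQTL calling: scan, peaks, CI, class, R^2.

    Spots without an annotation entry are skipped with a warning (they
    cannot be classified cis/trans).
    """
    profiles = map_single_marker(expr, geno)
    calls = _align_genotypes(expr, geno)
    mm = geno.markers
    records: list[EQTLRecord] = []
    skipped = []
    for i, prof in enumerate(profiles):
        try:
            gene, gchrom, gpos = annotation.lookup(prof.spot_id)
        except KeyError:
            skipped.append(prof.spot_id)
            continue
        for peak in call_peaks(prof, threshold, mm):
            ci = confidence_interval(prof, peak, mm, drop=drop)
            r2 = variance_explained(expr.values[i], calls[:, peak.marker_index])
            records.append(
                EQTLRecord(
                    spot_id=prof.spot_id,
                    gene_id=gene,
                    peak_marker=peak.marker_id,
                    chromosome=peak.chromosome,
                    position_bp=peak.position_bp,
                    neg_log10_p=peak.neg_log10_p,
                    effect=peak.effect,
                    variance_explained=r2,
                    ci_left_bp=ci[0],
                    ci_right_bp=ci[1],
                    qtl_type=classify_cis_trans(peak, gchrom, gpos, cis_window_bp),
                    treatment=treatment,
                )
            )
    if skipped:
        warnings.warn(
            f"{len(skipped)} spots lacked annotation and were skipped", stacklevel=2
        )
    return records


def compare_eqtl_sets(
    set_a: list[EQTLRecord], set_b: list[EQTLRecord]
) -> dict[str, set[str]]:
    """Gene-level overlap between two classified eQTL sets.

    A gene is shared-cis when both sets give it a cis-eQTL; shared-trans
    when both give it trans-eQTL whose confidence intervals intersect
    (closed intervals, same chromosome — a boundary touch counts).
    Remaining genes with any eQTL are set-specific.
    """
    def by_gene(records):
        cis, trans = {}, {}
        for r in records:
            if r.qtl_type == "cis":
                cis.setdefault(r.gene_id, []).append(r)
            else:
                trans.setdefault(r.gene_id, []).append(r)
        return cis, trans

    cis_a, trans_a = by_gene(set_a)
    cis_b, trans_b = by_gene(set_b)
    shared_cis = set(cis_a) & set(cis_b)
    shared_trans = set()
    for g in set(trans_a) & set(trans_b):
        for ra in trans_a[g]:
            for rb in trans_b[g]:
                if ra.chromosome == rb.chromosome and (
                    ra.ci_left_bp <= rb.ci_right_bp and rb.ci_left_bp <= ra.ci_right_bp
                ):
                    shared_trans.add(g)
    genes_a = {r.gene_id for r in set_a}
    genes_b = {r.gene_id for r in set_b}
    shared = shared_cis | shared_trans
    return {
        "shared_cis": shared_cis,
        "shared_trans": shared_trans,
        "a_specific": genes_a - shared,
        "b_specific": genes_b - shared,
    }
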