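"""Simulation-based power analysis for single-marker eQTL detection.

For each marker of a genotype matrix, phenotypes are simulated as
y = b*x + N(0,1) with the allelic effect b scaled so the marker explains
a chosen fraction v of the variance (b = sqrt(v/(1-v))/sd(x)). A full
genome scan is run per replicate.

Three detection conventions are supported. The default, ``"causal"``,
counts a simulated QTL as correctly detected when its own marker reaches
the genome-wide threshold — the natural reading of a per-marker power
analysis, and the convention whose power matches the closed-form
noncentral-t calculation. ``"window"`` accepts any marker within the
detection window (1 Mb, the cis-window convention) of the causal locus,
and ``"peak"`` demands that a called chromosome peak above the threshold
lie within the window (strictest: noise can displace the peak to a
correlated marker outside the window). Under every convention, passing
called peaks farther than the window from the causal marker count as
false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .io_core import ALT, MISSING, GenotypeMatrix
from .eqtl import _scan_matrices

DEFAULT_VARIANCE_GRID = tuple(np.round(np.arange(0.20, 0.801, 0.05), 2))
DETECT_WINDOW_BP = 1_000_000


@dataclass
class PowerResult:
    variance_grid: tuple[float, ...]
    detection_rate: np.ndarray  # per grid point
    false_positives_per_scan: np.ndarray
    median_abs_location_error_bp: np.ndarray  # over detected QTL
    mean_effect_ratio: np.ndarray  # estimated/true effect at the detecting peak
    n_strains: int
    threshold: float
    replicates_per_point: int
    seed: int | None
    detection: str = "causal"


def simulate_power(
    geno: GenotypeMatrix,
    variance_grid=DEFAULT_VARIANCE_GRID,
    threshold_neg_log10_p: float = 3.9,
    n_reps_per_marker: int = 3,
    detect_window_bp: int = DETECT_WINDOW_BP,
    detection: str = "causal",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PowerResult:
    """Power, false positives, location and effect accuracy over a v grid.

    Every polymorphic marker serves in turn as the causal locus with
    ``n_reps_per_marker`` independent noise replicates, so one grid point
    aggregates n_markers x n_reps_per_marker full genome scans.
    ``detection`` is one of ``"causal"``, ``"window"``, ``"peak"`` (see
    module docstring).
    """
    variance_grid = tuple(float(v) for v in variance_grid)
    if any(not 0 < v < 1 for v in variance_grid):
        raise ParameterError("variance fractions must lie in (0,1)")
    if detection not in ("causal", "window", "peak"):
        raise ParameterError(f"unknown detection convention {detection!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    mm = geno.markers
    calls = geno.calls
    if (calls == MISSING).any():
        raise ParameterError("power simulation requires complete genotypes")
    X = (calls == ALT).astype(float)  # strains x markers
    n, k = X.shape
    sx = X.std(axis=0)
    usable = sx > 0
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} monomorphic markers skipped in power simulation",
            stacklevel=2,
        )
    causal = np.flatnonzero(usable)

    chrom = mm.chromosome
    pos = mm.position_bp
    chrom_cols = [np.flatnonzero(chrom == c) for c in mm.chromosomes]

    det_rate, fp_rate, loc_err, eff_ratio = [], [], [], []
    for v in variance_grid:
        b = np.sqrt(v / (1.0 - v)) / sx[causal]  # per causal marker
        # replicate block: rows are (causal marker, rep) pairs
        reps = np.repeat(np.arange(len(causal)), n_reps_per_marker)
        Y = X[:, causal][:, reps].T * b[reps][:, None]
        Y = Y + rng.standard_normal(Y.shape)
        nlp, eff = _scan_matrices(Y, X)

        causal_idx = causal[reps]
        causal_chrom = chrom[causal_idx]
        causal_pos = pos[causal_idx]
        rows = np.arange(len(reps))
        peak_hit = np.zeros(len(reps), dtype=bool)
        fp = np.zeros(len(reps), dtype=int)
        err = np.full(len(reps), np.nan)
        ratio = np.full(len(reps), np.nan)
        for cols in chrom_cols:
            sub = nlp[:, cols]
            jmax = np.argmax(sub, axis=1)
            passing = sub[rows, jmax] > threshold_neg_log10_p
            peak_cols = cols[jmax]
            same = chrom[peak_cols] == causal_chrom
            near = same & (np.abs(pos[peak_cols] - causal_pos) <= detect_window_bp)
            hit = passing & near
            newly = hit & ~peak_hit
            err[newly] = np.abs(pos[peak_cols] - causal_pos)[newly]
            ratio[newly] = (eff[rows, peak_cols] / (b[reps]))[newly]
            peak_hit |= hit
            fp += (passing & ~near).astype(int)
        if detection == "peak":
            detected = peak_hit
        elif detection == "causal":
            detected = nlp[rows, causal_idx] > threshold_neg_log10_p
        else:  # any marker within the window
            in_window = (chrom[None, :] == causal_chrom[:, None]) & (
                np.abs(pos[None, :] - causal_pos[:, None]) <= detect_window_bp
            )
            detected = (np.where(in_window, nlp, 0.0) > threshold_neg_log10_p).any(axis=1)
        det_rate.append(detected.mean())
        fp_rate.append(fp.mean())
        loc_err.append(np.nanmedian(err) if peak_hit.any() else np.nan)
        eff_ratio.append(np.nanmean(ratio) if peak_hit.any() else np.nan)

    return PowerResult(
        variance_grid=variance_grid,
        detection_rate=np.array(det_rate),
        false_positives_per_scan=np.array(fp_rate),
        median_abs_location_error_bp=np.array(loc_err),
        mean_effect_ratio=np.array(eff_ratio),
        n_strains=n,
        threshold=threshold_neg_log10_p,
        replicates_per_point=len(causal) * n_reps_per_marker,
        seed=seed,
        detection=detection,
    )
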