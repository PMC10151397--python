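"""Synthetic RIL genotypes and expression with planted, known structure.

The generator emulates an N2 x CB4856 recombinant-inbred panel: each
strain is a fixed mosaic of the two parental genomes, produced by drawing
a Poisson number of crossovers per chromosome with uniform breakpoints
and fixing one parental allele per block (no residual heterozygosity).
Expression is built additively from a per-spot baseline, planted cis and
trans (hotspot) marker effects, a treatment main effect, a linear
developmental-age term, and i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_core import (
    ALT,
    REF,
    WS220_CHROM_LENGTHS,
    ExpressionMatrix,
    GenotypeMatrix,
    MarkerMap,
    SpotAnnotation,
)

REFERENCE_AGE_H = 56.75  # midpoint of the 41.5-72 h developmental window


def default_marker_map(n_markers: int = 729,
                       chrom_lengths: Mapping[str, int] = WS220_CHROM_LENGTHS) -> MarkerMap:
    """Markers spread over the genome proportionally to chromosome length.

    The default mimics the canonical N2 x CB4856 RIL setup: 729 markers
    over the 6 C. elegans chromosomes (WS220 lengths), evenly spaced
    within each chromosome.
    """
    total = sum(chrom_lengths.values())
    raw = {c: n_markers * L / total for c, L in chrom_lengths.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    # distribute the remainder by largest fractional part
    rem = n_markers - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    ids, chroms, pos = [], [], []
    for c, L in chrom_lengths.items():
        k = counts[c]
        p = np.linspace(1, L, k).astype(np.int64)
        for i, bp in enumerate(p, 1):
            ids.append(f"{c}_{i:03d}")
            chroms.append(c)
            pos.append(int(bp))
    return MarkerMap(tuple(ids), np.array(chroms, dtype=object), np.array(pos))


@dataclass
class SimulationDesign:
    """Parameters of a synthetic RIL eQTL experiment.

    Effects are in log2 expression units; ``recombination_rate`` is the
    expected crossover count per chromosome per meiosis. Defaults follow
    the canonical study conditions: 729 markers on 6 chromosomes, unit
    noise SD, a two-level RNAi treatment contrast, and a 41.5-72 h
    developmental window.
    """

    n_strains: int = 48
    marker_map: MarkerMap = field(default_factory=default_marker_map)
    recombination_rate: float = 1.5
    planted_cis: list[tuple[str, str, float]] = field(default_factory=list)  # (spot, marker, effect)
    planted_trans_bands: list[tuple[str, int, float]] = field(default_factory=list)  # (marker, n_spots, effect)
    treatment_effects: list[tuple[str, float]] = field(default_factory=list)  # (spot, log2 shift)
    ruler_genes: list[tuple[str, float, float]] = field(default_factory=list)  # (spot, slope/h, intercept)
    treatments: tuple[str, str] = ("empty_vector", "gld1_rnai")
    n_background_spots: int = 0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 4:
            raise ParameterError("n_strains must be >= 4")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        for what, eff in (("cis", [e for *_, e in self.planted_cis]),
                          ("trans", [e for *_, e in self.planted_trans_bands]),
                          ("treatment", [e for _, e in self.treatment_effects])):
            if any(not np.isfinite(e) for e in eff):
                raise ParameterError(f"non-finite planted {what} effect")


def effect_for_variance_explained(v: float, x: np.ndarray, noise_sd: float = 1.0) -> float:
    """Allelic effect b such that the marker explains fraction ``v`` of variance.

    With a 0/1 allele indicator x and noise SD sigma, b = sigma *
    sqrt(v/(1-v)) / sd(x) makes the population R-squared at the causal
    marker equal v.
    """
    if not 0 < v < 1:
        raise ParameterError("variance fraction must be in (0,1)")
    sx = np.std(x[x >= 0])
    if sx == 0:
        raise ParameterError("marker is monomorphic; cannot scale effect")
    return noise_sd * np.sqrt(v / (1.0 - v)) / sx


def simulate_ril_genotypes(design: SimulationDesign,
                           rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate fully inbred RIL genotypes as parental block mosaics.

    Per strain and chromosome, a Poisson(recombination_rate) number of
    crossovers is placed uniformly in bp; alternating parental blocks are
    then fixed, starting from a random parent. The output contains no
    heterozygous or missing calls.
    """
    if design.n_strains < 1:
        raise ParameterError("need at least one strain")
    rng = np.random.default_rng(design.seed) if rng is None else rng
    mm = design.marker_map
    n, k = design.n_strains, len(mm)
    calls = np.empty((n, k), dtype=np.int8)
    chrom_arr = mm.chromosome
    for c in mm.chromosomes:
        cols = np.flatnonzero(chrom_arr == c)
        pos = mm.position_bp[cols].astype(float)
        length = pos[-1]
        for s in range(n):
            n_xo = rng.poisson(design.recombination_rate)
            breaks = np.sort(rng.uniform(0, length, size=n_xo))
            # block index at each marker = number of breakpoints passed
            block = np.searchsorted(breaks, pos)
            start = rng.integers(0, 2)
            calls[s, cols] = (start + block) % 2
    strains = tuple(f"RIL{i + 1:03d}" for i in range(n))
    return GenotypeMatrix(strains=strains, markers=mm, calls=calls)


def _spot_universe(design: SimulationDesign, rng: np.random.Generator) -> list[str]:
    spots: list[str] = []
    for spot, *_ in design.planted_cis:
        spots.append(spot)
    for marker, n_spots, _ in design.planted_trans_bands:
        spots.extend(f"{marker}_t{i + 1:03d}" for i in range(n_spots))
    for spot, _ in design.treatment_effects:
        if spot not in spots:
            spots.append(spot)
    for spot, *_ in design.ruler_genes:
        if spot not in spots:
            spots.append(spot)
    spots.extend(f"bg{i + 1:05d}" for i in range(design.n_background_spots))
    # preserve order, drop duplicates
    return list(dict.fromkeys(spots))


def simulate_expression(
    geno: GenotypeMatrix,
    design: SimulationDesign,
    sample_ages: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate log2 expression with planted structure; return (matrix, truth).

    One sample is generated per strain and treatment level. Each spot i in
    sample j follows

        y_ij = baseline_i + b_i * allele_ij + shift_i * treated_j
               + slope_i * (age_j - reference) + N(0, noise_sd)

    The truth table records, per spot, the causal marker and effect, the
    treatment shift and the age slope that were planted.
    """
    rng = np.random.default_rng(design.seed + 1) if rng is None else rng
    mm = design.marker_map
    marker_index = {m: i for i, m in enumerate(mm.marker_ids)}
    for _, marker, _ in design.planted_cis:
        if marker not in marker_index:
            raise ParameterError(f"planted cis marker {marker!r} not in map")
    for marker, *_ in design.planted_trans_bands:
        if marker not in marker_index:
            raise ParameterError(f"planted hotspot marker {marker!r} not in map")

    spots = _spot_universe(design, rng)
    spot_idx = {s: i for i, s in enumerate(spots)}
    n_spots = len(spots)

    samples, strain_of, treat_of = [], [], []
    for t in design.treatments:
        for s in geno.strains:
            samples.append(f"{s}_{t}")
            strain_of.append(s)
            treat_of.append(t)
    n_samples = len(samples)
    if sample_ages is None:
        sample_ages = {smp: REFERENCE_AGE_H for smp in samples}
    ages = np.array([sample_ages.get(smp, REFERENCE_AGE_H) for smp in samples])

    strain_rows = geno.strain_index(strain_of)
    treated = np.array([t == design.treatments[1] for t in treat_of], dtype=float)

    baseline = rng.normal(8.0, 1.0, size=n_spots)  # arbitrary log2 abundance scale
    truth = pd.DataFrame(
        {
            "spot": spots,
            "true_marker": [""] * n_spots,
            "true_effect": np.zeros(n_spots),
            "treatment_shift": np.zeros(n_spots),
            "age_slope": np.zeros(n_spots),
        }
    ).set_index("spot", drop=False)

    y = baseline[:, None] + rng.normal(0.0, design.noise_sd, size=(n_spots, n_samples))

    def add_marker_effect(spot: str, marker: str, effect: float):
        j = marker_index[marker]
        allele = (geno.calls[strain_rows, j] == ALT).astype(float)
        y[spot_idx[spot]] += effect * allele
        truth.loc[spot, ["true_marker", "true_effect"]] = (marker, effect)

    for spot, marker, effect in design.planted_cis:
        add_marker_effect(spot, marker, effect)
    for marker, n_targets, effect in design.planted_trans_bands:
        for i in range(n_targets):
            add_marker_effect(f"{marker}_t{i + 1:03d}", marker, effect)
    for spot, shift in design.treatment_effects:
        y[spot_idx[spot]] += shift * treated
        truth.loc[spot, "treatment_shift"] = shift
    for spot, slope, intercept in design.ruler_genes:
        i = spot_idx[spot]
        y[i] += intercept - baseline[i] + slope * (ages - REFERENCE_AGE_H)
        truth.loc[spot, "age_slope"] = slope

    meta = pd.DataFrame(
        {"strain": strain_of, "treatment": treat_of, "age_h": ages},
        index=pd.Index(samples, name="sample"),
    )
    expr = ExpressionMatrix(
        spots=tuple(spots), samples=tuple(samples), values=y, metadata=meta
    )
    return expr, truth


def annotation_for_truth(truth: pd.DataFrame, marker_map: MarkerMap,
                         cis_spots: Sequence[str] = (),
                         rng: np.random.Generator | None = None) -> SpotAnnotation:
    """Build a spot annotation consistent with a simulation's truth table.

    Spots listed in ``cis_spots`` are placed at their causal marker's
    position (so their planted eQTL classifies cis); all other spots are
    scattered uniformly over the genome.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    chroms = marker_map.chromosomes
    lengths = {c: int(marker_map.position_bp[marker_map.chromosome == c].max())
               for c in chroms}
    rows = []
    for spot in truth["spot"]:
        marker = truth.loc[spot, "true_marker"]
        if spot in set(cis_spots) and marker:
            j = marker_map.index_of(marker)
            chrom = str(marker_map.chromosome[j])
            pos = int(marker_map.position_bp[j])
        else:
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(1, lengths[chrom] + 1))
        rows.append((spot, f"gene_{spot}", chrom, pos))
    return SpotAnnotation(
        frame=pd.DataFrame(rows, columns=["spot_id", "gene_id", "chromosome", "position_bp"])
    )
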