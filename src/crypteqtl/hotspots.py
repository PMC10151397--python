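"""Genome binning and Poisson trans-eQTL hotspot (trans-band) detection.

Trans-eQTL cluster at loci that regulate many genes. The genome is tiled
with fixed-width bins (0.5 Mb by default, 203 bins for the WS220 C.
elegans assembly), trans-eQTL peaks are counted per bin at spot level,
and a bin is a trans-band when its count is in the extreme upper tail of
a Poisson null with rate = total trans count / number of bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ParameterError, ValidationError
from .io_core import EQTLRecord, WS220_CHROM_LENGTHS

BIN_WIDTH_BP = 500_000


@dataclass(frozen=True)
class GenomeBins:
    """Half-open 1-based bins [start, start + width) tiling each chromosome."""

    chromosome: tuple[str, ...]
    start_bp: np.ndarray
    end_bp: np.ndarray  # exclusive
    chrom_lengths: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.chromosome)

    def locate(self, chromosome: str, position_bp: int) -> int:
        """Index of the unique bin containing a position."""
        length = self.chrom_lengths.get(str(chromosome))
        if length is None:
            raise ValidationError(f"unknown chromosome {chromosome!r}")
        if not 1 <= position_bp <= length:
            raise ValidationError(
                f"position {position_bp} outside chromosome {chromosome} (1..{length})"
            )
        for i, c in enumerate(self.chromosome):
            if c == chromosome and self.start_bp[i] <= position_bp < self.end_bp[i]:
                return i
        raise ValidationError(f"no bin contains {chromosome}:{position_bp}")


@dataclass
class TransBand:
    bin_index: int
    chromosome: str
    start_bp: int
    end_bp: int
    count: int  # trans-eQTL spots in the bin
    p_poisson: float  # upper-tail P(X >= count)
    spots: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    treatment: str = ""


def genome_bins(
    chromosome_lengths: Mapping[str, int] = WS220_CHROM_LENGTHS,
    width_bp: int = BIN_WIDTH_BP,
) -> GenomeBins:
    """Tile each chromosome with ceil(length/width) half-open bins from bp 1."""
    if width_bp <= 0:
        raise ParameterError("bin width must be positive")
    chroms, starts, ends = [], [], []
    for c, length in chromosome_lengths.items():
        if length <= 0:
            raise ParameterError(f"non-positive length for chromosome {c}")
        n_bins = int(np.ceil(length / width_bp))
        for b in range(n_bins):
            chroms.append(str(c))
            starts.append(1 + b * width_bp)
            ends.append(1 + (b + 1) * width_bp)
    return GenomeBins(
        chromosome=tuple(chroms),
        start_bp=np.array(starts, dtype=np.int64),
        end_bp=np.array(ends, dtype=np.int64),
        chrom_lengths=dict(chromosome_lengths),
    )


def count_trans_per_bin(
    records: Sequence[EQTLRecord], bins: GenomeBins
) -> tuple[np.ndarray, list[list[EQTLRecord]]]:
    """Spot-level trans-eQTL counts per bin (cis records are ignored)."""
    counts = np.zeros(len(bins), dtype=int)
    members: list[list[EQTLRecord]] = [[] for _ in range(len(bins))]
    for r in records:
        if r.qtl_type != "trans":
            continue
        try:
            i = bins.locate(r.chromosome, r.position_bp)
        except ValidationError as e:
            raise ValidationError(f"record for spot {r.spot_id!r}: {e}") from None
        counts[i] += 1
        members[i].append(r)
    return counts, members


def poisson_transbands(
    counts: np.ndarray,
    bins: GenomeBins,
    members: Sequence[Sequence[EQTLRecord]] | None = None,
    alpha: float = 1e-4,
    treatment: str = "",
) -> list[TransBand]:
    """Flag bins whose trans-eQTL count exceeds the Poisson null.

    The null rate is the dataset's own mean: lambda = total trans count /
    number of bins. A bin is a trans-band iff P(X >= count) < alpha, with
    the upper tail inclusive of the observed count.
    """
    counts = np.asarray(counts)
    if len(counts) != len(bins):
        raise ValidationError("counts length != number of bins")
    total = int(counts.sum())
    if total == 0:
        warnings.warn("no trans-eQTL: no trans-bands can be called", stacklevel=2)
        return []
    lam = total / len(bins)
    tails = stats.poisson.sf(counts - 1, lam)  # P(X >= count)
    bands = []
    for i in np.flatnonzero(tails < alpha):
        mem = list(members[i]) if members is not None else []
        bands.append(
            TransBand(
                bin_index=int(i),
                chromosome=bins.chromosome[i],
                start_bp=int(bins.start_bp[i]),
                end_bp=int(bins.end_bp[i]),
                count=int(counts[i]),
                p_poisson=float(tails[i]),
                spots=tuple(r.spot_id for r in mem),
                genes=tuple(sorted({r.gene_id for r in mem})),
                treatment=treatment,
            )
        )
    return bands


def compare_transbands(
    bands_a: Sequence[TransBand],
    bands_b: Sequence[TransBand],
    universe: set,
) -> list[dict]:
    """Pairs of colocating trans-bands plus gene-overlap hypergeometric tests.

    Two bands colocate when their bin intervals intersect on the same
    chromosome (closed-interval convention: a boundary touch counts). For
    each pair the shared-gene count is tested against a hypergeometric
    null over the supplied gene universe.
    """
    if not universe:
        raise ParameterError("empty universe")
    pairs = []
    for a in bands_a:
        for b in bands_b:
            if a.chromosome != b.chromosome:
                continue
            if a.start_bp <= b.end_bp and b.start_bp <= a.end_bp:
                genes_a, genes_b = set(a.genes), set(b.genes)
                shared = genes_a & genes_b
                p = float(
                    stats.hypergeom.sf(
                        len(shared) - 1, len(universe), len(genes_a), len(genes_b)
                    )
                )
                pairs.append(
                    {
                        "band_a": a,
                        "band_b": b,
                        "shared_genes": shared,
                        "p_hypergeometric": min(p, 1.0),
                    }
                )
    return pairs
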