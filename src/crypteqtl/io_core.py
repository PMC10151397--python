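"""Tabular readers/writers and the core in-memory containers.

All formats are tab-separated UTF-8 with ``#``-prefixed comment lines
ignored. Genotype calls are stored as small integers: 0 = reference
allele (N2), 1 = alternative allele (CB4856), -1 = missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

REF = 0
ALT = 1
MISSING = -1

#: canonical C. elegans chromosome order used by the default setup
CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")

#: WS220 chromosome lengths in bp
WS220_CHROM_LENGTHS: Mapping[str, int] = {
    "I": 15_072_423,
    "II": 15_279_345,
    "III": 13_783_700,
    "IV": 17_493_793,
    "V": 20_924_149,
    "X": 17_718_866,
}

_READ_CSV_KW = dict(sep="\t", comment="#")


@dataclass(frozen=True)
class MarkerMap:
    """Ordered genetic markers with physical positions (1-based bp)."""

    marker_ids: tuple[str, ...]
    chromosome: np.ndarray  # dtype object/str, len n_markers
    position_bp: np.ndarray  # dtype int, len n_markers

    def __post_init__(self):
        ids = self.marker_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate marker ids in marker map")
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(ids) == len(chrom) == len(pos)):
            raise ValidationError("marker map field lengths differ")
        if len(pos) and pos.min() < 1:
            raise ValidationError("marker positions must be >= 1")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"marker positions not strictly increasing on chromosome {c}"
                )
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(pd.unique(self.chromosome))

    def index_of(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.marker_ids),
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Strains x markers biallelic calls (0/1 with -1 for missing)."""

    strains: tuple[str, ...]
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n_strains, n_markers)
    monomorphic: tuple[str, ...] = ()

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("duplicate strain ids in genotype matrix")
        if calls.shape != (len(self.strains), len(self.markers)):
            raise ValidationError(
                f"genotype call matrix shape {calls.shape} inconsistent with "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        bad = ~np.isin(calls, (REF, ALT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code at strain {self.strains[i]!r}, "
                f"marker {self.markers.marker_ids[j]!r}"
            )
        object.__setattr__(self, "calls", calls)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def strain_index(self, strain_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.strains)}
        try:
            return np.array([lookup[s] for s in strain_ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"strain {e.args[0]!r} has no genotypes") from None

    def allele_fractions(self) -> np.ndarray:
        """Per-marker ALT fraction among non-missing calls."""
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.calls == ALT, 0).sum(0) / obs.sum(0)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Spots x samples log2 intensities plus per-sample metadata.

    ``metadata`` is indexed by sample id and carries at least the columns
    ``strain`` and ``treatment``.
    """

    spots: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # float, shape (n_spots, n_samples)
    metadata: pd.DataFrame

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.spots), len(self.samples)):
            raise ValidationError(
                f"expression shape {values.shape} inconsistent with "
                f"{len(self.spots)} spots x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value for spot {self.spots[i]!r}, "
                f"sample {self.samples[j]!r}"
            )
        missing = [s for s in self.samples if s not in self.metadata.index]
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {', '.join(map(str, missing))}"
            )
        for col in ("strain", "treatment"):
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "metadata", self.metadata.loc[list(self.samples)].copy()
        )

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.metadata["treatment"]))

    def subset_treatment(self, treatment: str) -> "ExpressionMatrix":
        keep = self.metadata["treatment"] == treatment
        if not keep.any():
            raise ValidationError(f"no samples with treatment {treatment!r}")
        idx = np.flatnonzero(keep.to_numpy())
        return ExpressionMatrix(
            spots=self.spots,
            samples=tuple(np.asarray(self.samples, dtype=object)[idx]),
            values=self.values[:, idx],
            metadata=self.metadata.loc[keep],
        )

    def subset_spots(self, spot_ids: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.spots)}
        idx = np.array([lookup[s] for s in spot_ids], dtype=int)
        return ExpressionMatrix(
            spots=tuple(spot_ids),
            samples=self.samples,
            values=self.values[idx],
            metadata=self.metadata,
        )


@dataclass(frozen=True)
class SpotAnnotation:
    """Mapping from microarray spots to genes and genomic positions."""

    frame: pd.DataFrame  # columns spot_id, gene_id, chromosome, position_bp

    def __post_init__(self):
        required = {"spot_id", "gene_id", "chromosome", "position_bp"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"spot annotation lacks columns {sorted(missing)}")
        if self.frame["spot_id"].duplicated().any():
            dup = self.frame.loc[self.frame["spot_id"].duplicated(), "spot_id"].iloc[0]
            raise ValidationError(f"duplicate spot id {dup!r} in annotation")
        object.__setattr__(self, "frame", self.frame.set_index("spot_id", drop=False))

    def lookup(self, spot_id: str) -> tuple[str, str, int]:
        """Return (gene_id, chromosome, position_bp) for a spot."""
        try:
            row = self.frame.loc[spot_id]
        except KeyError:
            raise KeyError(f"spot {spot_id!r} not annotated") from None
        return str(row["gene_id"]), str(row["chromosome"]), int(row["position_bp"])


@dataclass
class EQTLRecord:
    """A called eQTL peak for one spot under one treatment."""

    spot_id: str
    gene_id: str
    peak_marker: str
    chromosome: str
    position_bp: int
    neg_log10_p: float
    effect: float
    variance_explained: float
    ci_left_bp: int
    ci_right_bp: int
    qtl_type: str  # "cis" | "trans"
    treatment: str

    def __post_init__(self):
        if not (self.ci_left_bp <= self.position_bp <= self.ci_right_bp):
            raise ValidationError(
                f"peak position outside its confidence interval for {self.spot_id!r}"
            )
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValidationError(
                f"variance explained {self.variance_explained} outside [0,1]"
            )
        if self.qtl_type not in ("cis", "trans"):
            raise ValidationError(f"qtl_type must be cis or trans, got {self.qtl_type!r}")


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, **_READ_CSV_KW, dtype=str, index_col=0)


def read_marker_map(path) -> MarkerMap:
    """Read a marker map TSV with columns marker, chromosome, position_bp."""
    frame = pd.read_csv(path, **_READ_CSV_KW)
    for col in ("marker", "chromosome", "position_bp"):
        if col not in frame.columns:
            raise ParseError(f"marker map {path} lacks column {col!r}")
    return MarkerMap(
        marker_ids=tuple(frame["marker"].astype(str)),
        chromosome=frame["chromosome"].astype(str).to_numpy(dtype=object),
        position_bp=frame["position_bp"].astype(int).to_numpy(),
    )


def read_genotypes(
    path,
    marker_map: MarkerMap | None = None,
    ref_alleles: Iterable[str] = ("N2",),
    alt_alleles: Iterable[str] = ("CB", "CB4856"),
    missing_tokens: Iterable[str] = ("NA", "", "-"),
) -> GenotypeMatrix:
    """Read a strains x markers genotype TSV.

    The header row holds marker ids and the first column strain ids. Cells
    must come from the declared allele alphabet; anything else raises
    :class:`ParseError` naming the offending cell. Markers that are
    monomorphic among non-missing calls are reported with a warning and
    listed on the returned matrix.
    """
    table = _read_table(path)
    marker_ids = tuple(map(str, table.columns))
    strains = tuple(map(str, table.index))
    if len(set(strains)) != len(strains):
        raise ValidationError(f"duplicate strain id in {path}")

    code = {t: MISSING for t in missing_tokens}
    code.update({a: REF for a in ref_alleles})
    code.update({a: ALT for a in alt_alleles})
    calls = np.empty(table.shape, dtype=np.int8)
    raw = table.to_numpy(dtype=object)
    for (i, j), cell in np.ndenumerate(raw):
        cell = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
        try:
            calls[i, j] = code[cell]
        except KeyError:
            raise ParseError(
                f"unrecognized genotype {cell!r} at strain {strains[i]!r}, "
                f"marker {marker_ids[j]!r}"
            ) from None

    if marker_map is None:
        # placeholder map: one synthetic chromosome, unit spacing
        marker_map = MarkerMap(
            marker_ids=marker_ids,
            chromosome=np.array(["un"] * len(marker_ids), dtype=object),
            position_bp=np.arange(1, len(marker_ids) + 1),
        )
    elif tuple(marker_map.marker_ids) != marker_ids:
        raise ValidationError("genotype columns do not match the marker map")

    mono = []
    for j, mid in enumerate(marker_ids):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0 or (obs == obs[0]).all():
            mono.append(mid)
    if mono:
        warnings.warn(f"monomorphic markers: {', '.join(mono)}", stacklevel=2)

    return GenotypeMatrix(
        strains=strains, markers=marker_map, calls=calls, monomorphic=tuple(mono)
    )


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read a spots x samples expression TSV plus a sample metadata TSV.

    The metadata file needs columns sample, strain and treatment; every
    sample column of the expression matrix must appear in it.
    """
    table = pd.read_csv(path, **_READ_CSV_KW, index_col=0)
    spots = tuple(map(str, table.index))
    samples = tuple(map(str, table.columns))
    values = table.to_numpy()
    if values.dtype.kind not in "fi":
        for j, col in enumerate(table.columns):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                spot = table.index[bad.to_numpy().argmax()]
                raise ParseError(
                    f"non-numeric expression value {table[col][bad].iloc[0]!r} "
                    f"at spot {spot!r}, sample {col!r}"
                )
        values = table.apply(pd.to_numeric, errors="coerce").to_numpy()

    meta = pd.read_csv(metadata_path, **_READ_CSV_KW)
    for col in ("sample", "strain", "treatment"):
        if col not in meta.columns:
            raise ParseError(f"metadata {metadata_path} lacks column {col!r}")
    meta = meta.astype({"sample": str}).set_index("sample")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValidationError(
            f"samples missing from metadata: {', '.join(missing)}"
        )
    return ExpressionMatrix(
        spots=spots, samples=samples, values=values.astype(float), metadata=meta
    )


def read_spot_annotation(path) -> SpotAnnotation:
    frame = pd.read_csv(path, **_READ_CSV_KW, dtype={"spot_id": str, "gene_id": str, "chromosome": str})
    return SpotAnnotation(frame=frame)


_EQTL_COLUMNS = [
    "spot",
    "gene",
    "peak_marker",
    "chromosome",
    "position",
    "neg_log10_p",
    "effect",
    "variance_explained",
    "ci_left_bp",
    "ci_right_bp",
    "type",
    "treatment",
]


def write_eqtl_table(records: Sequence[EQTLRecord], path) -> None:
    """Write eQTL records as TSV; round-trips at 6-decimal precision."""
    rows = [
        (
            r.spot_id,
            r.gene_id,
            r.peak_marker,
            r.chromosome,
            r.position_bp,
            round(r.neg_log10_p, 6),
            round(r.effect, 6),
            round(r.variance_explained, 6),
            r.ci_left_bp,
            r.ci_right_bp,
            r.qtl_type,
            r.treatment,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_EQTL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_eqtl_table(path) -> list[EQTLRecord]:
    frame = pd.read_csv(path, **_READ_CSV_KW, dtype={"spot": str, "gene": str})
    missing = set(_EQTL_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"eQTL table {path} lacks columns {sorted(missing)}")
    return [
        EQTLRecord(
            spot_id=str(row.spot),
            gene_id=str(row.gene),
            peak_marker=str(row.peak_marker),
            chromosome=str(row.chromosome),
            position_bp=int(row.position),
            neg_log10_p=float(row.neg_log10_p),
            effect=float(row.effect),
            variance_explained=float(row.variance_explained),
            ci_left_bp=int(row.ci_left_bp),
            ci_right_bp=int(row.ci_right_bp),
            qtl_type=str(row.type),
            treatment=str(row.treatment),
        )
        for row in frame.itertuples()
    ]


def write_expression(expr: ExpressionMatrix, path, metadata_path=None) -> None:
    pd.DataFrame(
        expr.values, index=list(expr.spots), columns=list(expr.samples)
    ).to_csv(path, sep="\t", index_label="spot")
    if metadata_path is not None:
        expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def write_genotypes(geno: GenotypeMatrix, path, ref_label="N2", alt_label="CB", missing_label="NA") -> None:
    labels = np.empty(geno.calls.shape, dtype=object)
    labels[geno.calls == REF] = ref_label
    labels[geno.calls == ALT] = alt_label
    labels[geno.calls == MISSING] = missing_label
    pd.DataFrame(
        labels, index=list(geno.strains), columns=list(geno.markers.marker_ids)
    ).to_csv(path, sep="\t", index_label="strain")
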