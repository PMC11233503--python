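"""Domain types and I/O for chromatin-tracing coordinate tables.

Multiplexed DNA FISH experiments image an ordered set of genomic loci
(a "region") on each chromosome copy and report a 3D coordinate per
detected locus.  The unit of analysis throughout this package is the
haploid chromosome copy: one :class:`ChromosomeTrace` per
(cell, allele) pair.  A locus is either fully observed (finite x, y, z)
or fully missing; rows absent from the input table, or rows carrying any
non-finite coordinate, are both treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COORD_COLUMNS = ["cell_id", "allele_id", "region_id", "chrom", "start", "end", "x", "y", "z"]
ANNOT_COLUMNS = ["region_id", "locus_index", "chrom", "start", "end"]


class CoordinateTableError(ValueError):
    """Malformed coordinate table (unknown locus, duplicate record, ...)."""


@dataclass(frozen=True)
class GenomicAnnotation:
    """1D genomic annotation of the imaged loci of one region.

    Loci are 1-based, consecutive, ordered along the genome.  ``starts``
    and ``ends`` are 1-based inclusive bp coordinates of each probed
    interval.  The genomic position used for separation computations is
    the interval midpoint (start + end) / 2.
    """

    region_id: str
    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.size == 0:
            raise ValueError("annotation must contain at least one locus")
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("locus starts must be strictly increasing")
        if np.any(ends <= starts):
            raise ValueError("each end must exceed its start")

    @property
    def K(self) -> int:
        return int(self.starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        """Midpoint bp position of each locus (float)."""
        return (self.starts + self.ends) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "locus_index": np.arange(1, self.K + 1),
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
            }
        )


def read_annotations(path) -> dict[str, GenomicAnnotation]:
    """Read an annotation CSV (columns ``region_id,locus_index,chrom,start,end``).

    Returns one :class:`GenomicAnnotation` per region, loci sorted by
    ``locus_index``, which must be 1..K consecutive within each region.
    """
    df = pd.read_csv(path)
    missing = set(ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise CoordinateTableError(f"annotation file lacks columns: {sorted(missing)}")
    out: dict[str, GenomicAnnotation] = {}
    for region_id, grp in df.groupby("region_id", sort=False):
        grp = grp.sort_values("locus_index")
        idx = grp["locus_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise CoordinateTableError(
                f"region {region_id!r}: locus_index must be 1..K consecutive"
            )
        chroms = grp["chrom"].unique()
        if len(chroms) != 1:
            raise CoordinateTableError(f"region {region_id!r} spans multiple chromosomes")
        out[str(region_id)] = GenomicAnnotation(
            region_id=str(region_id),
            chrom=str(chroms[0]),
            starts=grp["start"].to_numpy(),
            ends=grp["end"].to_numpy(),
        )
    return out


@dataclass
class ChromosomeTrace:
    """One haploid chromosome copy: K loci with 3D coordinates in nm.

    ``coords`` is a (K, 3) float array; missing loci hold NaN in all
    three coordinates.  Partial observations (some but not all axes
    finite) are promoted to fully missing on construction.
    """

    cell_id: str
    allele_id: str
    region_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.array(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (K, 3)")
        partial = ~np.isfinite(coords).all(axis=1)
        coords[partial] = np.nan
        self.coords = coords

    @property
    def K(self) -> int:
        return self.coords.shape[0]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed loci."""
        return np.isfinite(self.coords).all(axis=1)

    @property
    def missing(self) -> np.ndarray:
        return ~self.observed

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def detection_efficiency(self) -> float:
        """Fraction of the region's loci with a resolved 3D coordinate."""
        return self.n_observed / self.K

    def with_coords(self, coords: np.ndarray) -> "ChromosomeTrace":
        return ChromosomeTrace(self.cell_id, self.allele_id, self.region_id, coords)


@dataclass
class TraceCollection:
    """All traces of one region, sharing one :class:`GenomicAnnotation`."""

    annotation: GenomicAnnotation
    traces: list[ChromosomeTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for t in self.traces:
            if t.region_id != self.annotation.region_id:
                raise ValueError(
                    f"trace ({t.cell_id}, {t.allele_id}) has region {t.region_id!r}, "
                    f"annotation is {self.annotation.region_id!r}"
                )
            if t.K != self.annotation.K:
                raise ValueError(
                    f"trace ({t.cell_id}, {t.allele_id}) has {t.K} loci, expected "
                    f"{self.annotation.K}"
                )
            key = (t.cell_id, t.allele_id)
            if key in seen:
                raise ValueError(f"duplicate trace identity {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def detection_efficiencies(self) -> np.ndarray:
        return np.array([t.detection_efficiency() for t in self.traces])


def detection_efficiency(trace: ChromosomeTrace) -> float:
    """Fraction of loci observed on one haploid chromosome copy."""
    return trace.detection_efficiency()


def filter_min_observed(collection: TraceCollection, min_observed: int = 1) -> TraceCollection:
    """Keep traces with at least ``min_observed`` observed loci (order preserved).

    The default reproduces the standard "at least one locus observed"
    filter applied before computing detection efficiencies.
    """
    if min_observed < 1:
        raise ValueError("min_observed must be >= 1")
    kept = [t for t in collection.traces if t.n_observed >= min_observed]
    return TraceCollection(collection.annotation, kept)


def read_coordinate_table(path, annotation: GenomicAnnotation) -> TraceCollection:
    """Read a per-locus coordinate CSV into a :class:`TraceCollection`.

    The file holds one row per observed locus with columns
    ``cell_id,allele_id,region_id,chrom,start,end,x,y,z``.  Loci of the
    region absent from the file are marked missing; rows with any
    non-finite coordinate are likewise treated as missing.  Rows whose
    (start, end) does not match a locus of ``annotation`` raise an
    error naming the row, as do duplicated (cell, allele, locus) records.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(COORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CoordinateTableError(f"coordinate table lacks columns: {sorted(missing_cols)}")
    df = df[df["region_id"].astype(str) == annotation.region_id]

    lookup = {
        (int(s), int(e)): i
        for i, (s, e) in enumerate(zip(annotation.starts, annotation.ends))
    }
    K = annotation.K
    traces: dict[tuple[str, str], np.ndarray] = {}
    filled: dict[tuple[str, str], set[int]] = {}
    for row in df.itertuples():
        key = (int(row.start), int(row.end))
        if key not in lookup:
            raise CoordinateTableError(
                f"row {row.Index}: locus {annotation.chrom}:{row.start}-{row.end} "
                f"not in annotation of region {annotation.region_id!r}"
            )
        locus = lookup[key]
        ident = (str(row.cell_id), str(row.allele_id))
        if ident not in traces:
            traces[ident] = np.full((K, 3), np.nan)
            filled[ident] = set()
        if locus in filled[ident]:
            raise CoordinateTableError(
                f"row {row.Index}: duplicate record for cell {ident[0]!r} allele "
                f"{ident[1]!r} locus {locus + 1}"
            )
        filled[ident].add(locus)
        traces[ident][locus] = (row.x, row.y, row.z)

    out = [
        ChromosomeTrace(cell, allele, annotation.region_id, coords)
        for (cell, allele), coords in traces.items()
    ]
    return TraceCollection(annotation, out)


def collection_to_frame(collection: TraceCollection) -> pd.DataFrame:
    """Flatten a collection to the coordinate-table layout (observed rows only)."""
    ann = collection.annotation
    rows = []
    for t in collection.traces:
        obs = np.flatnonzero(t.observed)
        for i in obs:
            rows.append(
                (
                    t.cell_id,
                    t.allele_id,
                    ann.region_id,
                    ann.chrom,
                    int(ann.starts[i]),
                    int(ann.ends[i]),
                    t.coords[i, 0],
                    t.coords[i, 1],
                    t.coords[i, 2],
                )
            )
    return pd.DataFrame(rows, columns=COORD_COLUMNS)


def write_coordinate_table(collection: TraceCollection, path) -> None:
    """Write a collection as a coordinate CSV; missing loci are omitted.

    Round trip with :func:`read_coordinate_table` is lossless for
    coordinates (bit exact via repr-precision floats) and missing masks.
    """
    df = collection_to_frame(collection)
    df.to_csv(path, index=False, float_format="%.17g")
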