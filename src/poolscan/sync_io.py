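"""Reading and writing popoolation2-style ``sync`` files and pool designs.

A sync file is tab-separated with one row per reference position::

    contig  position  ref_base  A:T:C:G:N:del  A:T:C:G:N:del  ...

one colon-separated count field per pooled sample, in a fixed column order.
The sample design table maps that column order onto the experimental layout
(country x ecotype x replicate), which everything downstream indexes into.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "T", "C", "G")
#: valid ecotype labels (crab = sheltered/predation habitat, wave = exposed)
ECOTYPES = ("crab", "wave")

_N_SYNC_FIELDS = 6


class SyncParseError(ValueError):
    """Raised when a sync file or count field cannot be parsed."""


class DesignError(ValueError):
    """Raised when a sample design table is inconsistent."""


@dataclass(frozen=True)
class SiteCounts:
    """Allele counts for one pooled sample at one position (one sync cell).

    ``coverage`` counts called bases only: Ns and deletion-supporting reads
    are tracked but never contribute to allele frequencies.
    """

    a: int = 0
    t: int = 0
    c: int = 0
    g: int = 0
    n: int = 0
    dele: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "t", "c", "g", "n", "dele"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name!r}: {getattr(self, name)}")

    @property
    def coverage(self) -> int:
        return self.a + self.t + self.c + self.g

    @property
    def nucleotide_counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.t, self.c, self.g)

    def to_field(self) -> str:
        return f"{self.a}:{self.t}:{self.c}:{self.g}:{self.n}:{self.dele}"


def parse_count_field(text: str, *, line: int | None = None, column: int | None = None) -> SiteCounts:
    """Parse one ``A:T:C:G:N:del`` cell into :class:`SiteCounts`."""
    where = ""
    if line is not None:
        where = f" at line {line}" + (f", column {column}" if column is not None else "")
    parts = text.split(":")
    if len(parts) != _N_SYNC_FIELDS:
        raise SyncParseError(
            f"count field {text!r}{where}: expected {_N_SYNC_FIELDS} colon-separated "
            f"values, got {len(parts)}"
        )
    values = []
    for part in parts:
        try:
            value = int(part)
        except ValueError:
            raise SyncParseError(f"count field {text!r}{where}: non-integer value {part!r}") from None
        if value < 0:
            raise SyncParseError(f"count field {text!r}{where}: negative value {value}")
        values.append(value)
    return SiteCounts(*values)


@dataclass(frozen=True)
class SyncRecord:
    """One sync line: a reference position with counts for every sample."""

    contig: str
    position: int
    ref_base: str
    samples: tuple[SiteCounts, ...]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def to_line(self) -> str:
        fields = [self.contig, str(self.position), self.ref_base]
        fields.extend(s.to_field() for s in self.samples)
        return "\t".join(fields)


@dataclass(frozen=True)
class PoolSample:
    sample_id: str
    country: str
    ecotype: str
    replicate: int

    @property
    def triple(self) -> tuple[str, str, int]:
        return (self.country, self.ecotype, self.replicate)


class PoolDesign:
    """Ordered sample layout: which sync column is which (country, ecotype, replicate).

    Row order must mirror sync column order. Validates that every
    (country, ecotype, replicate) triple occurs exactly once and that all
    countries share the same ecotype x replicate grid.
    """

    def __init__(self, samples: Sequence[PoolSample]):
        samples = tuple(samples)
        if not samples:
            raise DesignError("design has no samples")
        triples = [s.triple for s in samples]
        dupes = {t for t in triples if triples.count(t) > 1}
        if dupes:
            raise DesignError(f"duplicated (country, ecotype, replicate) triples: {sorted(dupes)}")
        for s in samples:
            if s.ecotype not in ECOTYPES:
                raise DesignError(f"unknown ecotype {s.ecotype!r} for sample {s.sample_id!r} "
                                  f"(expected one of {ECOTYPES})")
        countries = sorted({s.country for s in samples})
        replicates = sorted({s.replicate for s in samples})
        grid = {(e, r) for e in ECOTYPES for r in replicates}
        for country in countries:
            have = {(s.ecotype, s.replicate) for s in samples if s.country == country}
            missing = grid - have
            if missing:
                raise DesignError(f"country {country!r} is missing pools: {sorted(missing)}")
        self.samples = samples
        self.countries = tuple(countries)
        self.replicates = tuple(replicates)
        self._index = {s.triple: i for i, s in enumerate(samples)}

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PoolDesign) and self.samples == other.samples

    def index(self, country: str, ecotype: str, replicate: int) -> int:
        return self._index[(country, ecotype, replicate)]

    def replicate_pairs(self, country: str) -> list[tuple[int, int]]:
        """Between-ecotype (crab_r, wave_r) column pairs, one per replicate."""
        return [
            (self.index(country, "crab", r), self.index(country, "wave", r))
            for r in self.replicates
        ]

    def within_ecotype_pairs(self, country: str) -> list[tuple[int, int]]:
        """Within-ecotype (crab1, crab2) and (wave1, wave2) column pairs."""
        pairs = []
        for ecotype in ECOTYPES:
            for r1, r2 in itertools.combinations(self.replicates, 2):
                pairs.append((self.index(country, ecotype, r1), self.index(country, ecotype, r2)))
        return pairs

    def between_country_pairs(self, country_a: str, country_b: str) -> list[tuple[int, int]]:
        """Ecotype/replicate-matched cross-country column pairs (crab_r vs crab_r, ...)."""
        return [
            (self.index(country_a, e, r), self.index(country_b, e, r))
            for e in ECOTYPES
            for r in self.replicates
        ]

    def country_pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.countries, 2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "country": [s.country for s in self.samples],
                "ecotype": [s.ecotype for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


def read_design(path: str | Path) -> PoolDesign:
    """Read a design TSV (sample_id, country, ecotype, replicate; sync column order)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "country": str, "ecotype": str})
    required = {"sample_id", "country", "ecotype", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise DesignError(f"design file {path}: missing columns {sorted(missing)}")
    samples = [
        PoolSample(row.sample_id, row.country, row.ecotype, int(row.replicate))
        for row in frame.itertuples(index=False)
    ]
    return PoolDesign(samples)


def write_design(design: PoolDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_sync(path: str | Path, design: PoolDesign) -> Iterator[SyncRecord]:
    """Stream sync records, validating every line against the design width."""
    n_samples = len(design)
    expected_cols = 3 + n_samples
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected_cols:
                raise SyncParseError(
                    f"{path}:{line_no}: expected {expected_cols} columns for a "
                    f"{n_samples}-sample design, got {len(fields)}"
                )
            try:
                position = int(fields[1])
            except ValueError:
                raise SyncParseError(f"{path}:{line_no}: non-integer position {fields[1]!r}") from None
            counts = tuple(
                parse_count_field(field, line=line_no, column=i + 4)
                for i, field in enumerate(fields[3:])
            )
            try:
                yield SyncRecord(fields[0], position, fields[2], counts)
            except ValueError as exc:
                raise SyncParseError(f"{path}:{line_no}: {exc}") from None


def write_sync(records: Iterable[SyncRecord], path: str | Path) -> int:
    """Write records in sync format; returns the number of lines written."""
    n = 0
    with open(path, "w") as handle:
        for record in records:
            handle.write(record.to_line())
            handle.write("\n")
            n += 1
    return n


class SyncMatrix:
    """Array-backed view of a sync file for the vectorised pipeline stages.

    Attributes
    ----------
    contig, position, ref_base : 1-D arrays of length ``n_sites``
    counts : int array of shape ``(n_sites, n_samples, 6)`` in A,T,C,G,N,del order
    """

    def __init__(self, contig, position, ref_base, counts):
        self.contig = np.asarray(contig, dtype=object)
        self.position = np.asarray(position, dtype=np.int64)
        self.ref_base = np.asarray(ref_base, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != _N_SYNC_FIELDS:
            raise ValueError(f"counts must have shape (sites, samples, 6), got {self.counts.shape}")
        if not (len(self.contig) == len(self.position) == len(self.ref_base) == self.counts.shape[0]):
            raise ValueError("inconsistent site dimensions")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def nucleotide_counts(self) -> np.ndarray:
        """Called-base counts only, shape (sites, samples, 4)."""
        return self.counts[:, :, :4]

    def select(self, mask: np.ndarray) -> "SyncMatrix":
        return SyncMatrix(self.contig[mask], self.position[mask], self.ref_base[mask], self.counts[mask])

    @classmethod
    def from_records(cls, records: Iterable[SyncRecord]) -> "SyncMatrix":
        contigs, positions, refs, counts = [], [], [], []
        for rec in records:
            contigs.append(rec.contig)
            positions.append(rec.position)
            refs.append(rec.ref_base)
            counts.append([(s.a, s.t, s.c, s.g, s.n, s.dele) for s in rec.samples])
        if not contigs:
            return cls(
                np.empty(0, dtype=object),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=object),
                np.empty((0, 0, _N_SYNC_FIELDS), dtype=np.int64),
            )
        return cls(contigs, positions, refs, np.asarray(counts, dtype=np.int64))

    def to_records(self) -> Iterator[SyncRecord]:
        for i in range(self.n_sites):
            samples = tuple(SiteCounts(*map(int, self.counts[i, j])) for j in range(self.n_samples))
            yield SyncRecord(str(self.contig[i]), int(self.position[i]), str(self.ref_base[i]), samples)

    @classmethod
    def read(cls, path: str | Path, design: PoolDesign) -> "SyncMatrix":
        return cls.from_records(read_sync(path, design))

    def write(self, path: str | Path) -> int:
        return write_sync(self.to_records(), path)
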