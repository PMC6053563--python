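"""Core data model for diploid SSR genotypes.

The central container is :class:`GenotypeDataset`: an ordered collection of
sampling areas (populations), each holding diploid multi-locus genotypes
coded as positive integer allele labels (typically fragment/repeat sizes).
A call is stored as an unordered pair of allele codes; ``0`` marks a missing
gene, and a genotype with either gene missing is treated as fully missing
(the GenePop convention, which keeps per-locus gene counts even).

The module also provides GenePop text I/O, allele-frequency computation,
DMS coordinate parsing and great-circle distances for isolation-by-distance
analyses.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "AlleleFreqTable",
    "AreaMetadata",
    "GenePopFormatError",
    "read_genepop",
    "write_genepop",
    "read_metadata",
    "allele_frequencies",
    "parse_dms",
    "great_circle_km",
    "distance_matrix_km",
]

#: Allele code marking a missing gene.
MISSING = 0

EARTH_RADIUS_KM = 6371.0088


class GenePopFormatError(ValueError):
    """Raised for malformed GenePop input or unrepresentable output."""


@dataclass
class GenotypeDataset:
    """Diploid multi-locus, multi-area genotype matrix.

    Parameters
    ----------
    areas : list of str
        Ordered area (population) labels.
    individuals : dict
        Per-area ordered lists of individual identifiers.
    loci : list of str
        Ordered locus names, identical across areas.
    calls : dict
        Per-area integer arrays of shape ``(n_individuals, n_loci, 2)``.
        ``0`` denotes a missing gene; a half-missing call is normalised to
        fully missing on construction.
    """

    areas: list[str]
    individuals: dict[str, list[str]]
    loci: list[str]
    calls: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.areas:
            raise ValueError("dataset must contain at least one area")
        if not self.loci:
            raise ValueError("dataset must contain at least one locus")
        if len(set(self.areas)) != len(self.areas):
            raise ValueError("area labels must be unique")
        for area in self.areas:
            arr = np.asarray(self.calls[area], dtype=np.int64)
            n_ind = len(self.individuals[area])
            if arr.shape != (n_ind, len(self.loci), 2):
                raise ValueError(
                    f"calls for area {area!r} have shape {arr.shape}, "
                    f"expected ({n_ind}, {len(self.loci)}, 2)"
                )
            if (arr < 0).any():
                raise ValueError("allele codes must be non-negative")
            # half-missing -> fully missing
            half = (arr == MISSING).any(axis=2)
            arr[half] = MISSING
            self.calls[area] = arr

    # -- convenience -------------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def n_individuals(self, area: str) -> int:
        return len(self.individuals[area])

    @property
    def total_individuals(self) -> int:
        return sum(len(v) for v in self.individuals.values())

    def area_calls(self, area: str) -> np.ndarray:
        """Calls array ``(n_ind, n_loci, 2)`` for one area."""
        return self.calls[area]

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def drop_loci(self, exclude: list[str]) -> "GenotypeDataset":
        """Return a copy without the named loci."""
        keep = [i for i, l in enumerate(self.loci) if l not in exclude]
        if not keep:
            raise ValueError("cannot drop every locus")
        return GenotypeDataset(
            areas=list(self.areas),
            individuals={a: list(v) for a, v in self.individuals.items()},
            loci=[self.loci[i] for i in keep],
            calls={a: self.calls[a][:, keep, :].copy() for a in self.areas},
        )

    def subset_areas(self, areas: list[str]) -> "GenotypeDataset":
        """Return a copy restricted to the named areas (in the given order)."""
        return GenotypeDataset(
            areas=list(areas),
            individuals={a: list(self.individuals[a]) for a in areas},
            loci=list(self.loci),
            calls={a: self.calls[a].copy() for a in areas},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        if (self.areas, self.loci) != (other.areas, other.loci):
            return False
        for area in self.areas:
            if self.individuals[area] != other.individuals[area]:
                return False
            a = np.sort(self.calls[area], axis=2)
            b = np.sort(other.calls[area], axis=2)
            if not np.array_equal(a, b):
                return False
        return True


class AlleleFreqTable:
    """Per-(area, locus) allele counts and relative frequencies.

    Also exposes pooled (species-level) frequencies, which weight areas by
    their gene counts — i.e. they equal a direct recount over the pooled
    sample.
    """

    def __init__(self, dataset: GenotypeDataset):
        self.areas = list(dataset.areas)
        self.loci = list(dataset.loci)
        self._counts: dict[tuple[str, str], dict[int, int]] = {}
        self._genes: dict[tuple[str, str], int] = {}
        for area in self.areas:
            arr = dataset.area_calls(area)
            for j, locus in enumerate(self.loci):
                genes = arr[:, j, :].ravel()
                genes = genes[genes != MISSING]
                alleles, counts = np.unique(genes, return_counts=True)
                self._counts[(area, locus)] = dict(
                    zip(alleles.tolist(), counts.tolist())
                )
                self._genes[(area, locus)] = int(genes.size)

    def counts(self, area: str, locus: str) -> dict[int, int]:
        return dict(self._counts[(area, locus)])

    def gene_count(self, area: str, locus: str) -> int:
        """Number of non-missing genes (2 * typed individuals)."""
        return self._genes[(area, locus)]

    def allele_count(self, area: str, locus: str) -> int:
        return len(self._counts[(area, locus)])

    def freq(self, area: str, locus: str) -> dict[int, float]:
        n = self._genes[(area, locus)]
        if n == 0:
            return {}
        return {a: c / n for a, c in self._counts[(area, locus)].items()}

    def pooled_counts(self, locus: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for area in self.areas:
            for a, c in self._counts[(area, locus)].items():
                out[a] = out.get(a, 0) + c
        return out

    def pooled_freq(self, locus: str) -> dict[int, float]:
        counts = self.pooled_counts(locus)
        n = sum(counts.values())
        if n == 0:
            return {}
        return {a: c / n for a, c in counts.items()}

    def alleles_in_area(self, area: str, locus: str) -> set[int]:
        return set(self._counts[(area, locus)])


def allele_frequencies(dataset: GenotypeDataset) -> AlleleFreqTable:
    """Compute per-(area, locus) allele frequencies over non-missing genes."""
    return AlleleFreqTable(dataset)


@dataclass(frozen=True)
class AreaMetadata:
    """Sampling-area metadata: label, preservation class and coordinates."""

    label: str
    preservation: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if abs(self.longitude) > 180:
            raise ValueError(f"longitude {self.longitude} out of range")


# -- GenePop I/O -----------------------------------------------------------


def _parse_genotype(token: str, allele_digits: int, lineno: int) -> tuple[int, int]:
    if len(token) != 2 * allele_digits or not token.isdigit():
        raise GenePopFormatError(
            f"line {lineno}: genotype {token!r} is not {2 * allele_digits} digits"
        )
    return int(token[:allele_digits]), int(token[allele_digits:])


def read_genepop(path, allele_digits: int = 3) -> GenotypeDataset:
    """Read a GenePop text file into a :class:`GenotypeDataset`.

    The first line is a title; locus names follow, one per line or
    comma-separated on one line; populations are delimited by lines equal to
    ``pop`` (case-insensitive). Allele code 0 (``00``/``000``) is missing.
    Area labels are taken from the ID of the last individual of each pop
    (the GenePop custom), with any trailing ``_NNN`` counter stripped;
    falls back to ``pop1``, ``pop2``, ...
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopFormatError("empty file")

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise GenePopFormatError("no locus names before first 'Pop'")
    if i >= len(lines):
        raise GenePopFormatError("no 'Pop' separator found")

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            current = []
            pops.append(current)
            continue
        if current is None:
            raise GenePopFormatError(f"line {lineno + 1}: genotype before 'Pop'")
        if "," not in line:
            raise GenePopFormatError(f"line {lineno + 1}: missing ',' after ID")
        ident, rest = line.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenePopFormatError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, got {len(tokens)}"
            )
        genos = [_parse_genotype(t, allele_digits, lineno + 1) for t in tokens]
        current.append((ident.strip(), genos))

    if not pops or all(not p for p in pops):
        raise GenePopFormatError("no populations with individuals")

    areas: list[str] = []
    individuals: dict[str, list[str]] = {}
    calls: dict[str, np.ndarray] = {}
    for pi, pop in enumerate(pops):
        if not pop:
            raise GenePopFormatError(f"population {pi + 1} has no individuals")
        label = pop[-1][0].rstrip("0123456789").rstrip("_") or f"pop{pi + 1}"
        if label in individuals:  # keep labels unique
            label = f"{label}_{pi + 1}"
        areas.append(label)
        individuals[label] = [ident for ident, _ in pop]
        arr = np.array([g for _, g in pop], dtype=np.int64)
        calls[label] = arr
    return GenotypeDataset(areas=areas, individuals=individuals, loci=loci, calls=calls)


def write_genepop(
    dataset: GenotypeDataset, path, allele_digits: int = 3, title: str = "ssrpopgen export"
) -> None:
    """Write a dataset as GenePop text; inverse of :func:`read_genepop`."""
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    limit = 10**allele_digits
    for area in dataset.areas:
        if (dataset.calls[area] >= limit).any():
            raise GenePopFormatError(
                f"allele code >= {limit} cannot be written with {allele_digits} digits"
            )
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in dataset.loci:
            fh.write(locus + "\n")
        for area in dataset.areas:
            fh.write("Pop\n")
            ids = dataset.individuals[area]
            arr = dataset.calls[area]
            for i, ident in enumerate(ids):
                genos = " ".join(
                    f"{a:0{allele_digits}d}{b:0{allele_digits}d}"
                    for a, b in arr[i]
                )
                fh.write(f"{ident}, {genos}\n")


def read_metadata(path) -> list[AreaMetadata]:
    """Read area metadata from CSV with columns label, preservation, lat_dms, lon_dms."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AreaMetadata(
                    label=row["label"].strip(),
                    preservation=row["preservation"].strip(),
                    latitude=parse_dms(row["lat_dms"]),
                    longitude=parse_dms(row["lon_dms"]),
                )
            )
    labels = [m.label for m in out]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate area labels in metadata")
    return out


# -- coordinates and distances --------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d{1,3})\s*[°º]\s*(\d{1,2})\s*[′'’]\s*(\d{1,2}(?:\.\d+)?)\s*[″"”]\s*([NSEW])\s*$""",
    re.IGNORECASE,
)


def parse_dms(text: str) -> float:
    """Parse a D°M′S″[NSEW] coordinate string into signed decimal degrees.

    South and West are negative. Minutes or seconds >= 60 are rejected.
    """
    m = _DMS_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse DMS coordinate: {text!r}")
    deg, minutes, seconds, hemi = m.groups()
    minutes = float(minutes)
    seconds = float(seconds)
    if minutes >= 60 or seconds >= 60:
        raise ValueError(f"minutes/seconds out of range in {text!r}")
    value = float(deg) + minutes / 60 + seconds / 3600
    if hemi.upper() in ("S", "W"):
        value = -value
    return value


def great_circle_km(a: AreaMetadata, b: AreaMetadata) -> float:
    """Haversine great-circle distance in km (spherical Earth, R=6371.0088)."""
    lat1, lon1 = math.radians(a.latitude), math.radians(a.longitude)
    lat2, lon2 = math.radians(b.latitude), math.radians(b.longitude)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def distance_matrix_km(metadata: list[AreaMetadata]) -> np.ndarray:
    """Symmetric matrix of pairwise great-circle distances, in input order."""
    n = len(metadata)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = great_circle_km(metadata[i], metadata[j])
    return d
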