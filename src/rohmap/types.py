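"""Core data containers shared across the homozygosity-mapping pipeline.

Genotypes are coded per marker as 0 (homozygous reference), 1 (heterozygous),
2 (homozygous alternate) and :data:`MISSING` (= -1) for a missing call.
All genomic coordinates in the pipeline are 1-based inclusive base pairs,
the convention of PLINK MAP files.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

#: Genotype code for a missing call.
MISSING: int = -1

#: Largest autosome number accepted (cattle have 29 autosomes).
MAX_AUTOSOME: int = 29


class FormatError(ValueError):
    """Raised when an input file violates its declared text format."""


class PipelineError(ValueError):
    """Raised when pipeline inputs violate a documented precondition."""


# ---------------------------------------------------------------------------
# marker map / genotypes
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered autosomal SNP map.

    Markers must be strictly sorted by (chromosome, position); duplicate
    positions on a chromosome are rejected. ``chromosome_lengths`` may carry
    assembly lengths in bp; when absent, the position of the last marker on
    each chromosome is used wherever a chromosome length is needed.
    """

    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    chromosome_lengths: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=np.int64)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        n = len(self.marker_ids)
        if not (len(self.chromosomes) == len(self.positions_bp) == n):
            raise PipelineError("marker map columns have unequal lengths")
        if n:
            if self.chromosomes.min() < 1 or self.chromosomes.max() > MAX_AUTOSOME:
                raise PipelineError(
                    f"chromosome codes must be autosomes in 1..{MAX_AUTOSOME}"
                )
            if self.positions_bp.min() < 1:
                raise PipelineError("marker positions must be >= 1 bp")
            order = np.lexsort((self.positions_bp, self.chromosomes))
            if not np.array_equal(order, np.arange(n)):
                raise PipelineError(
                    "markers must be strictly sorted by (chromosome, position)"
                )
            same_chrom = self.chromosomes[1:] == self.chromosomes[:-1]
            if np.any(same_chrom & (np.diff(self.positions_bp) == 0)):
                raise PipelineError("duplicate marker positions on one chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @cached_property
    def chromosome_list(self) -> list[int]:
        return sorted(set(self.chromosomes.tolist()))

    def chrom_slice(self, chromosome: int) -> slice:
        """Index slice of the markers on one chromosome (markers are sorted)."""
        lo = int(np.searchsorted(self.chromosomes, chromosome, side="left"))
        hi = int(np.searchsorted(self.chromosomes, chromosome, side="right"))
        return slice(lo, hi)

    def chrom_length(self, chromosome: int) -> int:
        """Chromosome length in bp: supplied assembly length, else last marker."""
        if self.chromosome_lengths and chromosome in self.chromosome_lengths:
            return int(self.chromosome_lengths[chromosome])
        sl = self.chrom_slice(chromosome)
        if sl.start == sl.stop:
            raise PipelineError(f"no markers on chromosome {chromosome}")
        return int(self.positions_bp[sl.stop - 1])

    def covered_span(self, chromosome: int) -> int:
        """bp span from the first to the last marker of a chromosome (inclusive)."""
        sl = self.chrom_slice(chromosome)
        if sl.start == sl.stop:
            return 0
        return int(self.positions_bp[sl.stop - 1] - self.positions_bp[sl.start] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosomes,
                "position_bp": self.positions_bp,
            }
        )


@dataclass
class GenotypeDataset:
    """Animals x markers genotype matrix with its marker map."""

    animal_ids: list[str]
    markers: MarkerMap
    genotypes: np.ndarray  # int8, shape (n_animals, n_markers)

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise PipelineError("animal ids must be unique")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        expected = (len(self.animal_ids), self.markers.n_markers)
        if self.genotypes.shape != expected:
            raise PipelineError(
                f"genotype matrix shape {self.genotypes.shape} != {expected}"
            )
        legal = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not legal.all():
            bad = np.unique(self.genotypes[~legal])
            raise PipelineError(f"illegal genotype codes present: {bad.tolist()}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers


# ---------------------------------------------------------------------------
# phenotypes / pedigree
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """One sire conception rate (SCR) record per animal.

    ``scr`` is a percent deviation from the population mean (may be negative),
    ``n_breedings`` the number of breedings backing the record (>= 1).
    """

    animal_ids: list[str]
    scr: np.ndarray
    n_breedings: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.scr = np.asarray(self.scr, dtype=float)
        self.n_breedings = np.asarray(self.n_breedings, dtype=np.int64)
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise PipelineError("phenotype table has duplicate animal ids")
        if not (len(self.animal_ids) == len(self.scr) == len(self.n_breedings)):
            raise PipelineError("phenotype columns have unequal lengths")
        if len(self.scr) and not np.isfinite(self.scr).all():
            raise PipelineError("SCR values must be finite")
        if len(self.n_breedings) and self.n_breedings.min() < 1:
            raise PipelineError("n_breedings must be >= 1")

    def __len__(self) -> int:
        return len(self.animal_ids)

    @cached_property
    def by_animal(self) -> dict[str, tuple[float, int]]:
        return {
            a: (float(s), int(b))
            for a, s, b in zip(self.animal_ids, self.scr, self.n_breedings)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_ids,
                "scr": self.scr,
                "n_breedings": self.n_breedings,
            }
        )


@dataclass
class Pedigree:
    """Sire/dam triples; ``None`` marks an unknown parent.

    Construction verifies acyclicity and caches a topological order
    (every parent precedes its offspring).
    """

    records: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        seen = set()
        for animal, _, _ in self.records:
            if animal in seen:
                raise PipelineError(f"duplicate pedigree record for {animal!r}")
            seen.add(animal)
        self._parents = {a: (s, d) for a, s, d in self.records}
        # include parents that never appear as animals: they are founders
        graph: dict[str, set[str]] = {}
        for animal, sire, dam in self.records:
            deps = graph.setdefault(animal, set())
            for p in (sire, dam):
                if p is not None:
                    deps.add(p)
                    graph.setdefault(p, set())
        try:
            self._topo = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1]
            raise PipelineError(
                f"pedigree contains a cycle through animal {cycle[0]!r}"
            ) from exc

    @property
    def animals(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        """(sire, dam) of ``animal``; implicit founders have unknown parents."""
        return self._parents.get(animal, (None, None))

    @property
    def topological_order(self) -> list[str]:
        """All animals (incl. implicit founders), parents before offspring."""
        return list(self._topo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["animal_id", "sire_id", "dam_id"]
        )


# ---------------------------------------------------------------------------
# ROH calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROHParameters:
    """Sliding-window ROH calling parameters.

    ``window_snp``/``window_het``/``window_missing``/``max_gap_kb`` follow the
    PLINK ``--homozyg`` flags used in the study; the remaining fields are the
    tool defaults for the final segment filters: a segment must contain at
    least ``min_snp`` markers, span at least ``min_length_kb``, and be no
    sparser than ``max_density_kb_per_snp`` kb per SNP. ``hit_threshold`` is
    the minimum proportion of homozygous windows overlapping a SNP for that
    SNP to be eligible for a run.
    """

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 1
    max_gap_kb: float = 500.0
    hit_threshold: float = 0.05
    min_snp: int = 100
    min_length_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snp < 1:
            raise PipelineError("window_snp must be >= 1")
        for name in ("window_het", "window_missing"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be >= 0")
        if not (0.0 < self.hit_threshold <= 1.0):
            raise PipelineError("hit_threshold must be in (0, 1]")
        if self.max_gap_kb < 0:
            raise PipelineError("max_gap_kb must be >= 0")
        if self.min_snp < 0:
            raise PipelineError("min_snp must be >= 0")
        if self.min_length_kb <= 0:
            raise PipelineError("min_length_kb must be > 0")
        if self.max_density_kb_per_snp <= 0:
            raise PipelineError("max_density_kb_per_snp must be > 0")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity: a contiguous autozygous stretch of one animal.

    ``start_bp``/``end_bp`` sit on homozygous non-missing markers; ``n_snp``
    counts the markers spanned inside [start, end]; ``n_het``/``n_missing``
    count the (tolerated) heterozygous and missing calls inside the span.
    """

    animal_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snp: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0

    def covers(self, chromosome: int, start_bp: int, end_bp: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start_bp <= start_bp
            and self.end_bp >= end_bp
        )


@dataclass
class ROHResult:
    """All ROH segments of one study, with the calling parameters used.

    ``animal_ids`` lists every animal of the input dataset so that animals
    with zero segments are represented. ``markers`` (optional) carries the
    map the segments were called on, needed for F_ROH denominators.
    """

    parameters: ROHParameters
    segments: list[ROHSegment]
    animal_ids: list[str]
    markers: MarkerMap | None = None

    @cached_property
    def per_animal(self) -> dict[str, list[ROHSegment]]:
        index: dict[str, list[ROHSegment]] = {a: [] for a in self.animal_ids}
        for seg in self.segments:
            index.setdefault(seg.animal_id, []).append(seg)
        return index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [s.animal_id for s in self.segments],
                "chrom": [s.chromosome for s in self.segments],
                "start_bp": [s.start_bp for s in self.segments],
                "end_bp": [s.end_bp for s in self.segments],
                "length_kb": [s.length_kb for s in self.segments],
                "n_snp": [s.n_snp for s in self.segments],
                "n_het": [s.n_het for s in self.segments],
                "n_missing": [s.n_missing for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# summaries / association
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalROHStats:
    """Per-animal homozygosity summary derived from the ROH calls."""

    animal_id: str
    n_segments: int
    total_length_kb: float
    mean_length_kb: float
    max_length_kb: float
    f_roh: float

    @property
    def total_length_mb(self) -> float:
        return self.total_length_kb / 1000.0


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear regression fit of SCR on a homozygosity predictor."""

    beta: float
    intercept: float
    se_beta: float
    t_value: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapRegion:
    """Genomic interval with a constant set of ROH carriers.

    ``carriers`` holds the animals whose ROH segments fully cover
    [start_bp, end_bp]; by construction the set is identical at every bp of
    the region.
    """

    chromosome: int
    start_bp: int
    end_bp: int
    n_snp: int
    carriers: frozenset[str]

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 Fisher test of one overlap region against the fertility extremes.

    ``a`` = low-fertility carriers, ``b`` = low non-carriers,
    ``c`` = high-fertility carriers, ``d`` = high non-carriers.
    """

    region: OverlapRegion
    a: int
    b: int
    c: int
    d: int
    p_value: float


# ---------------------------------------------------------------------------
# mixed-model validation
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """Genomic relationship matrix over a set of animals."""

    animal_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise PipelineError("GRM shape does not match animal count")
        if not np.isfinite(self.matrix).all():
            raise PipelineError("GRM contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise PipelineError("GRM is not symmetric")

    def subset(self, animal_ids: list[str]) -> "GRM":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = np.array([idx[a] for a in animal_ids])
        return GRM(list(animal_ids), self.matrix[np.ix_(rows, rows)])


@dataclass
class MixedModelFit:
    """REML fit of the animal model y = Xb + u + e, u ~ N(0, G sigma_g2)."""

    beta: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    converged: bool

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass(frozen=True)
class RegionValidation:
    """Mixed-model result for one candidate region on the full population."""

    region: OverlapRegion
    n_carriers: int
    beta: float
    se: float
    t_value: float
    validated: bool
    untestable: bool = False


@dataclass
class ValidationReport:
    """Per-region mixed-model validation results."""

    results: list[RegionValidation]
    threshold: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "chrom": r.region.chromosome,
                    "start_bp": r.region.start_bp,
                    "end_bp": r.region.end_bp,
                    "n_carriers": r.n_carriers,
                    "beta": r.beta,
                    "se": r.se,
                    "t_value": r.t_value,
                    "validated": r.validated,
                    "untestable": r.untestable,
                }
            )
        return pd.DataFrame(rows)
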