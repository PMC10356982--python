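"""Synthetic study generator with exported ground truth.

Generates a complete desk-scale analogue of a dense-chip bull-fertility
study: a multi-generation pedigree with related matings (so pedigree
inbreeding varies), HWE background genotypes on an exponentially spaced
autosomal SNP map, directly planted autozygous tracts whose per-animal rate
scales with pedigree inbreeding, designated risk regions whose carriers
receive a fertility penalty, and a sire-conception-rate phenotype with an
inbreeding-depression slope on total ROH length plus a GRM-correlated
polygenic term. Every random draw derives from ``config.seed``, so a study
is byte-for-byte reproducible.

Tracts are planted in genotype space rather than via coalescent ancestry:
the exact ground-truth intervals are what downstream stages must recover,
and LD-realistic haplotype structure is deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import write_ped_map, write_pedigree, write_phenotypes
from .mixed_model import GRM_RIDGE, compute_grm
from .summary import pedigree_inbreeding
from .types import (
    MISSING,
    GRM,
    GenotypeDataset,
    MarkerMap,
    Pedigree,
    PhenotypeTable,
    PipelineError,
)

__all__ = [
    "RiskRegion",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_study",
    "generate_study",
]


@dataclass(frozen=True)
class RiskRegion:
    """A genomic interval whose ROH carriers incur an SCR penalty.

    ``effect`` is added (it is negative for a penalty) to the SCR of every
    carrier; carriers are drawn at rate ``carrier_freq`` and receive a
    planted autozygous tract covering the whole region.
    """

    chromosome: int
    start_bp: int
    end_bp: int
    effect: float
    carrier_freq: float = 0.12


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    The defaults describe the package's reference study: 800 bulls on a
    5-chromosome, 4,000-markers-per-chromosome map with ~25 kb mean marker
    spacing (~100 Mb per chromosome), autozygous tracts at about two per
    chromosome with gamma(2, 4 Mb) lengths so that roughly 16% of the
    covered genome lies in ROH, an inbreeding-depression slope of
    -0.01 SCR% per Mb of ROH, and one planted 3-Mb risk region with a
    -4 SCR% carrier penalty.
    """

    n_animals: int = 800
    n_chromosomes: int = 5
    markers_per_chromosome: int = 4000
    mean_spacing_kb: float = 25.0
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    # autozygous tract planting
    roh_rate_per_chrom: float = 2.0
    roh_length_shape: float = 2.0
    roh_length_scale_kb: float = 4000.0
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.002
    # marker-map gap structure (tests the gap-splitting rule)
    n_large_gaps_per_chrom: int = 2
    large_gap_kb_range: tuple[float, float] = (100.0, 800.0)
    # fertility model
    risk_regions: tuple[RiskRegion, ...] = (
        RiskRegion(2, 40_000_000, 43_000_000, effect=-4.0, carrier_freq=0.12),
    )
    beta_length: float = -0.01  # SCR % per Mb of total planted ROH
    h2: float = 0.3  # polygenic heritability of the residual SCR
    sigma_e: float = 2.0  # residual sd, SCR %
    mu: float = 0.0
    # pedigree
    pedigree_depth: int = 4
    n_sires: int = 25
    close_mating_rate: float = 0.15
    inbreeding_roh_slope: float = 4.0  # tract rate multiplier: 1 + slope * F
    n_breedings_range: tuple[int, int] = (50, 8110)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise PipelineError("allele_freq_range must lie in (0, 0.5]")
        for name in (
            "roh_rate_per_chrom",
            "genotyping_error_rate",
            "missing_rate",
            "close_mating_rate",
        ):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be >= 0")
        if self.pedigree_depth < 1:
            raise PipelineError("pedigree_depth must be >= 1")
        if not (0.0 <= self.h2 < 1.0):
            raise PipelineError("h2 must be in [0, 1)")
        if self.n_chromosomes < 1 or self.n_chromosomes > 29:
            raise PipelineError("n_chromosomes must be in 1..29")

    @property
    def sigma_g2(self) -> float:
        """Polygenic variance implied by h2 and sigma_e."""
        return self.h2 / (1.0 - self.h2) * self.sigma_e**2

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "risk_regions" in data:
            data["risk_regions"] = tuple(
                RiskRegion(**r) if isinstance(r, dict) else RiskRegion(*r)
                for r in data["risk_regions"]
            )
        for key in ("allele_freq_range", "large_gap_kb_range", "n_breedings_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["risk_regions"] = [dataclasses.asdict(r) for r in self.risk_regions]
        return d


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    tracts: dict[str, list[tuple[int, int, int, bool]]]  # chrom,start,end,truncated
    true_total_mb: dict[str, float]
    beta_length: float
    risk_regions: list[dict]  # region fields + carrier id list
    sigma_g2: float
    sigma_e2: float
    f_ped: dict[str, float]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tracts": self.tracts,
                    "true_total_mb": self.true_total_mb,
                    "beta_length": self.beta_length,
                    "risk_regions": self.risk_regions,
                    "sigma_g2": self.sigma_g2,
                    "sigma_e2": self.sigma_e2,
                    "f_ped": self.f_ped,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["tracts"] = {
            a: [tuple(t) for t in ts] for a, ts in data["tracts"].items()
        }
        return cls(**data)


@dataclass
class SimulatedStudy:
    """In-memory bundle of one simulated study."""

    config: SimulationConfig
    pedigree: Pedigree
    dataset: GenotypeDataset
    truth: GroundTruth
    phenotypes: PhenotypeTable
    grm: GRM


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Founders plus ``pedigree_depth`` generations of ``n_animals`` each.

    Each generation draws sires from a small pool (``n_sires``), producing
    widespread paternal half-sib structure; with probability
    ``close_mating_rate`` a dam is mated to her own sire, creating strongly
    inbred offspring. The final generation (the study animals, ids
    ``BULL0001``...) therefore shows a broad range of inbreeding
    coefficients.
    """
    rng = _stage_rng(config, 1)
    n = config.n_animals
    records: list[tuple[str, str | None, str | None]] = []
    prev = [f"F{i:05d}" for i in range(n)]
    records.extend((a, None, None) for a in prev)
    parents: dict[str, tuple[str | None, str | None]] = {a: (None, None) for a in prev}
    for gen in range(1, config.pedigree_depth + 1):
        last = gen == config.pedigree_depth
        ids = [
            f"BULL{i + 1:05d}" if last else f"G{gen}_{i:05d}" for i in range(n)
        ]
        n_sires = min(config.n_sires, len(prev))
        sire_pool = [str(x) for x in rng.choice(prev, size=n_sires, replace=False)]
        dams = [a for a in prev if a not in set(sire_pool)] or list(prev)
        for child in ids:
            dam = dams[int(rng.integers(len(dams)))]
            if (
                rng.random() < config.close_mating_rate
                and parents[dam][0] is not None
            ):
                sire = parents[dam][0]
            else:
                sire = sire_pool[int(rng.integers(len(sire_pool)))]
            records.append((child, sire, dam))
            parents[child] = (sire, dam)
        prev = ids
    return Pedigree(records)


def study_animals(pedigree: Pedigree, n_animals: int) -> list[str]:
    """The genotyped/phenotyped cohort: the final ``n_animals`` pedigree
    records, i.e. the last simulated generation."""
    animals = pedigree.animals
    if len(animals) < n_animals:
        raise PipelineError("pedigree has fewer animals than the study cohort")
    return animals[-n_animals:]


# ---------------------------------------------------------------------------
# genotypes with planted tracts
# ---------------------------------------------------------------------------


def _simulate_map(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    ids, chroms, positions = [], [], []
    for chrom in range(1, config.n_chromosomes + 1):
        m = config.markers_per_chromosome
        spacings = rng.exponential(config.mean_spacing_kb * 1000.0, m).astype(
            np.int64
        ) + 1
        if config.n_large_gaps_per_chrom and m > 2:
            at = rng.choice(
                np.arange(1, m), size=min(config.n_large_gaps_per_chrom, m - 1),
                replace=False,
            )
            lo, hi = config.large_gap_kb_range
            spacings[at] = (rng.uniform(lo, hi, size=len(at)) * 1000.0).astype(
                np.int64
            )
        pos = np.cumsum(spacings)
        ids.extend(f"snp{chrom}_{j + 1}" for j in range(m))
        chroms.extend([chrom] * m)
        positions.append(pos)
    return MarkerMap(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=np.int64),
        np.concatenate(positions),
    )


def _merged_length_bp(intervals: list[tuple[int, int, int]]) -> int:
    """Total bp covered by (chrom, start, end) intervals, overlaps merged."""
    total = 0
    by_chrom: dict[int, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e + 1:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s + 1
    return total


def simulate_genotypes(
    config: SimulationConfig, pedigree: Pedigree
) -> tuple[GenotypeDataset, GroundTruth]:
    """HWE background genotypes with planted autozygous tracts.

    Background codes are drawn marker-wise as Binomial(2, p_j) with
    p_j ~ U(allele_freq_range). Each study animal receives a Poisson number
    of tracts per chromosome at rate ``roh_rate_per_chrom * (1 +
    inbreeding_roh_slope * F_ped)``, each with a gamma-distributed length,
    planted by forcing homozygous codes (allele sampled by frequency);
    heterozygous calls are re-introduced inside tracts at
    ``genotyping_error_rate`` and missing calls everywhere at
    ``missing_rate``. Risk-region carriers are drawn explicitly and receive
    a tract covering the whole region. Marker columns are canonicalized so
    the first non-missing genotype is never homozygous-alternate, making
    the dataset stable under a PED round trip.
    """
    rng = _stage_rng(config, 2)
    markers = _simulate_map(config, rng)
    animals = study_animals(pedigree, config.n_animals)
    f_ped = pedigree_inbreeding(pedigree)
    n, m = len(animals), markers.n_markers

    p = rng.uniform(*config.allele_freq_range, size=m)
    genotypes = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)

    chrom_spans: dict[int, tuple[int, int]] = {}
    for chrom in markers.chromosome_list:
        sl = markers.chrom_slice(chrom)
        chrom_spans[chrom] = (
            int(markers.positions_bp[sl.start]),
            int(markers.positions_bp[sl.stop - 1]),
        )

    tracts: dict[str, list[tuple[int, int, int, bool]]] = {a: [] for a in animals}

    def plant(row: int, chrom: int, start: int, end: int) -> None:
        sl = markers.chrom_slice(chrom)
        lo = sl.start + int(
            np.searchsorted(markers.positions_bp[sl], start, side="left")
        )
        hi = sl.start + int(
            np.searchsorted(markers.positions_bp[sl], end, side="right")
        )
        if hi <= lo:
            return
        k = hi - lo
        codes = (rng.random(k) < p[lo:hi]).astype(np.int8) * 2
        err = rng.random(k) < config.genotyping_error_rate
        codes[err] = 1
        genotypes[row, lo:hi] = codes

    # random autozygous tracts, rate scaled by pedigree inbreeding
    for row, animal in enumerate(animals):
        rate = config.roh_rate_per_chrom * (
            1.0 + config.inbreeding_roh_slope * f_ped.get(animal, 0.0)
        )
        for chrom in markers.chromosome_list:
            span_lo, span_hi = chrom_spans[chrom]
            for _ in range(int(rng.poisson(rate))):
                length = int(
                    rng.gamma(config.roh_length_shape, config.roh_length_scale_kb)
                    * 1000.0
                )
                length = max(length, 1)
                start = int(rng.integers(span_lo, span_hi + 1))
                end = start + length - 1
                truncated = end > span_hi
                end = min(end, span_hi)
                tracts[animal].append((chrom, start, end, truncated))
                plant(row, chrom, start, end)

    # designated risk regions: explicit carriers, tract covers the region
    risk_truth: list[dict] = []
    for region in config.risk_regions:
        span_lo, span_hi = chrom_spans.get(region.chromosome, (None, None))
        if span_lo is None:
            raise PipelineError(
                f"risk region on chromosome {region.chromosome} outside the map"
            )
        carrier_mask = rng.random(n) < region.carrier_freq
        carriers = [animals[i] for i in np.flatnonzero(carrier_mask)]
        for i in np.flatnonzero(carrier_mask):
            pad_l = int(rng.exponential(1500.0) * 1000.0) + 300_000
            pad_r = int(rng.exponential(1500.0) * 1000.0) + 300_000
            start = max(span_lo, region.start_bp - pad_l)
            end = min(span_hi, region.end_bp + pad_r)
            tracts[animals[i]].append((region.chromosome, start, end, False))
            plant(int(i), region.chromosome, start, end)
        risk_truth.append(
            {
                "chromosome": region.chromosome,
                "start_bp": region.start_bp,
                "end_bp": region.end_bp,
                "effect": region.effect,
                "carrier_freq": region.carrier_freq,
                "carriers": carriers,
            }
        )

    if config.missing_rate > 0:
        genotypes[rng.random((n, m)) < config.missing_rate] = MISSING

    # canonicalize columns for PED round-trip stability
    observed = genotypes != MISSING
    has_obs = observed.any(axis=0)
    first_obs = np.argmax(observed, axis=0)
    first_code = genotypes[first_obs, np.arange(m)]
    flip = has_obs & (first_code == 2)
    col = genotypes[:, flip]
    col[col == 0] = 3
    col[col == 2] = 0
    col[col == 3] = 2
    genotypes[:, flip] = col

    true_total_mb = {
        a: _merged_length_bp([(c, s, e) for c, s, e, _ in ts]) / 1e6
        if ts
        else 0.0
        for a, ts in tracts.items()
    }
    truth = GroundTruth(
        tracts=tracts,
        true_total_mb=true_total_mb,
        beta_length=config.beta_length,
        risk_regions=risk_truth,
        sigma_g2=config.sigma_g2,
        sigma_e2=config.sigma_e**2,
        f_ped={a: f_ped.get(a, 0.0) for a in animals},
    )
    return GenotypeDataset(animals, markers, genotypes), truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    dataset: GenotypeDataset,
    truth: GroundTruth,
    grm: GRM,
    config: SimulationConfig,
) -> PhenotypeTable:
    """SCR records with inbreeding depression and a polygenic term.

    SCR_i = mu + beta_length * trueTotalMb_i + sum_r effect_r * carrier_ri
    + u_i + e_i with u ~ N(0, G sigma_g^2) drawn through the Cholesky factor
    of the ridge-regularized GRM and e ~ N(0, sigma_e^2). Breeding counts
    are uniform on ``n_breedings_range`` and carry no signal.
    """
    rng = _stage_rng(config, 3)
    animals = dataset.animal_ids
    n = len(animals)
    total_mb = np.array([truth.true_total_mb.get(a, 0.0) for a in animals])
    scr = config.mu + config.beta_length * total_mb
    for region in truth.risk_regions:
        carriers = set(region["carriers"])
        scr += region["effect"] * np.array(
            [1.0 if a in carriers else 0.0 for a in animals]
        )
    if config.sigma_g2 > 0:
        idx = {a: i for i, a in enumerate(grm.animal_ids)}
        rows = np.array([idx[a] for a in animals])
        g = grm.matrix[np.ix_(rows, rows)] + GRM_RIDGE * np.eye(n)
        scr += np.sqrt(config.sigma_g2) * (
            np.linalg.cholesky(g) @ rng.standard_normal(n)
        )
    scr += config.sigma_e * rng.standard_normal(n)
    lo, hi = config.n_breedings_range
    n_breedings = rng.integers(lo, hi + 1, size=n)
    return PhenotypeTable(list(animals), scr, n_breedings)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run all simulation stages in memory and return the bundle."""
    config = config or SimulationConfig()
    pedigree = simulate_pedigree(config)
    dataset, truth = simulate_genotypes(config, pedigree)
    grm = compute_grm(dataset)
    phenotypes = simulate_phenotypes(dataset, truth, grm, config)
    return SimulatedStudy(config, pedigree, dataset, truth, phenotypes, grm)


def generate_study(
    config: SimulationConfig | None = None,
    out_dir: str | os.PathLike = "study",
    overwrite: bool = False,
) -> SimulatedStudy:
    """Simulate a study and write the full bundle to ``out_dir``.

    Writes ``study.ped``/``study.map``, ``phenotypes.tsv``, ``pedigree.tsv``,
    ``genes.bed`` (decoy genes, three inside each risk region), ``truth.json``
    and ``manifest.json``. Refuses to write into a non-empty directory unless
    ``overwrite`` is set.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise PipelineError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    write_ped_map(study.dataset, out / "study.ped", out / "study.map")
    write_phenotypes(study.phenotypes, out / "phenotypes.tsv")
    write_pedigree(study.pedigree, out / "pedigree.tsv")
    _write_decoy_genes(study, out / "genes.bed")
    study.truth.to_json(out / "truth.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"format": "rohmap-study/1", "config": config.to_dict()}, fh)
    return study


def _write_decoy_genes(study: SimulatedStudy, path: Path) -> None:
    """Decoy gene BED: three genes inside each risk region plus random ones."""
    rng = _stage_rng(study.config, 4)
    markers = study.dataset.markers
    lines = []
    for k, region in enumerate(study.truth.risk_regions, start=1):
        span = region["end_bp"] - region["start_bp"] + 1
        for j in range(3):
            g_start = region["start_bp"] + (j * span) // 3
            g_end = min(g_start + span // 4, region["end_bp"])
            # BED is 0-based half-open
            lines.append(
                (region["chromosome"], g_start - 1, g_end, f"RISK{k}_GENE{j + 1}")
            )
    for chrom in markers.chromosome_list:
        sl = markers.chrom_slice(chrom)
        lo = int(markers.positions_bp[sl.start])
        hi = int(markers.positions_bp[sl.stop - 1])
        for j in range(10):
            g_start = int(rng.integers(lo, max(lo + 1, hi - 100_000)))
            g_end = g_start + int(rng.integers(5_000, 100_000))
            lines.append((chrom, g_start - 1, g_end, f"DECOY{chrom}_{j + 1}"))
    lines.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
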