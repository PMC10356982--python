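"""Overlap regions across animals and ROH enrichment in fertility extremes.

Overlap regions are built as a constant-carrier-set partition: on each
chromosome the line is cut at every segment start/end breakpoint, each
elementary interval carries the exact set of animals whose ROH fully cover
it, and adjacent intervals with identical carrier sets are merged. This
differs from PLINK's ``--homozyg-group`` pooling — the partition is
deterministic and each region's carrier set is exact, at the price of
producing differently delimited (typically more, shorter) regions.

Each region is then tested for over-representation of its carriers among
low-fertility animals with a one-tailed Fisher's exact test on the 2x2
table (low/high x carrier/non-carrier).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .types import (
    EnrichmentResult,
    MarkerMap,
    OverlapRegion,
    PhenotypeTable,
    PipelineError,
    ROHResult,
)

__all__ = [
    "split_extremes",
    "overlap_regions",
    "fisher_one_tailed",
    "test_enrichment",
    "significant_regions",
    "read_gene_intervals",
    "annotate_regions",
    "group_summary",
]


def split_extremes(
    phenotypes: PhenotypeTable, n: int = 100
) -> tuple[list[str], list[str]]:
    """Bottom-n (low-fertility) and top-n (high-fertility) animals by SCR.

    Boundary ties are broken in favor of the record with more breedings,
    then by lexicographic animal id. The groups are disjoint (low is
    assigned first).
    """
    if len(phenotypes) < 2 * n:
        raise PipelineError(
            f"need at least {2 * n} phenotyped animals, have {len(phenotypes)}"
        )
    records = list(
        zip(phenotypes.animal_ids, phenotypes.scr, phenotypes.n_breedings)
    )
    low_order = sorted(records, key=lambda r: (r[1], -r[2], r[0]))
    low = [r[0] for r in low_order[:n]]
    taken = set(low)
    high_order = sorted(
        (r for r in records if r[0] not in taken),
        key=lambda r: (-r[1], -r[2], r[0]),
    )
    high = [r[0] for r in high_order[:n]]
    return low, high


def overlap_regions(
    result: ROHResult, markers: MarkerMap | None = None, pool_min: int = 2
) -> list[OverlapRegion]:
    """Constant-carrier-set partition of the genome into overlap regions.

    Only regions carried (fully covered) by at least ``pool_min`` animals
    are kept. ``n_snp`` counts map markers with position inside the region.
    """
    markers = markers if markers is not None else result.markers
    if markers is None:
        raise PipelineError("overlap_regions needs a marker map")
    regions: list[OverlapRegion] = []
    by_chrom: dict[int, list] = {}
    for seg in result.segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom in sorted(by_chrom):
        segs = by_chrom[chrom]
        # events on the half-open integer line: +animal at start, -animal at end+1
        events: dict[int, list[tuple[int, str]]] = {}
        for s in segs:
            events.setdefault(s.start_bp, []).append((1, s.animal_id))
            events.setdefault(s.end_bp + 1, []).append((-1, s.animal_id))
        breakpoints = sorted(events)
        sl = markers.chrom_slice(chrom)
        positions = markers.positions_bp[sl]
        active: set[str] = set()
        pending: tuple[int, int, frozenset[str]] | None = None  # start,end,carriers
        for k, bp in enumerate(breakpoints):
            # removals first: an animal whose segment ends at bp-1 and whose
            # next segment starts at bp stays active across the breakpoint
            for delta, animal in sorted(events[bp], key=lambda e: e[0]):
                if delta > 0:
                    active.add(animal)
                else:
                    active.discard(animal)
            if k + 1 >= len(breakpoints):
                break
            start, end = bp, breakpoints[k + 1] - 1
            carriers = frozenset(active) if len(active) >= pool_min else None
            if pending is not None:
                if carriers is not None and pending[2] == carriers and pending[1] + 1 == start:
                    pending = (pending[0], end, carriers)
                    continue
                regions.append(_make_region(chrom, pending, positions))
                pending = None
            if carriers is not None:
                pending = (start, end, carriers)
        if pending is not None:
            regions.append(_make_region(chrom, pending, positions))
    return regions


def _make_region(
    chrom: int, pending: tuple[int, int, frozenset[str]], positions: np.ndarray
) -> OverlapRegion:
    start, end, carriers = pending
    lo = int(np.searchsorted(positions, start, side="left"))
    hi = int(np.searchsorted(positions, end, side="right"))
    return OverlapRegion(chrom, start, end, hi - lo, carriers)


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher exact p-value for over-representation in the top row.

    Computes the hypergeometric upper tail P(X >= a) with all margins fixed,
    i.e. the probability of observing at least ``a`` carriers among the
    low-fertility row. Evaluated in log space via the hypergeometric
    survival function.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise PipelineError("contingency counts must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        raise PipelineError("contingency table is empty")
    # X ~ Hypergeom(N=n_total, K=a+c carriers, n=a+b draws in the low row)
    return float(min(1.0, sps.hypergeom.sf(a - 1, n_total, a + c, a + b)))


def test_enrichment(
    regions: list[OverlapRegion],
    low: list[str],
    high: list[str],
) -> list[EnrichmentResult]:
    """Fisher enrichment of every overlap region in the low-fertility group.

    Results are sorted by ascending p-value (ties by genomic position).
    """
    low_set, high_set = set(low), set(high)
    if low_set & high_set:
        raise PipelineError("extreme groups must be disjoint")
    results = []
    for region in regions:
        a = len(region.carriers & low_set)
        c = len(region.carriers & high_set)
        b = len(low_set) - a
        d = len(high_set) - c
        results.append(
            EnrichmentResult(region, a, b, c, d, fisher_one_tailed(a, b, c, d))
        )
    results.sort(
        key=lambda r: (r.p_value, r.region.chromosome, r.region.start_bp)
    )
    return results


# the name starts with "test_" for API reasons; it is not a pytest test
test_enrichment.__test__ = False  # type: ignore[attr-defined]


def significant_regions(
    results: list[EnrichmentResult], alpha: float = 0.001
) -> list[EnrichmentResult]:
    """Subset with p <= alpha (inclusive), input order preserved."""
    return [r for r in results if r.p_value <= alpha]


# ---------------------------------------------------------------------------
# local gene annotation
# ---------------------------------------------------------------------------


def read_gene_intervals(path: str | os.PathLike) -> list[tuple[int, int, int, str]]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive) into the pipeline's 1-based inclusive convention.

    Returns (chromosome, start_bp, end_bp, name) tuples. Gene names come
    from BED column 4, or from the ``Name``/``gene_name``/``ID`` attribute
    of GFF3 ``gene`` features (all features are used when none are typed
    ``gene``).
    """
    suffix = Path(path).suffix.lower()
    genes: list[tuple[int, int, int, str]] = []
    if suffix == ".bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise PipelineError(
                        f"{path}:{lineno}: BED needs >= 4 columns (name required)"
                    )
                chrom = int(fields[0].removeprefix("chr"))
                genes.append((chrom, int(fields[1]) + 1, int(fields[2]), fields[3]))
    elif suffix in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise PipelineError(f"{path}: malformed GFF3 line")
                rows.append(fields)
        typed = [r for r in rows if r[2] == "gene"] or rows
        for r in typed:
            attrs = dict(
                kv.split("=", 1) for kv in r[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID")
            chrom = int(r[0].removeprefix("chr"))
            genes.append((chrom, int(r[3]), int(r[4]), name or "unnamed"))
    else:
        raise PipelineError(
            f"unknown annotation format {suffix!r} (expected .bed/.gff/.gff3)"
        )
    return genes


def annotate_regions(
    regions: list[OverlapRegion], gene_path: str | os.PathLike
) -> list[list[str]]:
    """Names of genes overlapping each region by at least 1 bp."""
    genes = read_gene_intervals(gene_path)
    out: list[list[str]] = []
    for region in regions:
        hits = [
            name
            for chrom, start, end, name in genes
            if chrom == region.chromosome
            and start <= region.end_bp
            and end >= region.start_bp
        ]
        out.append(sorted(set(hits)))
    return out


def group_summary(
    phenotypes: PhenotypeTable,
    stats_by_animal: dict[str, float],
    low: list[str],
    high: list[str],
) -> dict[str, float]:
    """Mean SCR and mean of a per-animal ROH statistic in each extreme group."""
    scr = phenotypes.by_animal
    return {
        "low_mean_scr": float(np.mean([scr[a][0] for a in low])),
        "high_mean_scr": float(np.mean([scr[a][0] for a in high])),
        "low_mean_stat": float(np.mean([stats_by_animal[a] for a in low])),
        "high_mean_stat": float(np.mean([stats_by_animal[a] for a in high])),
    }
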