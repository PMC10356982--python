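"""Sliding-window detection of runs of homozygosity (ROH).

The caller mirrors the PLINK ``--homozyg`` scan: a window of ``window_snp``
markers slides along each chromosome of each animal; a window is flagged
homozygous when it contains at most ``window_het`` heterozygous and at most
``window_missing`` missing calls. Each SNP then receives the proportion of
flagged windows among the complete windows overlapping it; SNPs at or above
``hit_threshold`` are eligible for a run. Maximal eligible stretches are
split wherever two adjacent markers are more than ``max_gap_kb`` apart,
trimmed to homozygous non-missing end markers, and finally filtered on
marker count, physical length and marker density.

Only complete windows are formed, so markers near chromosome ends are
covered by fewer windows; a chromosome shorter than one window yields no
calls. There is no cap on heterozygotes inside a final segment beyond the
per-window cap, and no MAF or LD pruning is applied anywhere.

:func:`detect_roh_oracle` re-derives the same contract by naive exhaustive
enumeration with no incremental bookkeeping; it exists as an independent
reference for differential testing and is only meant for small instances.
"""

from __future__ import annotations

import numpy as np

from .types import (
    MISSING,
    GenotypeDataset,
    ROHParameters,
    ROHResult,
    ROHSegment,
)

__all__ = [
    "window_flags",
    "snp_hit_proportions",
    "assemble_runs",
    "filter_runs",
    "detect_roh",
    "detect_roh_oracle",
]


def _moving_sum(x: np.ndarray, width: int) -> np.ndarray:
    c = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return c[width:] - c[:-width]


def window_flags(codes: np.ndarray, params: ROHParameters) -> np.ndarray:
    """Homozygosity flag for every complete window start on one chromosome.

    Returns a boolean array of length ``n - window_snp + 1`` (empty when the
    chromosome has fewer markers than one window).
    """
    codes = np.asarray(codes)
    w = params.window_snp
    if len(codes) < w:
        return np.zeros(0, dtype=bool)
    het = _moving_sum(codes == 1, w)
    miss = _moving_sum(codes == MISSING, w)
    return (het <= params.window_het) & (miss <= params.window_missing)


def snp_hit_proportions(
    flags: np.ndarray, n_markers: int, params: ROHParameters
) -> np.ndarray:
    """Per-marker proportion of flagged windows among windows covering it.

    Markers covered by zero complete windows get proportion 0.
    """
    w = params.window_snp
    props = np.zeros(n_markers, dtype=float)
    n_windows = len(flags)
    if n_windows == 0:
        return props
    idx = np.arange(n_markers)
    lo = np.maximum(0, idx - w + 1)  # first window start covering marker
    hi = np.minimum(idx, n_windows - 1)  # last window start covering marker
    covered = hi >= lo
    cum = np.concatenate(([0], np.cumsum(flags, dtype=np.int64)))
    hits = cum[hi[covered] + 1] - cum[lo[covered]]
    props[covered] = hits / (hi[covered] - lo[covered] + 1)
    return props


def assemble_runs(
    codes: np.ndarray,
    positions: np.ndarray,
    proportions: np.ndarray,
    params: ROHParameters,
) -> list[tuple[int, int]]:
    """Candidate runs as (first, last) marker index pairs for one
    animal x chromosome.

    Markers with hit proportion >= ``hit_threshold`` form maximal stretches;
    stretches are split at adjacent-marker gaps above ``max_gap_kb`` and
    trimmed so both ends sit on homozygous non-missing markers. Pieces left
    empty by trimming are dropped.
    """
    codes = np.asarray(codes)
    positions = np.asarray(positions, dtype=np.int64)
    in_run = np.asarray(proportions) >= params.hit_threshold
    if not in_run.any():
        return []
    max_gap_bp = params.max_gap_kb * 1000.0
    hom = (codes == 0) | (codes == 2)

    runs: list[tuple[int, int]] = []
    bounded = np.diff(np.concatenate(([0], in_run.astype(np.int8), [0])))
    starts = np.flatnonzero(bounded == 1)
    ends = np.flatnonzero(bounded == -1) - 1
    for i0, i1 in zip(starts, ends):
        piece_start = i0
        cuts = np.flatnonzero(
            np.diff(positions[i0 : i1 + 1]).astype(float) > max_gap_bp
        )
        boundaries = [i0 + c for c in cuts] + [i1]
        for last in boundaries:
            lo, hi = piece_start, last
            while lo <= hi and not hom[lo]:
                lo += 1
            while hi >= lo and not hom[hi]:
                hi -= 1
            if lo <= hi:
                runs.append((int(lo), int(hi)))
            piece_start = last + 1
    return runs


def filter_runs(
    runs: list[tuple[int, int]],
    codes: np.ndarray,
    positions: np.ndarray,
    params: ROHParameters,
    animal_id: str,
    chromosome: int,
) -> list[ROHSegment]:
    """Apply the final segment filters and materialize :class:`ROHSegment`s.

    A run is kept when it spans at least ``min_snp`` markers, at least
    ``min_length_kb`` kb, and its density (kb per SNP) does not exceed
    ``max_density_kb_per_snp``.
    """
    codes = np.asarray(codes)
    positions = np.asarray(positions, dtype=np.int64)
    segments: list[ROHSegment] = []
    for lo, hi in runs:
        n_snp = hi - lo + 1
        length_kb = (positions[hi] - positions[lo] + 1) / 1000.0
        if n_snp < params.min_snp:
            continue
        if length_kb < params.min_length_kb:
            continue
        if length_kb / n_snp > params.max_density_kb_per_snp:
            continue
        inside = codes[lo : hi + 1]
        segments.append(
            ROHSegment(
                animal_id=animal_id,
                chromosome=chromosome,
                start_bp=int(positions[lo]),
                end_bp=int(positions[hi]),
                n_snp=int(n_snp),
                n_het=int(np.count_nonzero(inside == 1)),
                n_missing=int(np.count_nonzero(inside == MISSING)),
            )
        )
    return segments


def detect_roh(
    dataset: GenotypeDataset, params: ROHParameters | None = None
) -> ROHResult:
    """Call ROH for every animal on every chromosome of ``dataset``.

    Segments are returned in deterministic (animal, chromosome, start) order;
    every animal appears in the result's index even with zero segments.
    """
    params = params or ROHParameters()
    segments: list[ROHSegment] = []
    for i, animal in enumerate(dataset.animal_ids):
        row = dataset.genotypes[i]
        for chrom in dataset.markers.chromosome_list:
            sl = dataset.markers.chrom_slice(chrom)
            codes = row[sl]
            positions = dataset.markers.positions_bp[sl]
            flags = window_flags(codes, params)
            props = snp_hit_proportions(flags, len(codes), params)
            runs = assemble_runs(codes, positions, props, params)
            segments.extend(
                filter_runs(runs, codes, positions, params, animal, chrom)
            )
    return ROHResult(params, segments, list(dataset.animal_ids), dataset.markers)


# ---------------------------------------------------------------------------
# naive reference implementation
# ---------------------------------------------------------------------------


def detect_roh_oracle(
    dataset: GenotypeDataset, params: ROHParameters | None = None
) -> ROHResult:
    """Same contract as :func:`detect_roh`, by brute-force enumeration.

    Every window, per-marker proportion and candidate stretch is recomputed
    from scratch with explicit loops; intended for instances of up to a few
    thousand markers.
    """
    params = params or ROHParameters()
    w = params.window_snp
    segments: list[ROHSegment] = []
    for i, animal in enumerate(dataset.animal_ids):
        for chrom in dataset.markers.chromosome_list:
            sl = dataset.markers.chrom_slice(chrom)
            codes = [int(c) for c in dataset.genotypes[i][sl]]
            positions = [int(p) for p in dataset.markers.positions_bp[sl]]
            n = len(codes)
            flagged = []
            for start in range(n - w + 1):
                window = codes[start : start + w]
                n_het = sum(1 for c in window if c == 1)
                n_miss = sum(1 for c in window if c == MISSING)
                flagged.append(
                    n_het <= params.window_het
                    and n_miss <= params.window_missing
                )
            in_run = []
            for j in range(n):
                covering = [
                    s for s in range(len(flagged)) if s <= j <= s + w - 1
                ]
                if covering:
                    prop = sum(1 for s in covering if flagged[s]) / len(covering)
                else:
                    prop = 0.0
                in_run.append(prop >= params.hit_threshold)
            # maximal stretches
            stretches = []
            j = 0
            while j < n:
                if in_run[j]:
                    k = j
                    while k + 1 < n and in_run[k + 1]:
                        k += 1
                    stretches.append((j, k))
                    j = k + 1
                else:
                    j += 1
            # split at large gaps, trim to homozygous non-missing ends
            pieces = []
            for lo, hi in stretches:
                piece = [lo]
                for j in range(lo, hi):
                    if positions[j + 1] - positions[j] > params.max_gap_kb * 1000.0:
                        piece.append(j)
                        pieces.append((piece[0], piece[1]))
                        piece = [j + 1]
                pieces.append((piece[0], hi))
            for lo, hi in pieces:
                while lo <= hi and codes[lo] not in (0, 2):
                    lo += 1
                while hi >= lo and codes[hi] not in (0, 2):
                    hi -= 1
                if lo > hi:
                    continue
                n_snp = hi - lo + 1
                length_kb = (positions[hi] - positions[lo] + 1) / 1000.0
                if (
                    n_snp >= params.min_snp
                    and length_kb >= params.min_length_kb
                    and length_kb / n_snp <= params.max_density_kb_per_snp
                ):
                    segments.append(
                        ROHSegment(
                            animal_id=animal,
                            chromosome=chrom,
                            start_bp=positions[lo],
                            end_bp=positions[hi],
                            n_snp=n_snp,
                            n_het=sum(
                                1 for c in codes[lo : hi + 1] if c == 1
                            ),
                            n_missing=sum(
                                1 for c in codes[lo : hi + 1] if c == MISSING
                            ),
                        )
                    )
    return ROHResult(params, segments, list(dataset.animal_ids), dataset.markers)
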