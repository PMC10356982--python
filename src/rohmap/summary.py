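"""Characterization of homozygosity and its association with fertility.

Covers per-animal and per-chromosome ROH summaries, Wright's pedigree
inbreeding coefficient via the tabular relationship method, the Pearson
correlation between genomic (F_ROH) and pedigree (F_PED) inbreeding, and
the simple linear regression of sire conception rate on ROH burden.

F_ROH is total ROH bp divided by the SNP-covered autosomal span (first to
last marker per chromosome) unless assembly chromosome lengths are supplied
on the marker map — ROH cannot be observed outside marker coverage, so the
covered span is the defensible default denominator.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .types import (
    AnimalROHStats,
    MarkerMap,
    Pedigree,
    PhenotypeTable,
    PipelineError,
    RegressionFit,
    ROHResult,
)

__all__ = [
    "summarize_animals",
    "chromosome_homozygosity",
    "pedigree_inbreeding",
    "correlate_roh_pedigree",
    "regress_scr_on_roh",
]


def _froh_denominator(markers: MarkerMap) -> float:
    if markers.chromosome_lengths:
        return float(
            sum(markers.chrom_length(c) for c in markers.chromosome_list)
        )
    return float(sum(markers.covered_span(c) for c in markers.chromosome_list))


def summarize_animals(result: ROHResult) -> list[AnimalROHStats]:
    """Per-animal ROH statistics; animals without segments get all zeros.

    Requires ``result.markers`` for the F_ROH denominator.
    """
    if result.markers is None:
        raise PipelineError("summarize_animals needs the marker map on the result")
    denom = _froh_denominator(result.markers)
    out: list[AnimalROHStats] = []
    for animal in result.animal_ids:
        segs = result.per_animal.get(animal, [])
        if not segs:
            out.append(AnimalROHStats(animal, 0, 0.0, 0.0, 0.0, 0.0))
            continue
        lengths_kb = np.array([s.length_kb for s in segs])
        total_bp = float(sum(s.length_bp for s in segs))
        out.append(
            AnimalROHStats(
                animal_id=animal,
                n_segments=len(segs),
                total_length_kb=float(lengths_kb.sum()),
                mean_length_kb=float(lengths_kb.mean()),
                max_length_kb=float(lengths_kb.max()),
                f_roh=total_bp / denom,
            )
        )
    return out


def chromosome_homozygosity(result: ROHResult) -> dict[int, float]:
    """Percent of each chromosome covered by ROH, averaged over animals.

    For chromosome c: 100 x (sum over animals of ROH bp on c) /
    (n_animals x chromosome length).
    """
    if result.markers is None:
        raise PipelineError(
            "chromosome_homozygosity needs the marker map on the result"
        )
    n_animals = len(result.animal_ids)
    totals: dict[int, float] = {c: 0.0 for c in result.markers.chromosome_list}
    for seg in result.segments:
        totals[seg.chromosome] = totals.get(seg.chromosome, 0.0) + seg.length_bp
    return {
        c: 100.0 * totals[c] / (n_animals * result.markers.chrom_length(c))
        if n_animals
        else 0.0
        for c in totals
    }


def pedigree_inbreeding(pedigree: Pedigree) -> dict[str, float]:
    """Wright's inbreeding coefficient F for every animal in the pedigree.

    Uses the tabular additive-relationship method in topological order:
    a(i,j) = 0.5 (a(sire_i, j) + a(dam_i, j)) for j processed before i and
    a(i,i) = 1 + 0.5 a(sire_i, dam_i); a founder (or unknown-parent)
    contribution is zero, and F(i) = a(i,i) - 1.
    """
    order = pedigree.topological_order
    index = {a: k for k, a in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, animal in enumerate(order):
        sire, dam = pedigree.parents(animal)
        si = index[sire] if sire is not None else None
        di = index[dam] if dam is not None else None
        if i:
            row = np.zeros(i)
            if si is not None:
                row += 0.5 * a[si, :i]
            if di is not None:
                row += 0.5 * a[di, :i]
            a[i, :i] = row
            a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
    return {animal: float(a[index[animal], index[animal]] - 1.0) for animal in order}


def correlate_roh_pedigree(
    stats: list[AnimalROHStats],
    f_ped: dict[str, float],
    use: str = "f_roh",
) -> float:
    """Pearson correlation between genomic and pedigree inbreeding.

    ``use`` selects the genomic side: ``"f_roh"`` (proportion of the covered
    genome in ROH, the default) or ``"total_kb"`` (raw total ROH length).
    Computed over the animals present on both sides; needs at least 3 such
    animals and nonzero variance on each side.
    """
    if use not in ("f_roh", "total_kb"):
        raise PipelineError(f"unknown correlation variable {use!r}")
    pairs = [
        (s.f_roh if use == "f_roh" else s.total_length_kb, f_ped[s.animal_id])
        for s in stats
        if s.animal_id in f_ped
    ]
    if len(pairs) < 3:
        raise PipelineError("need >= 3 animals with both F_ROH and F_PED")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise PipelineError("genomic inbreeding is constant across animals")
    if np.ptp(y) == 0:
        raise PipelineError("pedigree inbreeding is constant across animals")
    return float(np.corrcoef(x, y)[0, 1])


def regress_scr_on_roh(
    phenotypes: PhenotypeTable,
    stats: list[AnimalROHStats],
    predictor: str = "total_length_mb",
) -> RegressionFit:
    """Ordinary least squares of SCR on a per-animal ROH predictor.

    ``predictor`` is ``"total_length_mb"`` (total ROH length in Mb) or
    ``"n_segments"``. The regression is unweighted; breeding counts are not
    used. Returns slope, intercept, SE(slope), t = beta/se and the two-sided
    p-value on n - 2 degrees of freedom.
    """
    if predictor not in ("total_length_mb", "n_segments"):
        raise PipelineError(f"unknown predictor {predictor!r}")
    by_animal = {s.animal_id: s for s in stats}
    xs, ys = [], []
    for animal, scr, _nb in zip(
        phenotypes.animal_ids, phenotypes.scr, phenotypes.n_breedings
    ):
        s = by_animal.get(animal)
        if s is None:
            continue
        xs.append(
            s.total_length_mb if predictor == "total_length_mb" else s.n_segments
        )
        ys.append(scr)
    n = len(xs)
    if n < 3:
        raise PipelineError("need >= 3 animals with phenotype and ROH stats")
    x = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise PipelineError("predictor has zero variance")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - beta * x.mean())
    resid = y - intercept - beta * x
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se_beta = float(np.sqrt(sigma2 / sxx))
    if se_beta == 0.0:
        t_value = 0.0 if beta == 0.0 else np.inf * np.sign(beta)
        p_value = 1.0 if beta == 0.0 else 0.0
    else:
        t_value = beta / se_beta
        p_value = float(2.0 * sps.t.sf(abs(t_value), df))
    return RegressionFit(beta, intercept, se_beta, float(t_value), p_value, n)
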