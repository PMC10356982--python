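"""Readers and writers for the pipeline's text formats.

Supported inputs are PLINK PED/MAP genotype text files (autosomes only,
biallelic), a simple TSV genotype-matrix dialect for fixtures, tab-separated
phenotype and pedigree tables, and a ``.hom``-style ROH segment table.

Genotype recoding is deterministic: at each marker the reference allele is
the first non-missing allele encountered in file order. A consequence is
that a dataset freshly read from a PED file always has code 0 or 1 as the
first non-missing genotype of every marker, and such datasets round-trip
exactly through :func:`write_ped_map` / :func:`read_ped_map`.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    FormatError,
    GenotypeDataset,
    MarkerMap,
    Pedigree,
    PhenotypeTable,
    ROHParameters,
    ROHResult,
    ROHSegment,
)

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_roh",
    "write_roh",
]


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------


def _read_map(map_path: str | os.PathLike) -> tuple[MarkerMap, np.ndarray]:
    """Parse a 4-column MAP file; returns the sorted map and the permutation
    taking file order to (chromosome, position) order."""
    ids: list[str] = []
    chroms: list[int] = []
    positions: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom_s, marker_id, _cm, bp_s = fields
            try:
                chrom = int(chrom_s)
                bp = int(bp_s)
            except ValueError as exc:
                raise FormatError(
                    f"{map_path}:{lineno}: non-numeric chromosome or position"
                ) from exc
            if not (1 <= chrom <= 29):
                raise FormatError(
                    f"{map_path}:{lineno}: chromosome {chrom} is not an autosome"
                )
            ids.append(marker_id)
            chroms.append(chrom)
            positions.append(bp)
    chrom_arr = np.array(chroms, dtype=np.int64)
    pos_arr = np.array(positions, dtype=np.int64)
    order = np.lexsort((pos_arr, chrom_arr))
    markers = MarkerMap(
        np.array(ids, dtype=object)[order], chrom_arr[order], pos_arr[order]
    )
    return markers, order


def read_ped_map(
    ped_path: str | os.PathLike, map_path: str | os.PathLike
) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    The PED file carries 6 leading columns (family, individual, sire, dam,
    sex, phenotype) followed by two allele tokens per marker; allele "0"
    marks a missing call. At each marker the first non-missing allele seen
    (in file order) becomes the reference; a third allele is an error.
    Markers are re-sorted by (chromosome, position), permuting genotype
    columns consistently.
    """
    markers, order = _read_map(map_path)
    n_markers = markers.n_markers
    inverse = np.empty(n_markers, dtype=np.intp)
    inverse[order] = np.arange(n_markers)  # file column -> sorted column

    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    ref = np.full(n_markers, "", dtype=object)  # per file-order column
    alt = np.full(n_markers, "", dtype=object)
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns,"
                    f" got {len(fields)}"
                )
            animal_ids.append(fields[1])
            alleles = np.array(fields[6:], dtype=object)
            a1 = alleles[0::2]
            a2 = alleles[1::2]
            miss = (a1 == "0") | (a2 == "0")
            # establish reference alleles from the first non-missing call
            need = (ref == "") & ~miss
            ref[need] = a1[need]
            codes = np.full(n_markers, MISSING, dtype=np.int8)
            obs = ~miss
            codes[obs] = (a1[obs] != ref[obs]).astype(np.int8) + (
                a2[obs] != ref[obs]
            ).astype(np.int8)
            # biallelic check: record and verify the alternate allele
            for side in (a1, a2):
                nonref = obs & (side != ref)
                newalt = nonref & (alt == "")
                alt[newalt] = side[newalt]
                bad = nonref & (side != alt)
                if bad.any():
                    j = int(np.flatnonzero(bad)[0])
                    raise FormatError(
                        f"{ped_path}:{lineno}: third allele {side[j]!r} at marker"
                        f" {markers.marker_ids[inverse[j]]!r}"
                    )
            rows.append(codes[order])
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8)
    )
    return GenotypeDataset(animal_ids, markers, genotypes)


def write_ped_map(
    dataset: GenotypeDataset,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write a dataset as a PED/MAP pair with alleles labeled A (ref) / B (alt)."""
    with open(map_path, "w") as fh:
        for mid, chrom, pos in zip(
            dataset.markers.marker_ids,
            dataset.markers.chromosomes,
            dataset.markers.positions_bp,
        ):
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\n")
    allele_pairs = np.array(["A A", "A B", "B B", "0 0"], dtype=object)
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(dataset.animal_ids):
            codes = dataset.genotypes[i]
            tokens = allele_pairs[np.where(codes == MISSING, 3, codes)]
            fh.write(f"FAM {animal} 0 0 0 -9 " + " ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# TSV genotype-matrix dialect (fixtures)
# ---------------------------------------------------------------------------


def write_genotype_tsv(
    dataset: GenotypeDataset,
    genotype_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write genotype codes as a TSV matrix (animals in rows, header = marker
    ids, missing = ``NA``) plus a 3-column marker map TSV."""
    dataset.markers.to_frame().to_csv(map_path, sep="\t", index=False)
    frame = pd.DataFrame(
        dataset.genotypes,
        index=pd.Index(dataset.animal_ids, name="animal_id"),
        columns=dataset.markers.marker_ids,
    ).replace(MISSING, pd.NA)
    frame.to_csv(genotype_path, sep="\t", na_rep="NA")


def read_genotype_tsv(
    genotype_path: str | os.PathLike, map_path: str | os.PathLike
) -> GenotypeDataset:
    """Read the TSV genotype-matrix dialect written by :func:`write_genotype_tsv`."""
    map_frame = pd.read_csv(map_path, sep="\t")
    markers = MarkerMap(
        map_frame["marker_id"].astype(str).to_numpy(dtype=object),
        map_frame["chromosome"].to_numpy(),
        map_frame["position_bp"].to_numpy(),
    )
    frame = pd.read_csv(genotype_path, sep="\t", index_col="animal_id")
    frame = frame[list(markers.marker_ids)]
    codes = frame.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeDataset([str(a) for a in frame.index], markers, codes)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read a tab-separated SCR table (animal_id, scr, n_breedings).

    Multiple records per animal are collapsed at read time to the most
    reliable one: the row with the most breedings, ties broken by the larger
    SCR, then by file order.
    """
    records: dict[str, tuple[float, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[0].lower() in ("animal_id", "animal", "id"):
                continue
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            animal, scr_s, nb_s = fields
            try:
                scr = float(scr_s)
                nb = int(nb_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparsable numeric field"
                ) from exc
            if animal in records:
                prev_scr, prev_nb = records[animal]
                if (nb, scr) > (prev_nb, prev_scr):
                    records[animal] = (scr, nb)
            else:
                records[animal] = (scr, nb)
    animals = list(records)
    return PhenotypeTable(
        animals,
        np.array([records[a][0] for a in animals]),
        np.array([records[a][1] for a in animals]),
    )


def write_phenotypes(table: PhenotypeTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a tab-separated pedigree (animal, sire, dam; "0"/empty = unknown)."""
    records: list[tuple[str, str | None, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[0].lower() in ("animal_id", "animal", "id"):
                continue
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            animal, sire, dam = (f.strip() for f in fields)
            records.append(
                (
                    animal,
                    None if sire in ("", "0") else sire,
                    None if dam in ("", "0") else dam,
                )
            )
    return Pedigree(records)  # acyclicity verified on construction


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tsire_id\tdam_id\n")
        for animal, sire, dam in pedigree.records:
            fh.write(f"{animal}\t{sire or 0}\t{dam or 0}\n")


# ---------------------------------------------------------------------------
# ROH table
# ---------------------------------------------------------------------------

_ROH_COLUMNS = [
    "animal_id",
    "chrom",
    "start_bp",
    "end_bp",
    "length_kb",
    "n_snp",
    "n_het",
    "n_missing",
]


def write_roh(result: ROHResult, path: str | os.PathLike) -> None:
    """Write a ``.hom``-style tab-separated segment table (one row per ROH)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ROH_COLUMNS) + "\n")
        for s in result.segments:
            fh.write(
                f"{s.animal_id}\t{s.chromosome}\t{s.start_bp}\t{s.end_bp}\t"
                f"{s.length_kb:.3f}\t{s.n_snp}\t{s.n_het}\t{s.n_missing}\n"
            )


def read_roh(
    path: str | os.PathLike,
    parameters: ROHParameters | None = None,
    animal_ids: list[str] | None = None,
    markers: MarkerMap | None = None,
) -> ROHResult:
    """Read a segment table written by :func:`write_roh`.

    The table does not embed the calling parameters or the study context;
    pass ``parameters``/``animal_ids``/``markers`` to restore them.
    """
    segments: list[ROHSegment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ROH_COLUMNS:
            raise FormatError(f"{path}: unexpected ROH table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_ROH_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            try:
                segments.append(
                    ROHSegment(
                        animal_id=fields[0],
                        chromosome=int(fields[1]),
                        start_bp=int(fields[2]),
                        end_bp=int(fields[3]),
                        n_snp=int(fields[5]),
                        n_het=int(fields[6]),
                        n_missing=int(fields[7]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable field") from exc
    if animal_ids is None:
        animal_ids = sorted({s.animal_id for s in segments})
    return ROHResult(
        parameters or ROHParameters(), segments, animal_ids, markers
    )
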