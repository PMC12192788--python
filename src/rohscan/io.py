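"""Reading and writing PLINK PED/MAP text, BED intervals, and CSV tables.

PED/MAP is the interchange format: MAP carries (chromosome, snp_id, cM,
position), PED carries six metadata columns (family/population, individual,
father, mother, sex, phenotype) followed by two allele columns per marker.
``0 0`` encodes a missing genotype.  The PED family-ID column is used as the
population (breed) label.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    AnnotationInterval,
    GenotypeDataset,
    SnpMap,
)

_VALID_ALLELES = set("ACGT012")


class PlinkParseError(ValueError):
    pass


def read_plink(ped_path: str, map_path: str) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    Markers are sorted canonically by (chromosome, position) and genotype
    columns permuted to match.  When only one allele is observed at a marker
    it becomes ``allele_a`` and ``HOM_B`` never occurs for that marker.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts
            map_rows.append((chrom, int(pos), snp_id))
    n_markers = len(map_rows)

    sample_rows = []
    allele_cols: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            expected = 6 + 2 * n_markers
            if len(parts) != expected:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {expected} fields "
                    f"(6 + 2x{n_markers}), got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            alleles = parts[6:]
            for a in alleles:
                if a not in _VALID_ALLELES:
                    raise PlinkParseError(
                        f"{ped_path}:{lineno}: invalid allele {a!r}"
                    )
            sample_rows.append((iid, fid))
            allele_cols.append(np.array(alleles, dtype="U1"))

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise PlinkParseError(f"{ped_path}: duplicate sample_id {dup!r}")

    n_samples = len(samples)
    geno = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele_a = np.array(["0"] * n_markers, dtype="U1")
    allele_b = np.array(["0"] * n_markers, dtype="U1")

    if n_samples:
        allele_mat = np.stack(allele_cols)  # (n_samples, 2*n_markers)
        a1 = allele_mat[:, 0::2]
        a2 = allele_mat[:, 1::2]
        for j in range(n_markers):
            seen: list[str] = []
            for arr in (a1[:, j], a2[:, j]):
                for a in arr:
                    if a != "0" and a not in seen:
                        seen.append(a)
            if len(seen) > 2:
                raise PlinkParseError(
                    f"marker {map_rows[j][2]!r} has >2 alleles: {seen}"
                )
            aa = seen[0] if seen else "0"
            ab = seen[1] if len(seen) > 1 else "0"
            allele_a[j], allele_b[j] = aa, ab
            x1, x2 = a1[:, j], a2[:, j]
            called = (x1 != "0") & (x2 != "0")
            geno[:, j] = np.where(
                ~called,
                MISSING,
                np.where(
                    x1 != x2,
                    HET,
                    np.where(x1 == aa, HOM_A, HOM_B),
                ),
            )

    map_df = pd.DataFrame(map_rows, columns=["chromosome", "position", "snp_id"])
    map_df["allele_a"] = allele_a
    map_df["allele_b"] = allele_b
    order = SnpMap.canonical_order(map_df)
    snp_map = SnpMap(map_df.iloc[order])
    return GenotypeDataset(map=snp_map, samples=samples, genotypes=geno[:, order])


def write_plink(ds: GenotypeDataset, ped_path: str, map_path: str) -> None:
    """Write a dataset as a PLINK text PED/MAP pair (inverse of read_plink)."""
    with open(map_path, "w") as fh:
        for _, row in ds.map.df.iterrows():
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position}\n")

    aa = ds.map.df["allele_a"].to_numpy()
    ab = ds.map.df["allele_b"].to_numpy()
    # Unobserved alleles are written as 'A'/'B' placeholders only if absent;
    # a marker with allele code '0' never has that homozygote in the matrix.
    with open(ped_path, "w") as fh:
        for i in range(ds.n_samples):
            sid = ds.samples["sample_id"].iloc[i]
            pop = ds.samples["population"].iloc[i]
            fields = [str(pop), str(sid), "0", "0", "0", "-9"]
            g = ds.genotypes[i]
            for j in range(ds.n_snps):
                code = g[j]
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == HOM_A:
                    fields += [aa[j], aa[j]]
                elif code == HOM_B:
                    fields += [ab[j], ab[j]]
                else:
                    fields += [aa[j], ab[j]]
            fh.write(" ".join(fields) + "\n")


def write_segments_bed(segments, path: str) -> None:
    """Write run/island segments as BED (0-based half-open).

    Accepts a DataFrame with columns (chromosome, start_bp, end_bp[,
    sample_id]) or an iterable of objects with those attributes.  Lines are
    sorted by (chromosome, start, sample) for deterministic output.
    """
    rows = []
    if isinstance(segments, pd.DataFrame):
        for _, r in segments.iterrows():
            rows.append((
                str(r["chromosome"]), int(r["start_bp"]), int(r["end_bp"]),
                str(r["sample_id"]) if "sample_id" in segments.columns else ".",
            ))
    else:
        for s in segments:
            rows.append((
                str(s.chromosome), int(s.start_bp), int(s.end_bp),
                str(getattr(s, "sample_id", ".")),
            ))
    from .data import chromosome_sort_key
    rows.sort(key=lambda r: (chromosome_sort_key(r[0]), r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_annotation_bed(path: str) -> list[AnnotationInterval]:
    """Read a BED3+ annotation file into 1-based inclusive intervals.

    Column 4 (if present) is the interval name, column 5 the category
    (e.g. QTL trait); BED's 0-based half-open [start, end) becomes the
    1-based inclusive [start+1, end].
    """
    out: list[AnnotationInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            start, end = start0 + 1, end0
            if start > end:
                raise ValueError(
                    f"{path}:{lineno}: start > end after coordinate conversion"
                )
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            category = parts[4] if len(parts) > 4 else ""
            out.append(AnnotationInterval(chrom, start, end, name, category))
    return out


def write_csv(df: pd.DataFrame, path: str) -> None:
    """Deterministic CSV output: fixed float format, no index."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
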