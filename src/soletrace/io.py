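"""Readers and writers for the interchange formats.

Genotypes travel either as biallelic VCF (GT field only) or as a 0/1/2
alternate-allele-count CSV (first column sample id, header row of locus ids,
missing encoded as an empty cell). Otolith outlines travel as a long-format
CSV (otolith_id, point_index, x, y). Sample metadata is a plain CSV with
controlled vocabularies enforced on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .contour import Contour
from .popgen import GenotypeMatrix

log = logging.getLogger("soletrace")

__all__ = [
    "read_genotypes",
    "write_vcf",
    "write_csv012",
    "read_contours",
    "write_contours",
    "read_metadata",
    "write_metadata",
]

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal biallelic VCF v4.2 with GT-only genotypes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=soletrace\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            calls = [
                "./." if np.isnan(v) else _GT_CODE[v] for v in g.genotypes[:, j]
            ]
            fh.write(
                f"chr1\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _read_vcf(path: Path, metadata: pd.DataFrame | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    locus_ids = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = var.gt_types.astype(float)  # 0,1,2, 3=unknown with gts012
        gt[gt == 3] = np.nan
        rows.append(gt)
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_skipped:
        log.info("skipped %d multi-allelic records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    geno = np.stack(rows, axis=1)
    subunits, years = _subunits_from_metadata(samples, metadata, path)
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=samples,
        locus_ids=locus_ids,
        subunits=subunits,
        years=years,
    )


def _subunits_from_metadata(samples, metadata, path):
    if metadata is None:
        return np.array(["unknown"] * len(samples)), None
    meta = metadata.set_index("fish_id")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples in {path} missing from metadata: {missing}")
    subunits = np.array([meta.loc[s, "subunit"] for s in samples])
    years = (
        np.array([meta.loc[s, "year"] for s in samples])
        if "year" in meta.columns
        else None
    )
    return subunits, years


def write_csv012(g: GenotypeMatrix, path: str | Path) -> None:
    """0/1/2 CSV: first column sample id, locus ids in the header, blank = missing."""
    df = pd.DataFrame(g.genotypes, index=g.sample_ids, columns=g.locus_ids)
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.index.name = "sample_id"
    df.to_csv(path)


def read_genotypes(
    path: str | Path,
    format: str | None = None,
    metadata: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read genotypes from VCF or 0/1/2 CSV (format inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("vcf" if path.suffix.lower() == ".vcf" else "csv012")
    if fmt == "vcf":
        return _read_vcf(path, metadata)
    if fmt != "csv012":
        raise ValueError(f"unknown genotype format {fmt!r}")
    df = pd.read_csv(path, index_col=0, dtype=str)
    geno = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).to_numpy(float)
    bad = ~(np.isnan(geno) | np.isin(geno, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"malformed genotype at sample {df.index[i]!r}, locus {df.columns[j]!r}"
        )
    samples = list(df.index.astype(str))
    subunits, years = _subunits_from_metadata(samples, metadata, path)
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=samples,
        locus_ids=list(df.columns.astype(str)),
        subunits=subunits,
        years=years,
    )


def write_contours(contours: list[Contour], path: str | Path) -> None:
    """Long-format contour CSV: otolith_id, point_index, x, y."""
    frames = []
    for c in contours:
        frames.append(
            pd.DataFrame(
                {
                    "otolith_id": c.otolith_id,
                    "point_index": np.arange(c.n_points),
                    "x": c.points[:, 0],
                    "y": c.points[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_contours(
    path: str | Path, otolith_table: pd.DataFrame | None = None
) -> list[Contour]:
    """Read contours CSV; points reordered by index, orientation normalized CCW."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"otolith_id", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"contour CSV must have columns {sorted(required)}")
    if df.duplicated(subset=["otolith_id", "point_index"]).any():
        raise ValueError("duplicate (otolith_id, point_index) rows")
    meta = None
    if otolith_table is not None:
        meta = otolith_table.set_index("otolith_id")
    out = []
    for oid, grp in df.groupby("otolith_id", sort=False):
        grp = grp.sort_values("point_index")
        pts = grp[["x", "y"]].to_numpy(float)
        if len(pts) < 3:
            raise ValueError(f"otolith {oid} has fewer than 3 points")
        fish_id, side = "", "R"
        if meta is not None and oid in meta.index:
            fish_id = str(meta.loc[oid, "fish_id"])
            side = str(meta.loc[oid, "side"])
        out.append(Contour(points=pts, otolith_id=str(oid), fish_id=fish_id, side=side))
    return out


_SUBUNIT_VOCAB = {"SW", "NE", "UK"}


def write_metadata(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_metadata(path: str | Path, otolith_level: bool = False) -> pd.DataFrame:
    """Read a sample table, enforcing controlled vocabularies and unique ids."""
    df = pd.read_csv(path)
    key = "otolith_id" if otolith_level else "fish_id"
    if key not in df.columns:
        raise ValueError(f"metadata must contain a {key} column")
    if df[key].duplicated().any():
        dups = df.loc[df[key].duplicated(), key].tolist()
        raise ValueError(f"duplicate ids in metadata: {dups}")
    bad_sub = set(df["subunit"].astype(str)) - _SUBUNIT_VOCAB
    if bad_sub:
        raise ValueError(f"unknown subunit labels: {sorted(bad_sub)}")
    if "sex" in df.columns:
        bad = set(df["sex"].astype(str)) - {"F", "M"}
        if bad:
            raise ValueError(f"unknown sex codes: {sorted(bad)}")
    if "side" in df.columns:
        bad = set(df["side"].astype(str)) - {"L", "R"}
        if bad:
            raise ValueError(f"unknown side codes: {sorted(bad)}")
    return df


def write_truth(truth: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=_default))
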