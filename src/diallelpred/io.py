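"""Plain-TSV interchange formats and VCF import.

All tables are UTF-8, tab-separated with a header row.  Reals are written
with 12 significant digits so that write-then-read is the identity (bit-exact
for integers and ids).  Parse failures raise :class:`ParseError` naming the
file, line and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import Grm
from .simulate import GenotypeMatrix, Pedigree, PhenotypeTable, SiteMap

__all__ = [
    "ParseError",
    "write_sites", "read_sites",
    "write_genotypes", "read_genotypes",
    "write_pedigree", "read_pedigree",
    "write_phenotypes", "read_phenotypes",
    "write_grm", "read_grm",
    "write_predictions", "read_predictions",
    "write_results", "read_results",
    "import_vcf",
]

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Input-format error with file/line/column context."""

    def __init__(self, path, message: str, line: int | None = None,
                 column: str | None = None):
        loc = f"{path}"
        if line is not None:
            loc += f", line {line}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(path, f"missing columns {missing}")


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(path, f"unreadable TSV ({exc})") from exc


# -- sites ------------------------------------------------------------------


def write_sites(sites: SiteMap, path) -> None:
    df = sites.to_frame()
    df["pos_cM"] = [(_FLOAT_FMT % v) for v in df["pos_cM"]]
    df.to_csv(path, sep="\t", index=False)


def read_sites(path, chrom_length_cM: float | None = None) -> SiteMap:
    df = _read_tsv(path, dtype={"site_id": str})
    _require_columns(df, ("site_id", "chrom", "pos_cM"), path)
    if df["site_id"].duplicated().any():
        line = int(df.index[df["site_id"].duplicated()][0]) + 2
        raise ParseError(path, "duplicate site_id", line=line, column="site_id")
    length = chrom_length_cM if chrom_length_cM is not None else float(
        df["pos_cM"].max() if len(df) else 0.0
    ) or 1.0
    try:
        return SiteMap(
            site_id=df["site_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=np.int64),
            pos_cM=df["pos_cM"].to_numpy(dtype=np.float64),
            chrom_length_cM=length,
        )
    except ValueError as exc:
        raise ParseError(path, str(exc)) from exc


# -- genotypes --------------------------------------------------------------


def write_genotypes(G: GenotypeMatrix, path) -> None:
    G.to_frame().to_csv(path, sep="\t")


def read_genotypes(path, sites: SiteMap | None = None) -> GenotypeMatrix:
    df = _read_tsv(path, dtype={"hybrid_id": str})
    _require_columns(df, ("hybrid_id",), path)
    df = df.set_index("hybrid_id")
    if df.index.duplicated().any():
        line = int(np.nonzero(df.index.duplicated())[0][0]) + 2
        raise ParseError(path, "duplicate hybrid_id", line=line, column="hybrid_id")
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(path, f"dosage value {vals[r, c]!r} not in {{0,1,2}}",
                         line=int(r) + 2, column=str(df.columns[c]))
    if sites is None:
        n = len(df.columns)
        sites = SiteMap(
            site_id=np.array(df.columns, dtype=object),
            chrom=np.ones(n, dtype=np.int64),
            pos_cM=np.arange(n, dtype=np.float64),
            chrom_length_cM=float(max(n, 1)),
        )
    else:
        if list(df.columns) != list(sites.site_id):
            raise ParseError(path, "genotype columns do not match the site map")
    return GenotypeMatrix(
        individuals=df.index.to_numpy(dtype=object), sites=sites,
        G=vals.astype(np.int8),
    )


# -- pedigree ---------------------------------------------------------------


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ("hybrid_id", "parent_a", "parent_alpha"), path)
    if df["hybrid_id"].duplicated().any():
        line = int(df.index[df["hybrid_id"].duplicated()][0]) + 2
        raise ParseError(path, "duplicate hybrid_id", line=line, column="hybrid_id")
    try:
        return Pedigree(
            hybrid_id=df["hybrid_id"].to_numpy(dtype=object),
            parent_a=df["parent_a"].to_numpy(dtype=object),
            parent_alpha=df["parent_alpha"].to_numpy(dtype=object),
        )
    except ValueError as exc:
        raise ParseError(path, str(exc)) from exc


# -- phenotypes -------------------------------------------------------------


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pheno.frame.copy()
    df["value"] = [(_FLOAT_FMT % v) for v in df["value"]]
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_tsv(path, dtype={"hybrid_id": str, "trait": str})
    _require_columns(df, ("hybrid_id", "trait", "replicate", "value"), path)
    try:
        return PhenotypeTable(df)
    except ValueError as exc:
        raise ParseError(path, str(exc)) from exc


# -- GRM --------------------------------------------------------------------


def write_grm(grm: Grm, path) -> None:
    df = pd.DataFrame(grm.K, index=pd.Index(grm.individuals, name="hybrid_id"),
                      columns=list(grm.individuals))
    df = df.map(lambda v: _FLOAT_FMT % v)
    df.to_csv(path, sep="\t")


def read_grm(path, c: float = float("nan")) -> Grm:
    df = _read_tsv(path, dtype={"hybrid_id": str}).set_index("hybrid_id")
    if list(df.index) != list(df.columns):
        raise ParseError(path, "GRM row and column ids differ")
    return Grm(individuals=df.index.to_numpy(dtype=object),
               K=df.to_numpy(dtype=np.float64), c=c)


# -- predictions / results --------------------------------------------------

_PRED_COLS = ("hybrid_id", "trait", "fold", "pred_mean", "pred_sd")
_RESULT_COLS = ("trait", "model", "scenario", "fold", "r2", "n_train",
                "mean_pred_sd", "resid_sd")


def write_predictions(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(_PRED_COLS)].copy()
    for c in ("pred_mean", "pred_sd"):
        out[c] = [(_FLOAT_FMT % v) for v in out[c]]
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"hybrid_id": str, "trait": str})
    _require_columns(df, _PRED_COLS, path)
    return df


def write_results(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(_RESULT_COLS)].copy()
    for c in ("r2", "mean_pred_sd", "resid_sd"):
        out[c] = [(_FLOAT_FMT % v) for v in out[c]]
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"trait": str, "model": str, "scenario": str})
    _require_columns(df, _RESULT_COLS, path)
    return df


# -- VCF import -------------------------------------------------------------


def import_vcf(path) -> GenotypeMatrix:
    """Import biallelic diploid genotypes from a VCF.

    GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 (phased ``|`` treated like ``/``).
    Multi-allelic records and records with any missing GT are skipped (count
    reported via a logged warning).
    """
    import warnings

    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - env provides cyvcf2
        raise ImportError("VCF import requires the cyvcf2 package") from exc

    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, ids, chroms, pos = [], [], [], []
    skipped = 0
    chrom_codes: dict[str, int] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gts = rec.genotype.array()
        alleles = gts[:, :2]
        if (alleles < 0).any():
            skipped += 1
            continue
        dosage = alleles.sum(axis=1)
        code = chrom_codes.setdefault(rec.CHROM, len(chrom_codes) + 1)
        if chroms and chroms[-1] == code and pos[-1] >= rec.POS:
            skipped += 1  # unsorted/duplicate position
            continue
        rows.append(dosage.astype(np.int8))
        ids.append(rec.ID if rec.ID not in (None, ".") else
                   f"{rec.CHROM}_{rec.POS}")
        chroms.append(code)
        pos.append(float(rec.POS))
    if skipped:
        warnings.warn(f"skipped {skipped} VCF records (multi-allelic, missing "
                      "GT, or unsorted)")
    if not rows:
        raise ParseError(path, "no usable biallelic records")
    G = np.vstack(rows).T
    sites = SiteMap(
        site_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=np.int64),
        pos_cM=np.array(pos, dtype=np.float64),
        chrom_length_cM=float(max(pos)),
    )
    return GenotypeMatrix(individuals=np.array(samples, dtype=object),
                          sites=sites, G=G)
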