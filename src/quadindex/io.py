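"""Readers and writers: phenotype tables, marker matrices, summary tables.

All tabular outputs are plain CSV with fixed column orders mirroring the
standard selection-response table layout (per-cycle rows plus an Average
row; R and gains displayed at 1 decimal, correlations at 3). Full-precision
companion files are written alongside the rounded displays.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import CovarianceSet, TraitPanel
from .response import SelectionSummary

logger = logging.getLogger(__name__)

__all__ = [
    "read_phenotypes",
    "read_markers",
    "write_summary_tables",
    "summaries_to_frame",
    "average_row",
    "write_covariance_bundle",
    "read_covariance_bundle",
]

ROUND_R = 1
ROUND_COR = 3


def read_phenotypes(path: str | Path) -> TraitPanel:
    """Read a long-format phenotype CSV/TSV: genotype, rep, trait columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty phenotype file") from exc
    missing = {"genotype", "rep"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    traits = [c for c in df.columns if c not in ("genotype", "rep")]
    for trait in traits:
        bad = pd.to_numeric(df[trait], errors="coerce").isna() & df[trait].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric cells in column {trait!r}, rows {rows}")
        df[trait] = pd.to_numeric(df[trait], errors="coerce")
    panel = TraitPanel(df)
    logger.info("read %d records, %d genotypes, traits %s", len(df), df["genotype"].nunique(), traits)
    return panel


def write_phenotypes(panel: TraitPanel, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    panel.data.to_csv(path, sep=sep, index=False)


def read_markers(path: str | Path, fmt: str = "tsv") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read marker genotype codes. Returns (codes n x m, ids, marker names).

    ``fmt="tsv"``: rows = genotypes with an id column, cells in {0,1,2,NA}.
    ``fmt="vcf"``: biallelic SNPs only; GT fields become allele counts and
    multiallelic records are skipped with a logged count (requires cyvcf2).
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        ids = df.iloc[:, 0].to_numpy()
        codes = df.iloc[:, 1:].to_numpy(dtype=float)
        names = df.columns[1:].to_numpy()
        na_frac = np.isnan(codes).mean()
        if na_frac:
            logger.info("markers: %.2f%% missing cells", 100 * na_frac)
        return codes, ids, names
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown marker format {fmt!r}")


def _read_vcf(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.asarray(vcf.samples)
    cols, names = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gt = rec.genotype.array()[:, :2].astype(float)
        gt[gt < 0] = np.nan
        cols.append(gt.sum(axis=1))
        names.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if skipped:
        logger.warning("skipped %d multiallelic VCF records", skipped)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic records")
    return np.column_stack(cols), ids, np.asarray(names)


def summaries_to_frame(summaries: list[SelectionSummary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(response table, per-trait gains table) from SelectionSummary rows."""
    if not summaries:
        raise ValueError("no summaries to tabulate")
    resp = pd.DataFrame(
        {
            "cycle": [s.cycle for s in summaries],
            "index": [s.index_kind for s in summaries],
            "R": [s.R for s in summaries],
            "SCor": [s.scor for s in summaries],
            "SR-MSPE": [s.sr_mspe for s in summaries],
        }
    )
    t = len(np.atleast_1d(summaries[0].gains))
    gains = pd.DataFrame(
        [np.atleast_1d(s.gains) for s in summaries], columns=[f"T{i + 1}" for i in range(t)]
    )
    gains.insert(0, "index", [s.index_kind for s in summaries])
    gains.insert(0, "cycle", [s.cycle for s in summaries])
    return resp, gains


def average_row(df: pd.DataFrame, by: str | None = "index") -> pd.DataFrame:
    """Arithmetic mean of the per-cycle rows (the table's Average row)."""
    num = [c for c in df.columns if c != "cycle" and np.issubdtype(df[c].dtype, np.number)]
    if by and by in df.columns:
        out = df.groupby(by, sort=False)[num].mean().reset_index()
    else:
        out = df[num].mean().to_frame().T
    out.insert(0, "cycle", "Average")
    return out


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if not np.issubdtype(out[c].dtype, np.number):
            continue
        out[c] = out[c].round(ROUND_COR if c == "SCor" else ROUND_R)
    return out


def write_summary_tables(summaries: list[SelectionSummary], outdir: str | Path) -> dict[str, Path]:
    """Write the response and gains CSVs (per-cycle rows + Average row).

    Column order: cycle, index, R, SCor, SR-MSPE; gains table: cycle, index,
    then one column per trait. Rounded display files plus ``*_full.csv``
    full-precision companions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resp, gains = summaries_to_frame(summaries)
    paths = {}
    for name, df in (("response", resp), ("gains", gains)):
        avg = average_row(df)
        full = pd.concat([df, avg], ignore_index=True)
        p_full = outdir / f"{name}_full.csv"
        full.to_csv(p_full, index=False)
        p_disp = outdir / f"{name}.csv"
        _rounded(full).to_csv(p_disp, index=False)
        paths[name] = p_disp
        paths[f"{name}_full"] = p_full
    return paths


def write_covariance_bundle(covs: CovarianceSet, path: str | Path) -> None:
    """Serialize a CovarianceSet as labeled CSV blocks in one text file."""
    path = Path(path)
    traits = covs.traits or [f"T{i + 1}" for i in range(covs.P.shape[0] if covs.P is not None else 0)]
    with open(path, "w") as fh:
        fh.write(f"# covariance bundle; traits: {','.join(traits)}; n_reps: {covs.n_reps}\n")
        for label in ("P", "G", "Gamma"):
            mat = getattr(covs, label)
            if mat is None:
                continue
            fh.write(f"[{label}]\n")
            pd.DataFrame(mat, index=traits, columns=traits).to_csv(fh)
        if covs.h2 is not None:
            fh.write("[h2]\n")
            pd.Series(covs.h2, index=traits, name="h2").to_csv(fh)


def read_covariance_bundle(path: str | Path) -> CovarianceSet:
    text = Path(path).read_text().splitlines()
    header = text[0]
    traits = header.split("traits:")[1].split(";")[0].strip().split(",")
    n_reps = header.split("n_reps:")[1].strip()
    n_reps = None if n_reps == "None" else float(n_reps)
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text[1:]:
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            blocks[current] = []
        elif current is not None:
            blocks[current].append(line)
    import io as _io

    out = CovarianceSet(traits=traits, n_reps=n_reps)
    for label in ("P", "G", "Gamma"):
        if label in blocks:
            df = pd.read_csv(_io.StringIO("\n".join(blocks[label])), index_col=0)
            setattr(out, label, df.to_numpy(dtype=float))
    if "h2" in blocks:
        df = pd.read_csv(_io.StringIO("\n".join(blocks["h2"])), index_col=0)
        out.h2 = df["h2"].to_numpy(dtype=float)
    return out
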