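"""Readers and writers for the documented exchange formats.

Formats (all plain text):

* ``xic.tsv``       — class_id, rt_min, intensity (one row per trace point)
* ``ms2.tsv``       — class_id, rt_min, mz, intensity (one row per peak)
* ``abundance.csv`` — sample, condition, replicate, backbone, form, fraction,
  below_limit (tidy) — also readable from a wide samples-in-columns layout or
  an XLSX workbook shaped like a supplementary relative-quantification table.

Readers validate schemas strictly and name the offending line on failure;
every writer/reader pair round-trips to equal in-memory objects.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .quantification import AbundanceTable, TIDY_COLUMNS, family_unit_ids
from .signals import Ms2Spectrum, XicTrace
from . import histone_model as hm

__all__ = [
    "ParseError",
    "read_xic_tsv",
    "write_xic_tsv",
    "read_ms2_tsv",
    "write_ms2_tsv",
    "read_abundance_csv",
    "read_abundance_xlsx",
    "write_abundance_csv",
    "write_enrichment_csv",
    "write_correlations_csv",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _read_table(path: str | Path, columns: list[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file", stacklevel=3)
        return pd.DataFrame(columns=columns)
    if list(df.columns) != columns:
        raise ParseError(f"{path}: header {list(df.columns)} != expected {columns}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: line {line}: non-numeric value in column {col!r}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"{path}: line {line}: missing value in column {col!r}")
        df[col] = coerced
    return df


def write_xic_tsv(path: str | Path, traces: list[XicTrace]) -> None:
    rows = []
    for t in traces:
        for rt, inten in zip(t.rt_min, t.intensity):
            rows.append((t.trace_id, rt, inten))
    pd.DataFrame(rows, columns=["class_id", "rt_min", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_xic_tsv(path: str | Path) -> list[XicTrace]:
    df = _read_table(path, ["class_id", "rt_min", "intensity"], sep="\t")
    if df.empty:
        return []
    df = _require_numeric(df, ["rt_min", "intensity"], Path(path))
    traces = []
    for tid in df["class_id"].unique():
        sub = df[df["class_id"] == tid]
        try:
            traces.append(XicTrace(str(tid), sub["rt_min"].to_numpy(), sub["intensity"].to_numpy()))
        except ValueError as e:
            raise ParseError(f"{path}: trace {tid!r}: {e}") from e
    return traces


def write_ms2_tsv(path: str | Path, spectra: list[Ms2Spectrum]) -> None:
    rows = []
    for s in spectra:
        for mz, inten in zip(s.mz, s.intensity):
            rows.append((s.precursor_id, s.rt_min, mz, inten))
    pd.DataFrame(rows, columns=["class_id", "rt_min", "mz", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_ms2_tsv(path: str | Path) -> list[Ms2Spectrum]:
    df = _read_table(path, ["class_id", "rt_min", "mz", "intensity"], sep="\t")
    if df.empty:
        return []
    df = _require_numeric(df, ["rt_min", "mz", "intensity"], Path(path))
    spectra = []
    for (tid, rt), sub in df.groupby(["class_id", "rt_min"], sort=False):
        spectra.append(
            Ms2Spectrum(str(tid), float(rt), sub["mz"].to_numpy(), sub["intensity"].to_numpy())
        )
    return spectra


def write_abundance_csv(path: str | Path, table: AbundanceTable) -> None:
    table.data.to_csv(path, index=False, float_format="%.10g")


def _finalize_abundance(df: pd.DataFrame, path: Path, renorm_tol: float = 1e-3) -> AbundanceTable:
    df = _require_numeric(df, ["fraction"], path)
    if (df["fraction"] < 0).any():
        line = int((df["fraction"] < 0).idxmax()) + 2
        raise ParseError(f"{path}: line {line}: negative fraction")
    known: set[str] = set()
    for fam in df["backbone"].unique():
        try:
            known |= family_unit_ids(str(fam))
        except hm.RegistryError as e:
            raise ParseError(f"{path}: {e}") from e
    unknown = sorted(set(df["form"]) - known)
    if unknown:
        raise ParseError(
            f"{path}: unrecognized form labels {unknown[:10]}; accepted vocabulary is the "
            f"registry's enumerated form and class ids (e.g. 'H3_18-26:K18ac')"
        )
    out = []
    for (sample, fam), grp in df.groupby(["sample", "backbone"], sort=False):
        grp = grp.copy()
        live = grp.loc[~grp["below_limit"], "fraction"]
        total = float(live.sum())
        if total > 0 and abs(total - 1.0) > renorm_tol:
            warnings.warn(
                f"{path}: sample {sample!r} family {fam!r} sums to {total:.6g}; renormalizing",
                stacklevel=3,
            )
        if total > 0:
            grp.loc[~grp["below_limit"], "fraction"] = live / total
        out.append(grp)
    table = AbundanceTable(pd.concat(out, ignore_index=True))
    table.validate(atol=1e-6)
    return table


def read_abundance_csv(path: str | Path) -> AbundanceTable:
    df = _read_table(Path(path), TIDY_COLUMNS, sep=",")
    if df.empty:
        return AbundanceTable(pd.DataFrame(columns=TIDY_COLUMNS))
    df["below_limit"] = df["below_limit"].astype(bool)
    return _finalize_abundance(df, Path(path))


def _family_of_form(form: str) -> str:
    reg = hm.default_registry()
    backbone_id = form.split(":", 1)[0]
    if backbone_id in reg:
        return reg[backbone_id].family
    raise ParseError(f"form label {form!r} does not start with a registered backbone id")


def read_abundance_xlsx(path: str | Path, sheet: int | str = 0) -> AbundanceTable:
    """Read a relative-quantification workbook (tidy or wide layout).

    Tidy: the standard abundance.csv columns.  Wide: a ``form`` column plus
    one column per sample (named ``condition_rN``); fractions are
    renormalized per family when group sums drift beyond 1e-3.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if list(df.columns) == TIDY_COLUMNS:
        df["below_limit"] = df["below_limit"].astype(bool)
        return _finalize_abundance(df, Path(path))
    if "form" not in df.columns:
        raise ParseError(f"{path}: expected tidy columns {TIDY_COLUMNS} or a 'form' column")
    sample_cols = [c for c in df.columns if c != "form"]
    rows = []
    for col in sample_cols:
        cond, _, rep = str(col).rpartition("_r")
        if not cond or not rep.isdigit():
            raise ParseError(
                f"{path}: sample column {col!r} must be named <condition>_r<replicate>"
            )
        for _, rec in df.iterrows():
            form = str(rec["form"])
            val = rec[col]
            below = pd.isna(val)
            rows.append(
                (str(col), cond, int(rep), _family_of_form(form), form,
                 0.0 if below else float(val), below)
            )
    tidy = pd.DataFrame(rows, columns=TIDY_COLUMNS)
    return _finalize_abundance(tidy, Path(path))


def write_enrichment_csv(path: str | Path, enrichment: pd.DataFrame) -> None:
    enrichment.to_csv(path, index=False, float_format="%.10g")


def write_correlations_csv(path: str | Path, corr) -> None:
    rows = []
    for i, a in enumerate(corr.samples):
        for j, b in enumerate(corr.samples):
            if j <= i:
                continue
            rows.append(
                (a, b, corr.r.loc[a, b], corr.p.loc[a, b],
                 corr.ci_lower.loc[a, b], corr.ci_upper.loc[a, b], corr.n.loc[a, b])
            )
    pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "r", "p", "ci_lower", "ci_upper", "n_common"]
    ).to_csv(path, index=False, float_format="%.10g")
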