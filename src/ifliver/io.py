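"""Readers and writers for every external table the pipeline touches.

All interchange formats are plain TSV (expression tables, probe maps, sample
sheets, trait tables, result tables) plus standard GMT for pathway
annotations.  In memory the pipeline uses pandas objects with documented
shapes:

* probe / expression matrix — ``DataFrame`` indexed by probe (or probe-set)
  id, one column per array, ``attrs["log2"]`` recording the scale;
* probe→probe-set map — ``Series`` indexed by probe id;
* sample sheet — ``DataFrame`` indexed by array id with ``treatment`` and
  ``individual_id`` columns;
* trait table — ``DataFrame`` indexed by individual id, one column per trait
  (missing values permitted);
* pathway collection — ``dict`` pathway id → :class:`Pathway`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .params import TREATMENTS

#: The ten trait variables: seven liver/body physiology measures plus the
#: arcuate-nucleus expression of three appetite-regulating genes.
TRAIT_NAMES: tuple[str, ...] = (
    "body_mass",
    "liver_mass",
    "relative_liver_mass",
    "total_liver_lipids",
    "liver_lipid_concentration",
    "total_liver_glycogen",
    "liver_glycogen_concentration",
    "AgRP",
    "POMC",
    "NPY",
)


@dataclass
class Pathway:
    """A named gene set from a GMT annotation file."""

    pathway_id: str
    name: str
    genes: set = field(default_factory=set)


def read_expression_table(path: str, log_scale: bool = True) -> pd.DataFrame:
    """Read a probe (or probe-set) × array intensity table.

    The file must be TSV with a header row of array ids and probe ids in the
    first column.  ``log_scale`` records whether values are already log2; when
    False all values must be strictly positive (pre-log intensities).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:10]
        raise FormatError(f"duplicate probe ids in {path}: {dupes}")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        # locate the first offending cell for the error message
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[coerced.isna() & df[col].notna()]
            where = f"row {row[0]!r}, column {col!r}" if len(row) else f"column {col!r}"
            raise FormatError(f"non-numeric cell in {path} at {where}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"non-finite values in {path}")
    if not log_scale and (df.to_numpy() <= 0).any():
        raise FormatError(f"non-positive intensities in {path} but log_scale=False")
    df = df.astype(float)
    df.index.name = "probe_id"
    df.attrs["log2"] = bool(log_scale)
    return df


def write_expression_table(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_probe_map(path: str) -> pd.Series:
    """Read the probe → probe-set map (columns ``probe_id``, ``probeset_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "probeset_id"):
        if col not in df.columns:
            raise FormatError(f"probe map {path} lacks required column {col!r}")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()[:10]
        raise FormatError(f"probes mapped more than once in {path}: {dupes}")
    return df.set_index("probe_id")["probeset_id"]


def write_probe_map(probe_map: pd.Series, path: str) -> None:
    probe_map.rename("probeset_id").rename_axis("probe_id").to_frame().to_csv(
        path, sep="\t"
    )


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read the array → (treatment, individual) assignment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("array_id", "treatment", "individual_id"):
        if col not in df.columns:
            raise FormatError(f"sample sheet {path} lacks required column {col!r}")
    unknown = sorted(set(df["treatment"]) - set(TREATMENTS))
    if unknown:
        raise ValidationError(
            f"unknown treatment label(s) {unknown} in {path}; "
            f"allowed labels are {list(TREATMENTS)}"
        )
    if df["array_id"].duplicated().any():
        raise FormatError(f"duplicate array ids in {path}")
    if df["individual_id"].duplicated().any():
        raise FormatError(f"individual assigned to more than one array in {path}")
    return df.set_index("array_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str) -> None:
    sheet.rename_axis("array_id").to_csv(path, sep="\t")


def read_trait_table(path: str) -> pd.DataFrame:
    """Read the individual-level trait table; absent trait columns are allowed."""
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise FormatError(f"trait table {path} lacks required column 'individual_id'")
    df = df.set_index("individual_id")
    keep = [c for c in df.columns if c in TRAIT_NAMES]
    df = df[keep].apply(pd.to_numeric, errors="coerce")
    return df


def write_trait_table(traits: pd.DataFrame, path: str) -> None:
    traits.rename_axis("individual_id").to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path: str) -> dict:
    """Read a GMT pathway annotation file (name, description, genes...)."""
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} in {path} has fewer than 3 fields"
                )
            pid, name = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"GMT line {lineno} in {path} has an empty gene set")
            pathways[pid] = Pathway(pid, name, genes)
    return pathways


def write_gmt(pathways: dict, path: str) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways):
            pw = pathways[pid]
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


# columns used to impose a deterministic row order on result tables
_SORT_CANDIDATES = ("gene", "probeset_id", "unit", "cluster", "pathway", "pair", "trait")


def write_results(bundle: dict, out_dir: str) -> list:
    """Write a bundle of result tables, one TSV each, deterministically.

    ``bundle`` maps a table name to a DataFrame.  Floats are written at six
    significant digits; rows are ordered by the table's identifier columns
    (gene, then pair, etc.) so repeated writes are byte-identical.
    Returns the list of file paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in sorted(bundle):
        df = bundle[name]
        if df is None:
            continue
        df = df.reset_index() if df.index.name else df.copy()
        sort_cols = [c for c in _SORT_CANDIDATES if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="stable")
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    return written
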