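"""Readers and validators for MaxQuant-dialect tables and the sample sheet.

All tabular inputs are plain tab-separated text in the shapes MaxQuant emits:
a ``proteinGroups.txt``-like table (one row per protein group, ``+``/blank flag
columns), a ``peptides.txt``-like table (one row per peptide with one
``LFQ intensity <sample>`` column per run), and a small sample sheet assigning
each run to one of the study groups M (acute methanol poisoning), S (survivors,
4-year follow-up) or C (controls), with optional pair identifiers linking the
acute and follow-up sample of the same subject.

An LFQ intensity of 0 encodes "not quantified" (MaxQuant convention). Every
downstream module treats 0 as missing, never as a measured abundance; no
imputation is performed anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("M", "S", "C")

#: MaxQuant peptides.txt column holding the peptide sequence.
SEQUENCE_COL = "Sequence"
PROTEIN_GROUP_COL = "Protein group IDs"
UNIQUE_COL = "Unique (Groups)"
LFQ_PREFIX = "LFQ intensity "

MAJORITY_COL = "Majority protein IDs"
ONLY_BY_SITE_COL = "Only identified by site"
REVERSE_COL = "Reverse"
CONTAMINANT_COL = "Potential contaminant"
UNIQUE_PEPTIDES_COL = "Unique peptides"
ID_COL = "id"

CONTAMINANT_PREFIX = "CON__"

#: MaxQuant minimum peptide length for identification.
MIN_PEPTIDE_LENGTH = 7


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV table, sniffing the delimiter from the extension."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample sheet.

    Returns a DataFrame with columns ``sample_id``, ``group`` (one of M/S/C)
    and ``pair_id`` (NaN when the sample is unpaired). Each pair_id must occur
    on exactly one M sample and exactly one S sample.
    """
    df = _read_table(path)
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].str.strip(),
            "group": df["group"].str.strip().str.upper(),
        }
    )
    if "pair_id" in df.columns:
        pair = df["pair_id"].str.strip()
        out["pair_id"] = pair.where(pair != "", other=pd.NA)
    else:
        out["pair_id"] = pd.NA

    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    bad = set(out["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}; expected {GROUPS}")
    validate_pairs(out)
    return out


def validate_pairs(sheet: pd.DataFrame) -> None:
    """Check that every pair_id spans exactly one M and one S sample."""
    paired = sheet.dropna(subset=["pair_id"])
    for pid, sub in paired.groupby("pair_id"):
        groups = sorted(sub["group"].tolist())
        if groups != ["M", "S"]:
            raise ValueError(
                f"pair {pid!r} must contain exactly one M and one S sample, got {groups}"
            )


def group_samples(sheet: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to one group, or to the pooled 'SC' set."""
    if group == "SC":
        return group_samples(sheet, "S") + group_samples(sheet, "C")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return sheet.loc[sheet["group"] == group, "sample_id"].tolist()


def paired_samples(sheet: pd.DataFrame) -> pd.DataFrame:
    """One row per pair: columns pair_id, m_sample, s_sample."""
    paired = sheet.dropna(subset=["pair_id"])
    rows = []
    for pid, sub in paired.groupby("pair_id"):
        rows.append(
            {
                "pair_id": pid,
                "m_sample": sub.loc[sub["group"] == "M", "sample_id"].iloc[0],
                "s_sample": sub.loc[sub["group"] == "S", "sample_id"].iloc[0],
            }
        )
    return pd.DataFrame(rows, columns=["pair_id", "m_sample", "s_sample"])


def _parse_flag(series: pd.Series, column: str) -> pd.Series:
    """Parse a MaxQuant flag column: '+'/'' or true/false text."""
    raw = series.str.strip()
    out = []
    for val, low in zip(raw, raw.str.lower()):
        if val == "+":
            out.append(True)
        elif low in ("", "false"):
            out.append(False)
        elif low == "true":
            out.append(True)
        else:
            raise ValueError(f"unparseable flag {val!r} in column {column!r}")
    return pd.Series(out, index=series.index, dtype=bool)


def read_protein_groups(path: str | Path) -> pd.DataFrame:
    """Read a proteinGroups.txt-dialect table.

    Returns one row per protein group with columns ``group_id``,
    ``majority_ids`` (list of accessions), the QC flags ``only_by_site``,
    ``reverse``, ``contaminant``, the derived ``all_ids_contaminant`` (every
    majority id prefixed ``CON__``) and ``n_unique_peptides``.
    """
    df = _read_table(path)
    for col in (MAJORITY_COL, ID_COL, UNIQUE_PEPTIDES_COL):
        if col not in df.columns:
            raise ValueError(f"protein groups table missing column {col!r}")

    majority = [
        [tok.strip() for tok in cell.split(";") if tok.strip()]
        for cell in df[MAJORITY_COL]
    ]
    if any(len(ids) == 0 for ids in majority):
        raise ValueError("protein group with empty 'Majority protein IDs'")

    def flag(col: str) -> pd.Series:
        if col in df.columns:
            return _parse_flag(df[col], col)
        return pd.Series(False, index=df.index)

    out = pd.DataFrame(
        {
            "group_id": df[ID_COL].astype(int),
            "majority_ids": majority,
            "only_by_site": flag(ONLY_BY_SITE_COL),
            "reverse": flag(REVERSE_COL),
            "contaminant": flag(CONTAMINANT_COL),
            "n_unique_peptides": df[UNIQUE_PEPTIDES_COL].astype(int),
        }
    )
    out["all_ids_contaminant"] = [
        all(i.startswith(CONTAMINANT_PREFIX) for i in ids) for ids in majority
    ]
    if out["group_id"].duplicated().any():
        raise ValueError("duplicate protein group ids")
    if (out["n_unique_peptides"] < 0).any():
        raise ValueError("negative unique-peptide count")
    return out


def read_peptide_table(path: str | Path, samples: pd.DataFrame) -> pd.DataFrame:
    """Read a peptides.txt-dialect table restricted to the sheet's samples.

    Returns a DataFrame with columns ``sequence``, ``length``,
    ``protein_group_id``, ``is_unique`` followed by one float column per
    sample_id (0.0 = not quantified). A ``Length`` column, if present, must
    agree with the sequence's residue count.
    """
    df = _read_table(path)
    for col in (SEQUENCE_COL, PROTEIN_GROUP_COL, UNIQUE_COL):
        if col not in df.columns:
            raise ValueError(f"peptide table missing column {col!r}")

    sample_ids = samples["sample_id"].tolist()
    missing_cols = [s for s in sample_ids if LFQ_PREFIX + s not in df.columns]
    if missing_cols:
        raise ValueError(f"no LFQ intensity column for sample(s): {missing_cols}")

    seqs = df[SEQUENCE_COL].str.strip()
    lengths = seqs.str.len()
    if "Length" in df.columns:
        stated = df["Length"].astype(int)
        if (stated != lengths).any():
            raise ValueError("stated Length column disagrees with sequence length")
    if (lengths < MIN_PEPTIDE_LENGTH).any():
        raise ValueError(
            f"peptide shorter than the minimum of {MIN_PEPTIDE_LENGTH} residues"
        )

    group_ids = []
    for cell in df[PROTEIN_GROUP_COL]:
        toks = [t for t in str(cell).split(";") if t.strip()]
        if len(toks) != 1:
            raise ValueError(
                f"peptide assigned to {len(toks)} protein groups; expected exactly one"
            )
        group_ids.append(int(toks[0]))

    unique = df[UNIQUE_COL].str.strip().str.lower().map(
        {"yes": True, "no": False, "true": True, "false": False}
    )
    if unique.isna().any():
        raise ValueError("unparseable 'Unique (Groups)' value")

    out = pd.DataFrame(
        {
            "sequence": seqs,
            "length": lengths.astype(int),
            "protein_group_id": group_ids,
            "is_unique": unique.astype(bool),
        }
    )
    for s in sample_ids:
        vals = pd.to_numeric(df[LFQ_PREFIX + s])
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValueError(f"negative or non-finite LFQ intensity for sample {s}")
        out[s] = vals.astype(float)
    return out


def write_peptide_table(
    pep: pd.DataFrame, path: str | Path, float_format: str = "%.10g"
) -> None:
    """Write a PeptideTable back to the peptides.txt dialect (round-trippable)."""
    meta = pep[["sequence", "length", "protein_group_id", "is_unique"]]
    sample_ids = [c for c in pep.columns if c not in meta.columns]
    out = pd.DataFrame(
        {
            SEQUENCE_COL: meta["sequence"],
            "Length": meta["length"],
            PROTEIN_GROUP_COL: meta["protein_group_id"],
            UNIQUE_COL: np.where(meta["is_unique"], "yes", "no"),
        }
    )
    for s in sample_ids:
        out[LFQ_PREFIX + s] = pep[s]
    out.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_protein_groups(pg: pd.DataFrame, path: str | Path) -> None:
    """Write a ProteinGroupTable in the proteinGroups.txt dialect."""
    out = pd.DataFrame(
        {
            ID_COL: pg["group_id"],
            MAJORITY_COL: [";".join(ids) for ids in pg["majority_ids"]],
            ONLY_BY_SITE_COL: np.where(pg["only_by_site"], "+", ""),
            REVERSE_COL: np.where(pg["reverse"], "+", ""),
            CONTAMINANT_COL: np.where(pg["contaminant"], "+", ""),
            UNIQUE_PEPTIDES_COL: pg["n_unique_peptides"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def apply_qc_filters(
    pg: pd.DataFrame, *, remove_any_contaminant: bool = False
) -> pd.DataFrame:
    """Remove decoy and artifact protein groups.

    Drops groups only identified by site, reverse (target-decoy) hits, pure
    contaminants (every majority id prefixed ``CON__``) and groups with no
    unique peptide. With ``remove_any_contaminant=True`` the "Potential
    contaminant" flag alone suffices for removal (stricter than the default,
    which keeps mixed groups carrying at least one non-contaminant id).
    Idempotent; rows are never mutated.
    """
    contaminant_mask = (
        pg["contaminant"] if remove_any_contaminant else pg["all_ids_contaminant"]
    )
    keep = (
        ~pg["only_by_site"]
        & ~pg["reverse"]
        & ~contaminant_mask
        & (pg["n_unique_peptides"] >= 1)
    )
    removed = int((~keep).sum())
    if removed:
        logger.info("QC filters removed %d of %d protein groups", removed, len(pg))
    if keep.sum() == 0:
        logger.warning("QC filters removed every protein group")
    return pg.loc[keep].reset_index(drop=True)
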