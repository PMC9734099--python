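"""Peptide-to-protein intensity quantification.

The protein intensity quantification value of a protein group in a sample is
the maximum, over the group's *unique* peptides quantified in that sample, of
the peptide's LFQ intensity divided by its length. Shared (non-unique)
peptides never contribute. A protein is missing in a sample when none of its
unique peptides was quantified there; no imputation is applied.

The quantification matrix is a pandas DataFrame indexed by protein group id
with one float column per sample; missing cells are NaN.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROVENANCE = "max over unique peptides of (LFQ intensity / peptide length); 0 = not quantified"

_META_COLS = ("sequence", "length", "protein_group_id", "is_unique")


def peptide_sample_columns(pep: pd.DataFrame) -> list[str]:
    return [c for c in pep.columns if c not in _META_COLS]


def protein_intensity(peptides_of_protein: pd.DataFrame, sample_id: str) -> float:
    """Quantification value of one protein group in one sample (NaN if absent).

    ``peptides_of_protein`` must contain the rows of a single protein group.
    """
    if peptides_of_protein["protein_group_id"].nunique() > 1:
        raise ValueError("peptides from more than one protein group supplied")
    if (peptides_of_protein["length"] <= 0).any():
        raise ValueError("non-positive peptide length")
    rows = peptides_of_protein[
        peptides_of_protein["is_unique"] & (peptides_of_protein[sample_id] > 0)
    ]
    if rows.empty:
        return math.nan
    return float((rows[sample_id] / rows["length"]).max())


def build_quant_matrix(
    pep: pd.DataFrame, pg: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Quantification matrix for all QC-retained protein groups.

    One row per group in ``pg`` (in order), one column per sample in the
    sheet. Cells follow :func:`protein_intensity`; groups without any
    quantified unique peptide in a sample are NaN there.
    """
    sample_ids = samples["sample_id"].tolist()
    if (pep["length"] <= 0).any():
        raise ValueError("non-positive peptide length")
    keep = pep["is_unique"] & pep["protein_group_id"].isin(set(pg["group_id"]))
    sub = pep.loc[keep, ["protein_group_id", "length", *sample_ids]]

    vals = sub[sample_ids].to_numpy(dtype=float, copy=True)
    vals[vals <= 0] = np.nan
    ratios = vals / sub["length"].to_numpy(dtype=float)[:, None]
    ratio_df = pd.DataFrame(ratios, columns=sample_ids)
    ratio_df["protein_group_id"] = sub["protein_group_id"].to_numpy()
    mat = ratio_df.groupby("protein_group_id").max()
    mat = mat.reindex(pg["group_id"].to_numpy())
    mat.index.name = "protein_group_id"
    mat.attrs["provenance"] = PROVENANCE
    return mat


def merge_protein_groups(
    q: pd.DataFrame, merge_spec: Sequence[tuple[object, Iterable[object]]]
) -> pd.DataFrame:
    """Combine isoform protein groups into single rows by summation.

    Each ``(new_id, member_ids)`` entry replaces the member rows with one row
    whose value per sample is the sum of the member values (missing treated as
    0; the merged cell is missing only when every member is missing). Member
    sets must not overlap.
    """
    seen: set = set()
    out = q.copy()
    merged_rows = []
    for new_id, members in merge_spec:
        members = list(members)
        overlap = seen.intersection(members)
        if overlap:
            raise ValueError(f"protein group(s) {sorted(overlap)} in multiple merges")
        seen.update(members)
        absent = [m for m in members if m not in q.index]
        if absent:
            raise ValueError(f"merge member(s) not in matrix: {absent}")
        block = q.loc[members]
        summed = block.sum(axis=0, min_count=1)  # NaN iff all members missing
        summed.name = new_id
        merged_rows.append(summed)
        out = out.drop(index=members)
    if merged_rows:
        out = pd.concat([out, pd.DataFrame(merged_rows)])
        out.index.name = q.index.name
    out.attrs["provenance"] = q.attrs.get("provenance", PROVENANCE)
    return out


def write_quant_matrix(q: pd.DataFrame, path: str | Path) -> None:
    """Serialize as TSV; missing cells written empty (never 0)."""
    with open(path, "w") as fh:
        fh.write(f"# {q.attrs.get('provenance', PROVENANCE)}\n")
        q.to_csv(fh, sep="\t", na_rep="", float_format="%.10g")


def read_quant_matrix(path: str | Path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    q.attrs["provenance"] = PROVENANCE
    return q
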