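"""Occurrence-threshold overrepresentation analysis over GMT term maps.

Terms (GO categories, KEGG/Reactome/WikiPathways pathways, KEGG BRITE
hierarchy levels) are supplied as GMT files whose members are protein
accessions; a protein group counts as annotated with a term when *any* of its
majority accessions carries it. Before testing, a term must occur in the
tested set at a minimum fraction (10 %, KEGG 5 %) and minimum count (4), and
its tested-set occurrence ratio must exceed the background ratio (twice the
background ratio for the hierarchical BRITE policy). Eligible terms get a
one-sided ("greater") Fisher exact test on the 2x2 occurrence table with BH
correction within the category. The background is the analysis set, not the
whole proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENRICH_COLUMNS = [
    "term_id",
    "term_name",
    "a",
    "b",
    "c",
    "d",
    "ratio_tested",
    "ratio_background",
    "p",
    "q",
]


@dataclass
class ThresholdPolicy:
    """Eligibility thresholds applied before Fisher testing."""

    min_fraction: float = 0.10
    min_count: int = 4
    ratio_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in (0, 1]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.ratio_multiplier < 1:
            raise ValueError("ratio_multiplier must be >= 1")


#: Default policies per annotation category.
GO_POLICY = ThresholdPolicy(0.10, 4, 1.0)
KEGG_POLICY = ThresholdPolicy(0.05, 4, 1.0)
BRITE_POLICY = ThresholdPolicy(0.05, 4, 2.0)


@dataclass
class TermMap:
    """Annotation terms of one category mapped onto protein group ids."""

    category: str
    terms: dict[str, tuple[str, frozenset]] = field(default_factory=dict)

    def members(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


def load_term_map(
    path: str | Path,
    category: str,
    universe: Mapping[object, Iterable[str]],
) -> TermMap:
    """Read a GMT file and map accession members to protein group ids.

    ``universe`` maps each analysis-set protein group id to its majority
    accessions; a group joins a term's member set when any of its accessions
    is listed for the term. Members outside the universe are dropped (terms
    may end up empty but are retained).
    """
    if not universe:
        raise ValueError("empty universe")
    acc_to_groups: dict[str, set] = {}
    for gid, accs in universe.items():
        for acc in accs:
            acc_to_groups.setdefault(acc, set()).add(gid)

    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            term_id, term_name, *members = fields
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            groups: set = set()
            for acc in members:
                groups.update(acc_to_groups.get(acc, ()))
            terms[term_id] = (term_name, frozenset(groups))
    return TermMap(category=category, terms=terms)


def eligible_terms(
    term_map: TermMap,
    tested: set,
    background: set,
    policy: ThresholdPolicy = GO_POLICY,
) -> list[str]:
    """Terms passing the occurrence thresholds in the tested set.

    Keeps a term iff a/|tested| >= min_fraction, a >= min_count and
    a/|tested| > ratio_multiplier * (occurrence in background)/|background|,
    where a is the term's occurrence in the tested set.
    """
    if not tested <= background:
        raise ValueError("tested set must be a subset of the background")
    if not tested:
        return []
    out = []
    for term_id, (_, members) in term_map.terms.items():
        a = len(members & tested)
        bg = len(members & background)
        if a / len(tested) < policy.min_fraction or a < policy.min_count:
            continue
        if a / len(tested) > policy.ratio_multiplier * bg / len(background):
            out.append(term_id)
    return out


def fisher_enrich(
    term_map: TermMap,
    tested: set,
    background: set,
    policy: ThresholdPolicy = GO_POLICY,
    alpha: float = 0.05,
    *,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation tests for the eligible terms.

    The 2x2 table per term is (a, b; c, d) = (tested with term, tested
    without; rest-of-background with term, rest without). BH runs across the
    category's eligible terms; rows are sorted by q then p.
    """
    rows = []
    for term_id in eligible_terms(term_map, tested, background, policy):
        members = term_map.members(term_id)
        rows.append(
            _enrichment_row(
                term_id, term_map.name(term_id), members, tested, background,
                alternative,
            )
        )
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    out.attrs["category"] = term_map.category
    out.attrs["alpha"] = alpha
    return out


def _enrichment_row(term_id, term_name, members, tested, background, alternative):
    a = len(members & tested)
    b = len(tested) - a
    bg_with = len(members & background)
    c = bg_with - a
    d = len(background) - len(tested) - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
    return {
        "term_id": term_id,
        "term_name": term_name,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "ratio_tested": a / len(tested) if tested else 0.0,
        "ratio_background": bg_with / len(background),
        "p": p,
        "q": p,
    }


def keyword_aggregate(
    term_map: TermMap,
    word: str,
    tested: set,
    background: set,
    alpha: float = 0.05,
    *,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher test of the aggregated occurrence of terms naming ``word``.

    Builds a synthetic term whose members are every protein annotated with at
    least one term of the category whose name contains ``word``
    (case-insensitive substring), then runs a single Fisher test (no
    eligibility thresholds; q = p as a one-term family).
    """
    if not word:
        raise ValueError("keyword must be non-empty")
    needle = word.lower()
    members: set = set()
    for _, (name, term_members) in term_map.terms.items():
        if needle in name.lower():
            members |= term_members
    row = _enrichment_row(
        f"KEYWORD:{word}", f"terms containing '{word}'", frozenset(members),
        tested, background, alternative,
    )
    out = pd.DataFrame([row], columns=ENRICH_COLUMNS)
    out.attrs["category"] = term_map.category
    out.attrs["alpha"] = alpha
    return out
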