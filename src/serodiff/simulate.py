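"""Synthetic serum-proteomics studies with known ground truth.

Emulates the study design the pipeline targets: three groups of sizes
24/46/24 (acute poisoning M, survivors S, controls C) with a 10-subject
paired overlap between M and S, peptide-level log-normal LFQ intensities with
abundance-dependent dropout, a subset of proteins carrying group-specific
log2 effects, decoy protein groups exercising the QC filters, and annotation
term maps with planted enriched terms.

Generative model per protein and sample::

    abundance = 2^(baseline + group_effect + subject_effect + noise)
    LFQ(peptide) = abundance * peptide_length * peptide_efficiency
    P(detected)  = logistic(slope * (log2 LFQ - midpoint))

so the pipeline's max(LFQ/length) estimator recovers
``abundance * max(efficiency)`` — abundance up to a protein-specific
constant, which cancels in group-ratio fold changes. Subject effects are
shared between paired M/S samples, creating the within-subject correlation
the paired test exploits. Undetected peptides get LFQ 0 (missing).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_tables

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CONTRASTS = ("M_vs_S", "M_vs_C", "M_vs_SC", "S_vs_C")


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the target study: 24/46/24 samples with 10 paired
    subjects, serum-scale log2 baselines (mean 30 ~ 1e9 intensity units),
    within-group CV 0.3, a 10 % fraction of proteins shifted in the acute
    group by |log2 fold change| 2, and mild abundance-dependent dropout.
    """

    n_proteins: int = 500
    peptides_per_protein: tuple[int, int] = (3, 8)
    peptide_length: tuple[int, int] = (7, 30)
    group_sizes: tuple[int, int, int] = (24, 46, 24)
    n_pairs: int = 10
    baseline_log2_mean: float = 30.0
    baseline_log2_sd: float = 2.0
    subject_sd: float = 0.25
    efficiency_range: tuple[float, float] = (0.2, 1.0)
    cv_within: float = 0.3
    de_fraction_m: float = 0.10
    de_fraction_s: float = 0.05
    effect_log2: float = 2.0
    dropout_midpoint_log2: float = 31.0
    dropout_slope: float = 1.0
    frac_shared_peptides: float = 0.07
    n_decoys_per_kind: int = 2
    n_terms: int = 40
    n_planted_terms: int = 2
    planted_coverage: float = 0.6
    term_background_rate: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 2:
            raise ValueError("every group needs at least 2 samples")
        if not 0 <= self.de_fraction_m < 1 or not 0 <= self.de_fraction_s < 1:
            raise ValueError("de fractions must lie in [0, 1)")
        if self.n_pairs > min(self.group_sizes[0], self.group_sizes[1]):
            raise ValueError("more pairs than M or S samples")
        if self.peptide_length[0] < io_tables.MIN_PEPTIDE_LENGTH:
            raise ValueError("peptide length below the identification minimum")


@dataclass
class GroundTruth:
    """Simulation truth: per-protein effects, DE flags, planted terms."""

    accessions: list[str]
    baseline_log2: list[float]
    effects: dict[str, list[float]]  # group -> per-protein log2 effect
    de_flags: dict[str, list[bool]]  # contrast -> per-protein flag
    planted_terms: list[str]
    subject_ids: dict[str, str]  # sample -> subject
    dropout_midpoint_log2: float
    dropout_slope: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def de_proteins(self, contrast: str) -> list[int]:
        """Protein group ids (1-based) truly changed in a contrast."""
        return [i + 1 for i, f in enumerate(self.de_flags[contrast]) if f]


@dataclass
class StudyData:
    """In-memory simulated study in the exact dialects the readers accept."""

    peptides: pd.DataFrame
    protein_groups: pd.DataFrame
    sample_sheet: pd.DataFrame
    term_maps: dict[str, dict[str, tuple[str, list[str]]]]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": outdir / "peptides.tsv",
            "protein_groups": outdir / "proteinGroups.tsv",
            "samples": outdir / "samples.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        io_tables.write_peptide_table(self.peptides, paths["peptides"])
        io_tables.write_protein_groups(self.protein_groups, paths["protein_groups"])
        self.sample_sheet.to_csv(paths["samples"], sep="\t", index=False, na_rep="")
        self.truth.to_json(paths["ground_truth"])
        for category, terms in self.term_maps.items():
            p = outdir / f"terms_{category}.gmt"
            with open(p, "w") as fh:
                for term_id, (name, members) in terms.items():
                    fh.write("\t".join([term_id, name, *members]) + "\n")
            paths[f"terms_{category}"] = p
        return paths


def _sample_sheet(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    n_m, n_s, n_c = cfg.group_sizes
    rows, subjects = [], {}
    for i in range(n_m):
        sid = f"M{i + 1:02d}"
        pid = f"P{i + 1:02d}" if i < cfg.n_pairs else None
        subjects[sid] = f"subj_M{i + 1:02d}"
        rows.append((sid, "M", pid))
    for i in range(n_s):
        sid = f"S{i + 1:02d}"
        pid = f"P{i + 1:02d}" if i < cfg.n_pairs else None
        # paired follow-up samples re-use the acute subject
        subjects[sid] = f"subj_M{i + 1:02d}" if i < cfg.n_pairs else f"subj_S{i + 1:02d}"
        rows.append((sid, "S", pid))
    for i in range(n_c):
        sid = f"C{i + 1:02d}"
        subjects[sid] = f"subj_C{i + 1:02d}"
        rows.append((sid, "C", None))
    sheet = pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"])
    return sheet, subjects


def _group_effects(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-group log2 effect vectors; M- and S-affected protein sets disjoint."""
    n = cfg.n_proteins
    effects = {g: np.zeros(n) for g in ("M", "S", "C")}
    n_m = round(cfg.de_fraction_m * n)
    n_s = round(cfg.de_fraction_s * n)
    chosen = rng.choice(n, size=n_m + n_s, replace=False)
    m_idx, s_idx = chosen[:n_m], chosen[n_m:]
    effects["M"][m_idx] = cfg.effect_log2 * rng.choice([-1.0, 1.0], size=n_m)
    effects["S"][s_idx] = cfg.effect_log2 * rng.choice([-1.0, 1.0], size=n_s)
    return effects


def _de_flags(effects: dict[str, np.ndarray]) -> dict[str, list[bool]]:
    e_m, e_s, e_c = effects["M"], effects["S"], effects["C"]
    return {
        "M_vs_S": (e_m != e_s).tolist(),
        "M_vs_C": (e_m != e_c).tolist(),
        "M_vs_SC": ((e_m != e_s) | (e_m != e_c)).tolist(),
        "S_vs_C": (e_s != e_c).tolist(),
    }


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    seqs, seen = [], set()
    for ln in lengths:
        while True:
            s = "".join(rng.choice(AMINO_ACIDS, size=int(ln)))
            if s not in seen:
                seen.add(s)
                seqs.append(s)
                break
    return seqs


def simulate_study(cfg: SimConfig) -> StudyData:
    """Generate a complete study (peptides, groups, sheet, terms, truth)."""
    rng = np.random.default_rng(cfg.seed)
    sheet, subjects = _sample_sheet(cfg)
    sample_ids = sheet["sample_id"].tolist()
    sample_groups = sheet["group"].tolist()
    n_samples = len(sample_ids)
    n_prot = cfg.n_proteins

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_prot)
    effects = _group_effects(cfg, rng)

    # per-(subject, protein) baseline deviations: shared between the paired
    # acute/follow-up samples of a subject, independent across proteins
    subj_names = sorted(set(subjects.values()))
    subj_effect = {
        name: rng.normal(0.0, cfg.subject_sd, n_prot) for name in subj_names
    }
    # log-normal multiplicative noise with the requested within-group CV
    noise_sd_log2 = np.sqrt(np.log1p(cfg.cv_within**2)) / np.log(2)

    log2_abund = np.empty((n_prot, n_samples))
    for j, (sid, grp) in enumerate(zip(sample_ids, sample_groups)):
        log2_abund[:, j] = (
            baseline
            + effects[grp]
            + subj_effect[subjects[sid]]
            + rng.normal(0.0, noise_sd_log2, n_prot)
        )
    abundance = 2.0**log2_abund

    # peptide layout
    lo, hi = cfg.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, n_prot)
    prot_of_pep = np.repeat(np.arange(n_prot), n_pep)
    total = int(n_pep.sum())
    lengths = rng.integers(cfg.peptide_length[0], cfg.peptide_length[1] + 1, total)
    eff = rng.uniform(*cfg.efficiency_range, total)
    shared = rng.random(total) < cfg.frac_shared_peptides
    # every protein keeps at least one unique peptide
    first_pep = np.concatenate(([0], np.cumsum(n_pep)[:-1]))
    shared[first_pep] = False

    lfq = abundance[prot_of_pep] * (lengths * eff)[:, None]
    with np.errstate(divide="ignore"):
        logit = cfg.dropout_slope * (np.log2(lfq) - cfg.dropout_midpoint_log2)
    p_detect = 1.0 / (1.0 + np.exp(-logit))
    detected = rng.random(lfq.shape) < p_detect
    lfq = np.where(detected, lfq, 0.0)

    peptides = pd.DataFrame(
        {
            "sequence": _random_sequences(rng, lengths),
            "length": lengths.astype(int),
            "protein_group_id": prot_of_pep + 1,
            "is_unique": ~shared,
        }
    )
    for j, sid in enumerate(sample_ids):
        peptides[sid] = lfq[:, j]

    accessions = [f"P{i + 1:05d}" for i in range(n_prot)]
    pg_rows = [
        {
            "group_id": i + 1,
            "majority_ids": [accessions[i]],
            "only_by_site": False,
            "reverse": False,
            "contaminant": False,
            "n_unique_peptides": int((~shared[prot_of_pep == i]).sum()),
            "all_ids_contaminant": False,
        }
        for i in range(n_prot)
    ]
    pg_rows, peptides = _add_decoys(cfg, rng, pg_rows, peptides, sample_ids)
    protein_groups = pd.DataFrame(pg_rows)

    planted, term_maps = _term_maps(cfg, rng, accessions, effects)

    truth = GroundTruth(
        accessions=accessions,
        baseline_log2=baseline.tolist(),
        effects={g: e.tolist() for g, e in effects.items()},
        de_flags=_de_flags(effects),
        planted_terms=planted,
        subject_ids=subjects,
        dropout_midpoint_log2=cfg.dropout_midpoint_log2,
        dropout_slope=cfg.dropout_slope,
        seed=cfg.seed,
    )
    return StudyData(peptides, protein_groups, sheet, term_maps, truth)


def _add_decoys(cfg, rng, pg_rows, peptides, sample_ids):
    """Append reverse / pure-contaminant / only-by-site / no-unique groups."""
    next_id = len(pg_rows) + 1
    kinds = (
        [("reverse", True, False, False)] * cfg.n_decoys_per_kind
        + [("contaminant", False, True, False)] * cfg.n_decoys_per_kind
        + [("only_by_site", False, False, True)] * cfg.n_decoys_per_kind
        + [("no_unique", False, False, False)]
    )
    extra = []
    for kind, rev, con, obs in kinds:
        acc = f"{'CON__' if con else 'REV__' if rev else ''}DEC{next_id:04d}"
        no_unique = kind == "no_unique"
        pg_rows.append(
            {
                "group_id": next_id,
                "majority_ids": [acc],
                "only_by_site": obs,
                "reverse": rev,
                "contaminant": con,
                "n_unique_peptides": 0 if no_unique else 1,
                "all_ids_contaminant": con,
            }
        )
        ln = int(rng.integers(*cfg.peptide_length))
        row = {
            "sequence": "".join(rng.choice(AMINO_ACIDS, size=ln)),
            "length": ln,
            "protein_group_id": next_id,
            "is_unique": not no_unique,
        }
        for sid in sample_ids:
            row[sid] = float(np.round(rng.uniform(1e4, 1e6), 2))
        extra.append(row)
        next_id += 1
    peptides = pd.concat([peptides, pd.DataFrame(extra)], ignore_index=True)
    return pg_rows, peptides


def _term_maps(cfg, rng, accessions, effects):
    """One GO-style category with planted terms biased toward M-shifted proteins."""
    n = len(accessions)
    m_de = np.flatnonzero(effects["M"] != 0)
    terms: dict[str, tuple[str, list[str]]] = {}
    planted = []
    for t in range(cfg.n_planted_terms):
        term_id = f"GO:{9000000 + t}"
        members = [
            accessions[i] for i in m_de if rng.random() < cfg.planted_coverage
        ] + [
            accessions[i]
            for i in range(n)
            if effects["M"][i] == 0 and rng.random() < cfg.term_background_rate
        ]
        terms[term_id] = (f"planted blood coagulation cascade {t}", sorted(members))
        planted.append(term_id)
    for t in range(cfg.n_terms - cfg.n_planted_terms):
        term_id = f"GO:{1000000 + t}"
        rate = rng.uniform(0.03, 0.15)
        members = [accessions[i] for i in range(n) if rng.random() < rate]
        terms[term_id] = (f"background process term {t}", sorted(members))
    return planted, {"GO_BP": terms}


def simulate_null(cfg: SimConfig) -> StudyData:
    """Same generator with every effect zeroed and no planted terms."""
    null_cfg = dataclasses.replace(
        cfg, de_fraction_m=0.0, de_fraction_s=0.0, n_planted_terms=0
    )
    return simulate_study(null_cfg)
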