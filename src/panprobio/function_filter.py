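"""Database-specific annotation-hit filtering and functional comparisons.

Homology-search hit tables (BLAST outfmt-6-like) against four databases are
filtered with database-specific rules before any counting:

* KEGG:        query coverage >= 50%
* ARDB:        query AND subject coverage >= 40%, identity strictly above the
               per-gene ARDB-recommended identity threshold
* VFDB, CAZy:  query coverage >= 50% and identity >= 60%

Coverage is alignment length over the corresponding sequence length. After
filtering, one best hit is kept per query per database (highest identity,
ties by subject id). Two downstream comparisons are provided: per-species
feature-enrichment counts (how many other species are significantly weaker
in a feature) and the friendly/unfriendly risk-gene burden test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, ranksum

__all__ = [
    "DATABASES",
    "filter_hits",
    "feature_matrix",
    "feature_enrichment_matrix",
    "risk_burden_compare",
    "RiskBurdenResult",
    "species_feature_presence",
]

DATABASES = ("KEGG", "ARDB", "VFDB", "CAZy")

HIT_COLUMNS = ["query_id", "subject_id", "database", "identity_pct",
               "query_len", "subject_len", "align_len"]


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table is missing columns: {missing}")
    bad_db = set(hits["database"]) - set(DATABASES)
    if bad_db:
        raise ValueError(f"unknown databases in hit table: {sorted(bad_db)}")
    if (hits[["query_len", "subject_len", "align_len"]] <= 0).any().any():
        raise ValueError("lengths must be positive")
    if ((hits["identity_pct"] < 0) | (hits["identity_pct"] > 100)).any():
        raise ValueError("identity must lie in [0, 100]")
    return hits


def _hit_accepted(row) -> bool:
    qcov = row["align_len"] / row["query_len"]
    db = row["database"]
    if db == "KEGG":
        return qcov >= 0.5
    if db == "ARDB":
        thr = row.get("subject_threshold_pct", np.nan)
        if pd.isna(thr):
            warnings.warn(
                f"ARDB hit {row['query_id']}->{row['subject_id']} lacks a "
                "recommended identity threshold; rejected", stacklevel=2)
            return False
        scov = row["align_len"] / row["subject_len"]
        return qcov >= 0.4 and scov >= 0.4 and row["identity_pct"] > thr
    # VFDB and CAZy share one rule
    return qcov >= 0.5 and row["identity_pct"] >= 60.0


def filter_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Apply the database-specific acceptance rules and keep one best hit
    per (query, database): highest identity, ties broken by subject id."""
    hits = _validate_hits(hits)
    accepted = hits[hits.apply(_hit_accepted, axis=1)].copy()
    if accepted.empty:
        return accepted
    accepted = accepted.sort_values(
        ["query_id", "database", "identity_pct", "subject_id"],
        ascending=[True, True, False, True])
    return accepted.drop_duplicates(["query_id", "database"], keep="first"
                                    ).reset_index(drop=True)


def feature_matrix(accepted: pd.DataFrame, genome_of: dict[str, str],
                   feature_col: str = "subject_id") -> pd.DataFrame:
    """Genome-by-feature count matrix from accepted annotations.

    ``genome_of`` maps query (gene) ids to genome ids; ``feature_col`` names
    the column holding the feature identifier (subject id by default, or a
    mapped KO/pathway/family column added by the caller)."""
    df = accepted.copy()
    df["genome_id"] = df["query_id"].map(genome_of)
    if df["genome_id"].isna().any():
        raise ValueError("some query ids have no genome mapping")
    return (df.groupby(["genome_id", feature_col]).size().unstack(fill_value=0)
            .astype(int))


def feature_enrichment_matrix(features: pd.DataFrame, species: pd.Series,
                              q_threshold: float = 0.05,
                              correction: str = "joint") -> pd.DataFrame:
    """Per-species, per-feature count of other species significantly weaker.

    For each feature and unordered species pair, an unpaired rank-sum test
    compares the two species' per-strain counts; q-values are BH-corrected
    across all tests of the analysis (``correction="joint"``) or within each
    feature (``"per_feature"``). Cell (s, f) counts species t with q below
    the threshold and s's strains holding the higher mean rank, so a cell
    can be at most (number of species - 1).
    """
    if correction not in ("joint", "per_feature"):
        raise ValueError("correction must be 'joint' or 'per_feature'")
    species = species.reindex(features.index)
    if species.isna().any():
        raise ValueError("every genome row needs a species label")
    sp_list = sorted(species.unique())
    groups = {s: features.loc[species == s] for s in sp_list}
    for s, g in groups.items():
        if len(g) == 1:
            warnings.warn(f"species {s!r} has a single strain; tests are "
                          "low-powered", stacklevel=2)

    tests = []  # (feature, s, t, p, winner)
    for feat in features.columns:
        for s, t in itertools.combinations(sp_list, 2):
            res = ranksum(groups[s][feat].to_numpy(), groups[t][feat].to_numpy())
            winner = {"x": s, "y": t, None: None}[res.direction]
            tests.append((feat, s, t, res.p, winner))
    result = pd.DataFrame(0, index=sp_list, columns=features.columns, dtype=int)
    if not tests:
        return result
    df = pd.DataFrame(tests, columns=["feature", "s", "t", "p", "winner"])
    if correction == "joint":
        df["q"] = bh_fdr(df["p"])
    else:
        df["q"] = np.nan
        for feat, idx in df.groupby("feature").groups.items():
            df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"])
    hits = df[(df["q"] < q_threshold) & df["winner"].notna()]
    for _, row in hits.iterrows():
        result.loc[row["winner"], row["feature"]] += 1
    return result


@dataclass(frozen=True)
class RiskBurdenResult:
    p: float
    direction: str | None  # group with the higher mean rank
    stars: str  # "" / "*" (p<0.05) / "**" (p<0.01)
    mean_friendly: float
    mean_unfriendly: float


def risk_burden_compare(risk_counts: pd.Series, friendliness: pd.Series
                        ) -> RiskBurdenResult:
    """Compare per-genome risk-gene counts (virulence + antibiotic
    resistance) between friendly- and unfriendly-source strains with an
    unpaired two-sided rank-sum test."""
    friendliness = friendliness.reindex(risk_counts.index)
    friendly = risk_counts[friendliness == "friendly"].to_numpy(dtype=float)
    unfriendly = risk_counts[friendliness == "unfriendly"].to_numpy(dtype=float)
    if friendly.size == 0 or unfriendly.size == 0:
        raise ValueError("both friendliness groups must be non-empty")
    res = ranksum(friendly, unfriendly)
    direction = {"x": "friendly", "y": "unfriendly", None: None}[res.direction]
    stars = "**" if res.p < 0.01 else "*" if res.p < 0.05 else ""
    return RiskBurdenResult(res.p, direction, stars,
                            float(friendly.mean()), float(unfriendly.mean()))


def species_feature_presence(accepted: pd.DataFrame, genome_of: dict[str, str],
                             species_of: dict[str, str],
                             feature_col: str = "subject_id") -> pd.DataFrame:
    """Presence/absence summary: which species carry each feature in at
    least one strain; a feature present in exactly one species is
    species-specific."""
    fm = feature_matrix(accepted, genome_of, feature_col)
    species = pd.Series({g: species_of[g] for g in fm.index})
    present = (fm > 0).groupby(species).any()
    rows = []
    for feat in present.columns:
        carriers = sorted(present.index[present[feat]])
        rows.append({"feature": feat, "species": ";".join(carriers),
                     "n_species": len(carriers),
                     "specific": len(carriers) == 1})
    return pd.DataFrame(rows, columns=["feature", "species", "n_species", "specific"])
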