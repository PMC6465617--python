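"""KEGG-module integrity and cross-species functional complementarity.

Module integrity for one genome is the fraction of a module's key/essential
KOs present in that genome's KO set. For a pair of genomes, the two KO sets
are merged and the summed integrity over all modules is compared with the
better single genome:

    improvement_ratio = (T(A u B) - max(T(A), T(B))) / max(T(A), T(B))

where T(G) is the sum of module integrities of genome G. Merging can only
add KOs, so T(merged) >= max(T(A), T(B)) and the ratio is non-negative.
Ratios are computed for every unordered pair of strains from different
species and summarised per species pair (mean, descending rank, tercile).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import pearson

__all__ = [
    "ModuleDefinition",
    "KOProfile",
    "PairComplementarity",
    "module_integrity",
    "total_integrity",
    "pair_complementarity",
    "enumerate_cross_species_pairs",
    "cross_species_pair_count",
    "all_pair_complementarities",
    "species_pair_summary",
    "complementarity_ani_correlation",
]


@dataclass(frozen=True)
class ModuleDefinition:
    """One functional module and its key/essential KO set."""

    module_id: str
    required_kos: frozenset[str]

    def __post_init__(self):
        if not self.required_kos:
            raise ValueError(f"module {self.module_id!r} has no required KOs")


@dataclass
class KOProfile:
    """Per-genome set of KEGG Orthology identifiers."""

    genome_id: str
    species_label: str
    kos: set[str] = field(default_factory=set)


def module_integrity(kos: set[str], module: ModuleDefinition) -> float:
    """Fraction of the module's required KOs present in ``kos``."""
    return len(module.required_kos & set(kos)) / len(module.required_kos)


def total_integrity(kos: set[str], modules) -> float:
    """Summed integrity over all modules."""
    return sum(module_integrity(kos, m) for m in modules)


@dataclass(frozen=True)
class PairComplementarity:
    genome_a: str
    genome_b: str
    total_integrity_a: float
    total_integrity_b: float
    total_integrity_merged: float
    improvement_ratio: float  # math.inf when the baseline is 0 but merged > 0
    infinite: bool = False


def pair_complementarity(a: KOProfile, b: KOProfile, modules,
                         baseline: str = "max") -> PairComplementarity:
    """Complementarity improvement of merging two genomes' KO sets.

    ``baseline`` is the denominator of the improvement: ``"max"`` (default,
    gain over the better single genome) or ``"mean"`` (gain over the average
    of the two). A pair whose baseline is 0 while the merged total is
    positive is flagged infinite and must be reported separately.
    """
    if not modules:
        raise ValueError("modules must be non-empty")
    if baseline not in ("max", "mean"):
        raise ValueError("baseline must be 'max' or 'mean'")
    t_a = total_integrity(a.kos, modules)
    t_b = total_integrity(b.kos, modules)
    t_m = total_integrity(a.kos | b.kos, modules)
    base = max(t_a, t_b) if baseline == "max" else (t_a + t_b) / 2.0
    if base == 0.0:
        ratio, infinite = (0.0, False) if t_m == 0.0 else (math.inf, True)
    else:
        ratio, infinite = (t_m - base) / base, False
    return PairComplementarity(a.genome_id, b.genome_id, t_a, t_b, t_m, ratio, infinite)


def enumerate_cross_species_pairs(strains_by_species: dict[str, list[str]]
                                  ) -> list[tuple[str, str]]:
    """All unordered strain pairs whose members belong to different species."""
    species = sorted(strains_by_species)
    pairs = []
    for sa, sb in itertools.combinations(species, 2):
        for a in sorted(strains_by_species[sa]):
            for b in sorted(strains_by_species[sb]):
                pairs.append((a, b))
    return pairs


def cross_species_pair_count(sizes) -> int:
    """Closed-form count: C(N, 2) - sum_s C(n_s, 2)."""
    sizes = list(sizes)
    n = sum(sizes)
    return math.comb(n, 2) - sum(math.comb(s, 2) for s in sizes)


def all_pair_complementarities(profiles: dict[str, KOProfile], modules,
                               baseline: str = "max") -> pd.DataFrame:
    """Improvement ratios for every cross-species strain pair.

    Columns: a, b, species_a, species_b, T_a, T_b, T_merged, ratio, infinite.
    """
    by_species: dict[str, list[str]] = {}
    for gid, prof in profiles.items():
        by_species.setdefault(prof.species_label, []).append(gid)
    rows = []
    for a, b in enumerate_cross_species_pairs(by_species):
        pc = pair_complementarity(profiles[a], profiles[b], modules, baseline)
        rows.append({
            "a": a, "b": b,
            "species_a": profiles[a].species_label,
            "species_b": profiles[b].species_label,
            "T_a": pc.total_integrity_a, "T_b": pc.total_integrity_b,
            "T_merged": pc.total_integrity_merged,
            "ratio": pc.improvement_ratio, "infinite": pc.infinite,
        })
    return pd.DataFrame(rows, columns=["a", "b", "species_a", "species_b",
                                       "T_a", "T_b", "T_merged", "ratio", "infinite"])


def species_pair_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean improvement ratio per species pair with descending rank and
    tercile group (top / middle / bottom third of ranks).

    Infinite-ratio strain pairs are excluded from the means (they are
    reported separately by :func:`all_pair_complementarities`).
    """
    finite = pairs[~pairs["infinite"]].copy()
    key = finite.apply(
        lambda r: " | ".join(sorted([r["species_a"], r["species_b"]])), axis=1)
    finite["species_pair"] = key
    summary = (finite.groupby("species_pair")["ratio"].agg(["mean", "count"])
               .rename(columns={"mean": "mean_ratio", "count": "n_strain_pairs"})
               .reset_index())
    summary = summary.sort_values(["mean_ratio", "species_pair"],
                                  ascending=[False, True], ignore_index=True)
    p = len(summary)
    summary["rank"] = np.arange(1, p + 1)
    top = math.ceil(p / 3)
    mid = math.ceil(2 * p / 3)
    summary["tercile"] = ["top" if r <= top else "middle" if r <= mid else "bottom"
                          for r in summary["rank"]]
    return summary


def complementarity_ani_correlation(species_pair_means: dict[str, float],
                                    species_pair_ani: dict[str, float]
                                    ) -> tuple[float, float]:
    """Pearson correlation between per-species-pair mean complementarity and
    ANI (a negative sign means more distant pairs complement more)."""
    keys = sorted(set(species_pair_means) & set(species_pair_ani))
    if len(keys) < 3:
        raise ValueError("need at least 3 shared species pairs")
    x = [species_pair_ani[k] for k in keys]
    y = [species_pair_means[k] for k in keys]
    return pearson(x, y)
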