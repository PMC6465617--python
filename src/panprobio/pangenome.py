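"""Pan-genome construction and the pan-genome index (PI).

Gene families are built by greedy incremental clustering of protein
sequences (longest first): a sequence joins the first existing family whose
representative it matches at >= 95% identity over >= 90% of the shorter
sequence, otherwise it founds a new family. Families present in every genome
are core, in exactly one genome strain-specific, otherwise accessory.

The pan-genome index quantifies openness as

    PI = pan-genome family count / mean per-genome family count

so identical genomes give PI = 1 and a more open accessory repertoire gives
a larger PI. Openness levels: A ("relatively conserved") PI <= 1.5,
B ("half-open") 1.5 < PI <= 3, C ("relatively open") PI > 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._align import pair_stats
from .stats import pearson

__all__ = [
    "GeneFamily",
    "PanGenome",
    "PanIndex",
    "cluster_gene_families",
    "build_pangenome",
    "partition_families",
    "rarefaction_curves",
    "pan_genome_index",
    "openness_correlates",
]

PREFILTER_K = 5  # amino-acid k-mer length for the candidate prefilter


@dataclass
class GeneFamily:
    family_id: str
    representative: tuple[str, str]  # (genome_id, gene_id)
    representative_seq: str
    members: list[tuple[str, str]] = field(default_factory=list)


def meets_family_thresholds(seq: str, representative: str,
                            identity: float = 0.95, coverage: float = 0.90) -> bool:
    """True if ``seq`` matches ``representative`` at >= ``identity`` over an
    aligned region covering >= ``coverage`` of the shorter sequence."""
    st = pair_stats(seq, representative, mode="local")
    return st.identity_fraction >= identity and st.shorter_coverage >= coverage


def cluster_gene_families(proteins: dict[str, dict[str, str]],
                          identity: float = 0.95, coverage: float = 0.90,
                          prefilter: bool = True) -> list[GeneFamily]:
    """Greedy incremental protein-family clustering.

    ``proteins`` maps genome_id -> gene_id -> amino-acid sequence. Sequences
    are processed longest first (length ties broken lexicographically by
    (genome_id, gene_id)); each joins the first family, in founding order,
    whose representative meets both thresholds. A shared-k-mer prefilter
    skips representatives that cannot plausibly match; disable it to force
    alignment against every representative.
    """
    items = [
        (genome, gene, seq)
        for genome in proteins
        for gene, seq in proteins[genome].items()
    ]
    if not items:
        raise ValueError("no protein sequences to cluster")
    items.sort(key=lambda t: (-len(t[2]), t[0], t[1]))

    families: list[GeneFamily] = []
    kmer_index: dict[str, set[int]] = {}

    def candidates(seq: str):
        if not prefilter:
            return range(len(families))
        hits: set[int] = set()
        for off in range(len(seq) - PREFILTER_K + 1):
            hits |= kmer_index.get(seq[off : off + PREFILTER_K], set())
        return sorted(hits)

    for genome, gene, seq in items:
        placed = False
        for fi in candidates(seq):
            if meets_family_thresholds(seq, families[fi].representative_seq,
                                       identity, coverage):
                families[fi].members.append((genome, gene))
                placed = True
                break
        if not placed:
            fi = len(families)
            fam = GeneFamily(
                family_id=f"F{fi:05d}",
                representative=(genome, gene),
                representative_seq=seq,
                members=[(genome, gene)],
            )
            families.append(fam)
            for off in range(len(seq) - PREFILTER_K + 1):
                kmer_index.setdefault(seq[off : off + PREFILTER_K], set()).add(fi)
    return families


@dataclass
class PanGenome:
    """Gene families plus the genome-by-family presence table."""

    families: list[GeneFamily]
    membership: pd.DataFrame  # genomes x family_ids, bool
    gene_counts: dict[str, int]  # raw gene count per genome

    @property
    def n_genomes(self) -> int:
        return self.membership.shape[0]

    @property
    def family_sets(self) -> dict[str, set[str]]:
        return {
            g: set(self.membership.columns[self.membership.loc[g].to_numpy()])
            for g in self.membership.index
        }

    @property
    def core_ids(self) -> list[str]:
        return partition_families(self)[0]

    @property
    def accessory_ids(self) -> list[str]:
        return partition_families(self)[1]

    @property
    def specific_ids(self) -> list[str]:
        return partition_families(self)[2]


def build_pangenome(families: list[GeneFamily] | None = None,
                    proteins: dict[str, dict[str, str]] | None = None,
                    family_sets: dict[str, set[str]] | None = None) -> PanGenome:
    """Assemble a :class:`PanGenome` from clustered families (clustering
    ``proteins`` first if needed) or directly from per-genome family sets."""
    if family_sets is not None:
        genomes = sorted(family_sets)
        fam_ids = sorted(set().union(*family_sets.values())) if genomes else []
        membership = pd.DataFrame(
            [[f in family_sets[g] for f in fam_ids] for g in genomes],
            index=genomes, columns=fam_ids, dtype=bool,
        )
        gene_counts = {g: len(family_sets[g]) for g in genomes}
        return PanGenome([], membership, gene_counts)
    if families is None:
        if proteins is None:
            raise ValueError("provide families, proteins or family_sets")
        families = cluster_gene_families(proteins)
    genomes = sorted({g for fam in families for g, _ in fam.members})
    fam_ids = [fam.family_id for fam in families]
    membership = pd.DataFrame(False, index=genomes, columns=fam_ids, dtype=bool)
    gene_counts = {g: 0 for g in genomes}
    for fam in families:
        for genome, _gene in fam.members:
            membership.loc[genome, fam.family_id] = True
            gene_counts[genome] += 1
    return PanGenome(families, membership, gene_counts)


def partition_families(pan: PanGenome) -> tuple[list[str], list[str], list[str]]:
    """(core, accessory, strain-specific) family ids: core in all genomes,
    specific in exactly one, accessory in between."""
    counts = pan.membership.sum(axis=0)
    n = pan.n_genomes
    core = [f for f in pan.membership.columns if counts[f] == n]
    specific = [f for f in pan.membership.columns if counts[f] == 1 and n > 1]
    accessory = [f for f in pan.membership.columns
                 if f not in set(core) and f not in set(specific)]
    return core, accessory, specific


def rarefaction_curves(pan: PanGenome, n_permutations: int = 100,
                       seed: int = 0) -> pd.DataFrame:
    """Mean pan (union) and core (intersection) family counts as genomes are
    added in random order; columns k, pan_mean, core_mean."""
    genomes = list(pan.membership.index)
    if len(genomes) < 2:
        raise ValueError("rarefaction requires at least 2 genomes")
    sets = pan.family_sets
    rng = np.random.default_rng(seed)
    n = len(genomes)
    pan_sizes = np.zeros((n_permutations, n))
    core_sizes = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        union: set[str] = set()
        inter: set[str] | None = None
        for k, gi in enumerate(order):
            s = sets[genomes[gi]]
            union |= s
            inter = set(s) if inter is None else inter & s
            pan_sizes[p, k] = len(union)
            core_sizes[p, k] = len(inter)
    return pd.DataFrame({
        "k": np.arange(1, n + 1),
        "pan_mean": pan_sizes.mean(axis=0),
        "core_mean": core_sizes.mean(axis=0),
    })


@dataclass(frozen=True)
class PanIndex:
    pi: float
    level: str  # A (<=1.5), B (1.5, 3], C (>3)
    mean_genes_per_genome: float
    pan_family_count: int


def _pi_level(pi: float) -> str:
    if pi <= 1.5:
        return "A"
    if pi <= 3.0:
        return "B"
    return "C"


def pan_genome_index(pan: PanGenome, count_mode: str = "families") -> PanIndex:
    """Pan-genome index: pan family count over mean per-genome count.

    ``count_mode`` selects the per-genome denominator: distinct families
    (default) or raw gene counts (``"genes"``, which counts in-paralogs
    separately).
    """
    per_genome = pan.membership.sum(axis=1).astype(float)
    if (per_genome == 0).any():
        raise ValueError("every genome must carry at least one gene family")
    if count_mode == "families":
        mean_genes = float(per_genome.mean())
    elif count_mode == "genes":
        mean_genes = float(np.mean([pan.gene_counts[g] for g in pan.membership.index]))
    else:
        raise ValueError("count_mode must be 'families' or 'genes'")
    pan_count = int(pan.membership.any(axis=0).sum())
    pi = pan_count / mean_genes
    return PanIndex(pi, _pi_level(pi), mean_genes, pan_count)


def openness_correlates(pi_by_species: dict[str, float],
                        source_counts: dict[str, float],
                        genome_counts: dict[str, float],
                        aai_sds: dict[str, float]) -> dict:
    """Correlate PI with candidate openness drivers.

    Per factor: Pearson correlation coefficient, R^2 and p. Combined:
    ordinary least squares of PI on all non-constant factors, reporting the
    model R^2 and overall F-test p-value. Constant factors are flagged and
    excluded from the combined fit.
    """
    species = sorted(pi_by_species)
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    y = np.array([pi_by_species[s] for s in species], dtype=float)
    factors = {
        "source_count": np.array([source_counts[s] for s in species], dtype=float),
        "genome_count": np.array([genome_counts[s] for s in species], dtype=float),
        "aai_sd": np.array([aai_sds[s] for s in species], dtype=float),
    }
    per_factor = {}
    usable = {}
    for name, x in factors.items():
        if np.all(x == x[0]):
            per_factor[name] = {"cc": float("nan"), "r2": float("nan"),
                                "p": float("nan"), "constant": True}
            continue
        cc, p = pearson(x, y)
        per_factor[name] = {"cc": cc, "r2": cc ** 2, "p": p, "constant": False}
        usable[name] = x
    combined = {"r2": float("nan"), "p": float("nan"), "factors": sorted(usable)}
    if usable:
        X = sm.add_constant(np.column_stack([usable[n] for n in sorted(usable)]))
        fit = sm.OLS(y, X).fit()
        combined["r2"] = float(fit.rsquared)
        combined["p"] = float(fit.f_pvalue)
    return {"per_factor": per_factor, "combined": combined}
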