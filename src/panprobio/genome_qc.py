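"""Three-stage genome quality control.

Stage 1 applies the Human Microbiome Project's five high-quality draft
criteria to assembly statistics. Stage 2 gates on CheckM-style completeness
and contamination values (consumed as numbers; CheckM itself is not run).
Stage 3 removes genomes whose intra-species average nucleotide identity (ANI)
to the rest of their species falls at or below a purity threshold, which
flags genomes mis-assigned to the species.

All thresholds are strict inequalities except the contig-fraction criterion,
which is ">= 0.98"; boundary behaviour is deliberate and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "AssemblyStats",
    "GenomeRecord",
    "Friendliness",
    "HMPReport",
    "n50",
    "hmp_draft_pass",
    "checkm_gate",
    "intra_species_purity_filter",
    "classify_isolation_source",
    "DEFAULT_FRIENDLY_KEYWORDS",
    "DEFAULT_UNFRIENDLY_KEYWORDS",
]


class Friendliness(str, Enum):
    FRIENDLY = "friendly"
    UNFRIENDLY = "unfriendly"
    UNKNOWN = "unknown"


# Keyword tables for classifying isolation sources. "Friendly" sources are
# foods and the healthy human gut; "unfriendly" sources are clinical
# specimens and harsh environments. Both tables are configurable inputs.
DEFAULT_FRIENDLY_KEYWORDS: tuple[str, ...] = (
    "milk", "cheese", "yogurt", "yoghurt", "beer", "human gut", "food",
    "dairy", "infant feces", "fermented",
)
DEFAULT_UNFRIENDLY_KEYWORDS: tuple[str, ...] = (
    "patient", "soil", "blood", "saliva", "silage", "specimen", "abscess",
    "wound", "sewage",
)


def classify_isolation_source(
    source: str | None,
    friendly_keywords=DEFAULT_FRIENDLY_KEYWORDS,
    unfriendly_keywords=DEFAULT_UNFRIENDLY_KEYWORDS,
) -> Friendliness:
    """Map a free-text isolation source to a friendliness class.

    Unfriendly keywords take precedence (a "patient's milk specimen" is
    clinical); unmatched or missing sources are ``unknown``.
    """
    if not source:
        return Friendliness.UNKNOWN
    s = source.lower()
    if any(k in s for k in unfriendly_keywords):
        return Friendliness.UNFRIENDLY
    if any(k in s for k in friendly_keywords):
        return Friendliness.FRIENDLY
    return Friendliness.UNKNOWN


@dataclass
class AssemblyStats:
    """Assembly metrics feeding the five HMP draft-quality criteria."""

    total_length: int
    contig_lengths: list[int]
    scaffold_n50: int
    contig_n50: int
    mean_contig_length: float
    frac_in_long_contigs: float  # fraction of assembly in contigs > 500 bp
    core_gene_fraction: float  # fraction of reference core-gene set detected

    def __post_init__(self):
        if self.total_length <= 0 or not self.contig_lengths:
            raise ValueError("assembly must have positive length and contigs")
        if any(c <= 0 for c in self.contig_lengths):
            raise ValueError("contig lengths must be positive")
        for name in ("frac_in_long_contigs", "core_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.contig_n50 > max(self.contig_lengths):
            raise ValueError("contig N50 cannot exceed the longest contig")

    @classmethod
    def from_contigs(cls, contig_lengths, scaffold_n50=None,
                     frac_in_long_contigs=None, core_gene_fraction=1.0):
        """Build stats directly from contig lengths (scaffold N50 defaults to
        contig N50 for unscaffolded assemblies)."""
        contig_lengths = list(contig_lengths)
        total = sum(contig_lengths)
        cn50 = n50(contig_lengths)
        if frac_in_long_contigs is None:
            frac_in_long_contigs = sum(c for c in contig_lengths if c > 500) / total
        return cls(
            total_length=total,
            contig_lengths=contig_lengths,
            scaffold_n50=scaffold_n50 if scaffold_n50 is not None else cn50,
            contig_n50=cn50,
            mean_contig_length=total / len(contig_lengths),
            frac_in_long_contigs=frac_in_long_contigs,
            core_gene_fraction=core_gene_fraction,
        )


@dataclass
class GenomeRecord:
    """One strain: identity, assembly, QC numbers and sequence sets."""

    genome_id: str
    species_label: str
    assembly: AssemblyStats | None = None
    completeness_pct: float = float("nan")
    contamination_pct: float = float("nan")
    isolation_source: str = ""
    friendliness: Friendliness = Friendliness.UNKNOWN
    genes_nt: dict[str, str] = field(default_factory=dict)
    proteins_aa: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_metadata(cls, genome_id, species_label, isolation_source="",
                      completeness_pct=float("nan"), contamination_pct=float("nan"),
                      **kw):
        return cls(
            genome_id=genome_id,
            species_label=species_label,
            isolation_source=isolation_source,
            completeness_pct=float(completeness_pct),
            contamination_pct=float(contamination_pct),
            friendliness=classify_isolation_source(isolation_source),
            **kw,
        )


def n50(lengths) -> int:
    """Smallest length L such that contigs of length >= L cover at least half
    the total assembly."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("no contigs")
    if any(v <= 0 for v in lengths):
        raise ValueError("contig lengths must be positive")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


# (criterion label, attribute, threshold, strictness)
_HMP_CRITERIA = (
    ("contig_fraction_gt500bp", "frac_in_long_contigs", 0.98, ">="),
    ("scaffold_n50", "scaffold_n50", 20_000, ">"),
    ("contig_n50", "contig_n50", 20_000, ">"),
    ("mean_contig_length", "mean_contig_length", 10_000, ">"),
    ("core_gene_fraction", "core_gene_fraction", 0.90, ">"),
)


@dataclass(frozen=True)
class HMPReport:
    passed: bool
    criteria: dict[str, dict]  # label -> {value, threshold, op, passed}


def hmp_draft_pass(assembly: AssemblyStats) -> HMPReport:
    """Evaluate the five HMP high-quality draft criteria.

    (i) >= 98% of the assembly in contigs longer than 500 bp, (ii) scaffold
    N50 > 20 kb, (iii) contig N50 > 20 kb, (iv) mean contig length > 10 kb,
    (v) > 90% of the reference core-gene set detected.
    """
    report = {}
    for label, attr, threshold, op in _HMP_CRITERIA:
        value = getattr(assembly, attr)
        ok = value >= threshold if op == ">=" else value > threshold
        report[label] = {"value": value, "threshold": threshold, "op": op, "passed": ok}
    return HMPReport(all(c["passed"] for c in report.values()), report)


def checkm_gate(completeness_pct: float, contamination_pct: float) -> bool:
    """Completeness/contamination gate: completeness > 95 and contamination
    < 5, both strict."""
    for name, v in (("completeness", completeness_pct), ("contamination", contamination_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    return completeness_pct > 95.0 and contamination_pct < 5.0


def intra_species_purity_filter(
    genome_ids,
    ani,
    threshold: float = 93.0,
):
    """Iteratively drop genomes until every intra-species pair has ANI
    strictly above ``threshold``.

    ``ani`` maps unordered genome pairs to percent identity, either as a
    nested mapping ``ani[a][b]`` or a callable ``ani(a, b)``; it must cover
    every pair of the input set. While any pair fails the rule, the genome
    with the lowest mean ANI to the other retained genomes is removed (the
    most "mis-distributed" one); name order breaks ties for determinism.

    Returns ``(retained_ids, removal_log)`` where the log records each
    removal's genome, mean intra-species ANI and the failing pairs that
    triggered it.
    """
    ids = sorted(genome_ids)
    if callable(ani):
        lookup = ani
    else:
        lookup = lambda a, b: ani[a][b]  # noqa: E731

    log: list[dict] = []
    if len(ids) < 2:
        log.append({"note": "fewer than 2 genomes; purity filter not applicable"})
        return ids, log

    retained = list(ids)
    while True:
        failing = [
            (a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1 :]
            if lookup(a, b) <= threshold
        ]
        if not failing:
            break
        involved = sorted({g for pair in failing for g in pair})
        means = {
            g: float(np.mean([lookup(g, h) for h in retained if h != g]))
            for g in involved
        }
        drop = min(involved, key=lambda g: (means[g], g))
        retained.remove(drop)
        log.append(
            {
                "removed": drop,
                "mean_intra_species_ani": means[drop],
                "failing_pairs": [p for p in failing if drop in p],
                "reason": f"pairwise ANI <= {threshold} with "
                          f"{sum(drop in p for p in failing)} retained genome(s)",
            }
        )
        if len(retained) < 2:
            break
    return retained, log
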