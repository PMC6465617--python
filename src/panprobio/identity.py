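"""Fragment-based average nucleotide / amino-acid identity (ANI / AAI).

The query genome is cut into consecutive fixed-length fragments; each
fragment is placed on the reference by k-mer seed voting (best diagonal) and
scored by ungapped comparison. Fragments passing an identity floor over a
coverage floor are accepted, and the one-way identity is the mean identity of
accepted fragments. The pairwise ANI (or AAI) is the mean of the two one-way
values, so it is symmetric by construction.

Species-level AAI between two species is the mean identity over
reciprocal-best-hit pairs of their core proteins; the intra-species AAI
standard deviation summarises how dispersed the strain-pair AAI values are
within one species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from statistics import pstdev

import numpy as np
import pandas as pd

from ._align import pair_stats

__all__ = [
    "FragmentParams",
    "NT_PARAMS",
    "AA_PARAMS",
    "IdentityMatrix",
    "one_way_identity",
    "symmetric_identity",
    "identity_matrix",
    "species_aai_matrix",
    "intra_species_aai_sd",
    "aai_stats",
    "aai_clusters",
]


@dataclass(frozen=True)
class FragmentParams:
    """Fragmentation and acceptance parameters for one-way identity.

    Defaults follow the conventional ANI fragment recipe: 1,020 bp fragments
    (300 aa for proteins), accepted when they align at >= 30% identity over
    >= 70% of the fragment.
    """

    fragment_length: int = 1020
    seed_k: int = 11
    min_fragment_identity: float = 30.0  # percent
    min_fragment_coverage: float = 0.7  # fraction of the fragment aligned
    seed_stride: int = 4  # sample every seed_stride-th k-mer of a fragment

    def __post_init__(self):
        if self.fragment_length < self.seed_k:
            raise ValueError("fragment_length must be >= seed_k")
        if not 0 <= self.min_fragment_identity <= 100:
            raise ValueError("min_fragment_identity must be a percent")
        if not 0 < self.min_fragment_coverage <= 1:
            raise ValueError("min_fragment_coverage must be a fraction in (0, 1]")


NT_PARAMS = FragmentParams(fragment_length=1020, seed_k=11)
AA_PARAMS = FragmentParams(fragment_length=300, seed_k=4, seed_stride=2)


def _as_seq_list(seqs) -> list[str]:
    if isinstance(seqs, str):
        return [seqs]
    if isinstance(seqs, dict):
        return [seqs[k] for k in sorted(seqs)]
    return list(seqs)


def _build_seed_index(ref_seqs: list[str], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, seq in enumerate(ref_seqs):
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((ri, pos))
    return index


def _fragments(seqs: list[str], length: int, min_len: int):
    for seq in seqs:
        for start in range(0, len(seq), length):
            frag = seq[start : start + length]
            if len(frag) >= min_len:
                yield frag


def _best_diagonal(frag: str, index, k: int, stride: int):
    """Vote for (reference sequence, diagonal) pairs using sampled k-mer
    seeds; returns the best-supported placement or None."""
    votes: dict[tuple[int, int], int] = {}
    for off in range(0, len(frag) - k + 1, stride):
        for ri, pos in index.get(frag[off : off + k], ()):
            key = (ri, pos - off)
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    # max votes; ties broken by smallest (ref index, diagonal) for determinism
    return min(votes, key=lambda key: (-votes[key], key))


def _ungapped_score(frag: str, ref: str, diag: int) -> tuple[int, int]:
    """(matches, aligned columns) of the fragment laid on the reference at
    offset ``diag``, clipped to the reference bounds."""
    f0 = max(0, -diag)
    r0 = max(0, diag)
    span = min(len(frag) - f0, len(ref) - r0)
    if span <= 0:
        return 0, 0
    fa = np.frombuffer(frag[f0 : f0 + span].encode(), dtype=np.uint8)
    ra = np.frombuffer(ref[r0 : r0 + span].encode(), dtype=np.uint8)
    return int((fa == ra).sum()), span


def one_way_identity(query, reference, params: FragmentParams = NT_PARAMS) -> float | None:
    """Mean percent identity of accepted query fragments against the
    reference, or ``None`` (no-alignment) when no fragment is accepted."""
    q = _as_seq_list(query)
    r = _as_seq_list(reference)
    if not q or not r or not any(q) or not any(r):
        raise ValueError("one_way_identity requires non-empty sequence sets")
    index = _build_seed_index(r, params.seed_k)
    identities = []
    for frag in _fragments(q, params.fragment_length, params.seed_k):
        placement = _best_diagonal(frag, index, params.seed_k, params.seed_stride)
        if placement is None:
            continue
        ri, diag = placement
        matches, cols = _ungapped_score(frag, r[ri], diag)
        if cols == 0:
            continue
        identity = 100.0 * matches / cols
        coverage = cols / len(frag)
        if identity >= params.min_fragment_identity and coverage >= params.min_fragment_coverage:
            identities.append(identity)
    if not identities:
        return None
    return float(np.mean(identities))


def symmetric_identity(a, b, params: FragmentParams = NT_PARAMS) -> float | None:
    """Bidirectional identity: the mean of the two one-way values.

    If only one direction aligns, that value is returned (with the other
    treated as missing rather than zero); if neither aligns the result is
    ``None``.
    """
    ab = one_way_identity(a, b, params)
    ba = one_way_identity(b, a, params)
    vals = [v for v in (ab, ba) if v is not None]
    if not vals:
        return None
    return float(np.mean(vals))


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix (diagonal 100, NaN = no alignment)."""

    values: pd.DataFrame
    kind: str  # "ANI" or "AAI"

    def __post_init__(self):
        if self.kind not in ("ANI", "AAI"):
            raise ValueError("kind must be 'ANI' or 'AAI'")
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValueError("matrix labels must match on rows and columns")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def __getitem__(self, pair):
        a, b = pair
        return self.values.loc[a, b]

    def to_tsv(self, path):
        self.values.to_csv(path, sep="\t")

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "kind": self.kind, "identity": self.values.loc[a, b]}
            for a, b in itertools.combinations(self.labels, 2)
        ]
        return pd.DataFrame(rows, columns=["a", "b", "kind", "identity"])

    @classmethod
    def from_tsv(cls, path, kind):
        return cls(pd.read_csv(path, sep="\t", index_col=0), kind)


def identity_matrix(seq_sets: dict, params: FragmentParams = NT_PARAMS,
                    kind: str = "ANI") -> IdentityMatrix:
    """All-vs-all symmetric identity over labelled sequence sets."""
    labels = sorted(seq_sets)
    mat = pd.DataFrame(np.full((len(labels), len(labels)), np.nan),
                       index=labels, columns=labels)
    for lab in labels:
        mat.loc[lab, lab] = 100.0
    for a, b in itertools.combinations(labels, 2):
        v = symmetric_identity(seq_sets[a], seq_sets[b], params)
        mat.loc[a, b] = mat.loc[b, a] = np.nan if v is None else v
    return IdentityMatrix(mat, kind)


RBH_MIN_COVERAGE = 0.5  # a hit must cover half the shorter protein


def _rbh_mean_identity(prots_a: dict[str, str], prots_b: dict[str, str]) -> float | None:
    """Mean percent identity over reciprocal-best-hit protein pairs.

    A hit requires the local alignment to cover at least half of the shorter
    protein (rejecting the spuriously perfect micro-alignments unrelated
    proteins produce); the best hit maximises matched residues.
    """
    ids_a, ids_b = sorted(prots_a), sorted(prots_b)
    score: dict[tuple[str, str], int] = {}
    ident: dict[tuple[str, str], float] = {}
    for i in ids_a:
        for j in ids_b:
            st = pair_stats(prots_a[i], prots_b[j], mode="local")
            if st.shorter_coverage >= RBH_MIN_COVERAGE:
                score[(i, j)] = st.identities
                ident[(i, j)] = 100.0 * st.identity_fraction
    rbh = []
    for i in ids_a:
        hits_i = [j for j in ids_b if (i, j) in score]
        if not hits_i:
            continue
        j = max(hits_i, key=lambda j: (score[(i, j)], j))
        hits_j = [i2 for i2 in ids_a if (i2, j) in score]
        if max(hits_j, key=lambda i2: (score[(i2, j)], i2)) == i:
            rbh.append((i, j))
    if not rbh:
        return None
    return float(np.mean([ident[p] for p in rbh]))


def species_aai_matrix(core_by_species: dict[str, dict[str, str]]) -> IdentityMatrix:
    """Species-level AAI: reciprocal-best-hit mean identity between each
    pair of species' core-protein sets."""
    labels = sorted(core_by_species)
    mat = pd.DataFrame(np.full((len(labels), len(labels)), np.nan),
                       index=labels, columns=labels)
    for lab in labels:
        if not core_by_species[lab]:
            raise ValueError(f"species {lab!r} has no core proteins")
        mat.loc[lab, lab] = 100.0
    for a, b in itertools.combinations(labels, 2):
        v = _rbh_mean_identity(core_by_species[a], core_by_species[b])
        mat.loc[a, b] = mat.loc[b, a] = np.nan if v is None else v
    return IdentityMatrix(mat, "AAI")


def intra_species_aai_sd(strain_proteins: dict[str, dict[str, str]],
                         params: FragmentParams = AA_PARAMS) -> float:
    """Population standard deviation of all within-species strain-pair AAI
    values (0 for a single pair)."""
    strains = sorted(strain_proteins)
    if len(strains) < 2:
        raise ValueError("need at least 2 strains for intra-species AAI")
    vals = []
    for a, b in itertools.combinations(strains, 2):
        v = symmetric_identity(strain_proteins[a], strain_proteins[b], params)
        if v is not None:
            vals.append(v)
    if not vals:
        raise ValueError("no strain pair produced an alignment")
    return float(pstdev(vals)) if len(vals) > 1 else 0.0


def aai_stats(core_by_species, strains_by_species=None, params: FragmentParams = AA_PARAMS):
    """Species-level AAI matrix plus per-species intra-species AAI SD.

    ``strains_by_species`` maps species -> strain -> protein dict; species
    with fewer than two strains get SD ``nan``.
    """
    matrix = species_aai_matrix(core_by_species)
    sds: dict[str, float] = {}
    if strains_by_species:
        for sp, strains in sorted(strains_by_species.items()):
            sds[sp] = (intra_species_aai_sd(strains, params)
                       if len(strains) >= 2 else float("nan"))
    return matrix, sds


def aai_clusters(matrix: IdentityMatrix, cutoff: float = 70.0) -> dict[str, int]:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever identity >= cutoff. Returns label -> cluster id (0-based,
    ordered by the smallest member label)."""
    labels = matrix.labels
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(labels, 2):
        v = matrix[a, b]
        if pd.notna(v) and v >= cutoff:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(lab) for lab in labels})
    root_id = {r: i for i, r in enumerate(roots)}
    return {lab: root_id[find(lab)] for lab in labels}
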