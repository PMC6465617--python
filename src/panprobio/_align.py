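"""Pairwise alignment helpers shared by the clustering and AAI code.

Thin wrappers over :class:`Bio.Align.PairwiseAligner` that reduce an
alignment to the three numbers the thresholds operate on: identical columns,
aligned columns, and the fraction of the shorter sequence covered.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align


@dataclass(frozen=True)
class PairStats:
    identities: int
    aligned_columns: int  # identities + mismatches + internal gap columns
    shorter_coverage: float  # aligned residues of the shorter sequence / its length

    @property
    def identity_fraction(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return self.identities / self.aligned_columns


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    if mode == "global":
        # free end gaps: penalise internal indels only, so a short sequence
        # aligned inside a longer one is not punished for the overhangs
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def pair_stats(a: str, b: str, mode: str = "local") -> PairStats:
    """Align two sequences and report identity/coverage statistics.

    ``mode`` is ``"local"`` (Smith-Waterman, used for family clustering where
    the covered region matters) or ``"global"`` (end-gap-free
    Needleman-Wunsch, used for homolog identity).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(mode).align(a, b)[0]
    counts = aln.counts()
    identities = counts.identities
    blocks_a, blocks_b = aln.aligned
    # columns between the outermost aligned blocks: letter pairs plus
    # internal gap columns; end overhangs are excluded on purpose
    spans_a = sum(int(e - s) for s, e in blocks_a)
    spans_b = sum(int(e - s) for s, e in blocks_b)
    internal_gaps = 0
    for blocks in (blocks_a, blocks_b):
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            internal_gaps += int(s1 - e0)
    aligned_cols = spans_a + internal_gaps  # spans_a == spans_b (letter pairs)
    shorter_len = min(len(a), len(b))
    covered_shorter = spans_a if len(a) <= len(b) else spans_b
    return PairStats(
        identities=int(identities),
        aligned_columns=int(aligned_cols),
        shorter_coverage=covered_shorter / shorter_len,
    )
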