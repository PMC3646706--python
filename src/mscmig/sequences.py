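"""Jukes-Cantor sequence simulation along gene trees, plus alignment summaries.

Sites evolve independently under JC69 with a strict clock: the root state is
uniform over {A, C, G, T}, and along a branch spanning ``dt`` time units the
probability that a site differs from its parent state is the closed form
``(3/4)(1 - exp(-4 d / 3))`` with ``d = rate * dt`` expected substitutions
per site.  No rate heterogeneity, no indels.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .structured_coalescent import GeneTree

__all__ = [
    "Alignment",
    "diversity_summary",
    "haplotype_count",
    "nucleotide_diversity",
    "pairwise_identity",
    "segregating_sites",
    "simulate_jc",
    "jc_mismatch_probability",
]

_ALPHABET = "ACGT"


class Alignment:
    """Equal-length nucleotide sequences with taxon labels.

    Stored as an ``(n_sequences, length)`` int8 matrix over the coded
    alphabet 0..3 = A, C, G, T.
    """

    def __init__(self, labels: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2 or matrix.shape[0] != len(labels):
            raise ValueError("matrix must be (n_labels, length)")
        if matrix.size and (matrix.min() < 0 or matrix.max() > 3):
            raise ValueError("matrix entries must code A,C,G,T as 0..3")
        self.labels = list(labels)
        self._index = {lb: i for i, lb in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("labels must be unique")
        self.matrix = matrix

    @classmethod
    def from_strings(cls, labels: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        code = {c: i for i, c in enumerate(_ALPHABET)}
        rows = [[code[c] for c in s.upper()] for s in seqs]
        if len({len(r) for r in rows}) > 1:
            raise ValueError("all sequences must have the same length")
        return cls(labels, np.asarray(rows, dtype=np.int8))

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self._index[label]]

    def sequence(self, label: str) -> str:
        return "".join(_ALPHABET[i] for i in self.row(label))

    def to_fasta(self, path) -> None:
        """Write the alignment as FASTA (one record per taxon)."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequence(lb)), id=lb, description="")
            for lb in self.labels
        ]
        seqio_write(records, path, "fasta")


def jc_mismatch_probability(d: float) -> float:
    """JC69 probability that two sites at distance ``d`` substitutions differ."""
    return 0.75 * -math.expm1(-4.0 * d / 3.0)


def simulate_jc(
    g: GeneTree, length: int, rate: float, rng: np.random.Generator
) -> Alignment:
    """Evolve ``length`` iid sites down the gene tree under JC69.

    ``rate`` is in substitutions per site per model time unit; the branch
    distance is ``rate`` times the branch's time span (strict clock).
    """
    if length < 1:
        raise ValueError("length must be at least 1")
    if not rate > 0:
        raise ValueError("rate must be positive")
    seqs: Dict[int, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
    stack = [(g.root, root_seq)]
    tip_rows: Dict[str, np.ndarray] = {}
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            tip_rows[node.name] = seq
            continue
        for child in node.children:
            d = rate * (node.time - child.time)
            p = jc_mismatch_probability(d)
            out = seq.copy()
            if p > 0.0:
                mask = rng.random(length) < p
                k = int(mask.sum())
                if k:
                    out[mask] = (out[mask] + rng.integers(1, 4, size=k)) % 4
            stack.append((child, out))
    labels = g.tip_labels()
    return Alignment(labels, np.stack([tip_rows[lb] for lb in labels]))


def pairwise_identity(a: Alignment, pairs: Sequence[Tuple[str, str]]) -> float:
    """Mean fraction of identical sites over the given taxon pairs."""
    if not pairs:
        raise ValueError("pairs must be nonempty")
    vals = []
    for x, y in pairs:
        rx, ry = a.row(x), a.row(y)
        vals.append(float(np.mean(rx == ry)))
    return float(np.mean(vals))


def segregating_sites(a: Alignment) -> int:
    """Number of columns showing at least two observed states."""
    if a.n_sequences == 0:
        raise ValueError("empty alignment")
    return int(np.any(a.matrix != a.matrix[0], axis=0).sum())


def haplotype_count(a: Alignment) -> int:
    """Number of distinct sequences in the alignment."""
    if a.n_sequences == 0:
        raise ValueError("empty alignment")
    return len({row.tobytes() for row in a.matrix})


def _pairs_for(
    a: Alignment, partition: Optional[Dict[str, str]], which: str
) -> List[Tuple[str, str]]:
    labels = a.labels
    allp = list(itertools.combinations(labels, 2))
    if which == "overall":
        return allp
    if partition is None:
        raise ValueError("within/between diversity needs a species partition")
    if which == "within":
        return [(x, y) for x, y in allp if partition[x] == partition[y]]
    if which == "between":
        return [(x, y) for x, y in allp if partition[x] != partition[y]]
    raise ValueError("which must be 'overall', 'within' or 'between'")


def nucleotide_diversity(
    a: Alignment,
    partition: Optional[Dict[str, str]] = None,
    which: str = "overall",
) -> float:
    """Mean per-site pairwise difference over the selected taxon pairs.

    With a ``partition`` (taxon label -> species) the statistic restricts
    to same-species (``which='within'``) or cross-species
    (``which='between'``) pairs; the overall value is the pair-count
    weighted mean of the two.
    """
    pairs = _pairs_for(a, partition, which)
    if not pairs:
        return float("nan")
    return 1.0 - pairwise_identity(a, pairs)


def diversity_summary(
    a: Alignment, partition: Optional[Dict[str, str]] = None
) -> Dict[str, float]:
    """Per-locus summary: diversities, segregating sites and haplotypes."""
    out = {
        "diversity_overall": nucleotide_diversity(a),
        "segregating_sites": float(segregating_sites(a)),
        "haplotypes": float(haplotype_count(a)),
    }
    if partition is not None:
        out["diversity_within"] = nucleotide_diversity(a, partition, "within")
        out["diversity_between"] = nucleotide_diversity(a, partition, "between")
    return out
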