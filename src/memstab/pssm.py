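"""Position-specific score matrices from homolog alignments.

The PSSM encodes, per target position, the log-odds (bits) of observing
each amino acid among homologs relative to a background distribution.
Mutations the phylogeny disfavors — strictly negative log-odds — are
eliminated before any energy calculation.

Counts are weighted with the Henikoff & Henikoff position-based scheme
applied to the *unique* alignment rows, so exact duplicate sequences never
influence the profile. A flat pseudocount toward the background keeps all
scores finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tables import AMINO_ACIDS, AA_INDEX
from .masking import ConfidenceMask, designable_positions
from .structio import Alignment

logger = logging.getLogger(__name__)

__all__ = ["PSSM", "MutationCandidate", "build_pssm", "enumerate_candidates"]


@dataclass
class PSSM:
    """L x 20 log-odds matrix (bits) over the canonical amino acid alphabet."""

    scores: np.ndarray
    alphabet: str
    column_counts: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.alphabet):
            raise ValueError("scores must be (L, len(alphabet))")
        if not np.isfinite(self.scores).all():
            raise ValueError("PSSM scores must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, aa: str) -> float:
        """Log-odds score (bits) for amino acid ``aa`` at 1-based ``position``."""
        return float(self.scores[position - 1, AA_INDEX[aa]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(self.alphabet) + "\n")
            for i in range(self.length):
                row = "\t".join(f"{v:.4f}" for v in self.scores[i])
                fh.write(f"{i + 1}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PSSM":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            alphabet = "".join(header[1:])
            rows = [
                [float(x) for x in line.rstrip("\n").split("\t")[1:]]
                for line in fh
                if line.strip()
            ]
        scores = np.array(rows, dtype=float)
        return cls(scores, alphabet, np.zeros(len(rows)), {"source": str(path)})


@dataclass
class MutationCandidate:
    """A single point mutation surviving the phylogenetic filter."""

    position: int
    wt_aa: str
    mut_aa: str
    pssm_score: float
    energy_score: float | None = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError("wild-type and mutant amino acids must differ")


def _henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights, normalized to mean 1.

    Per column with r distinct standard residues, a sequence carrying a
    residue seen in s rows contributes 1/(r*s); gaps and non-standard
    characters contribute nothing.
    """
    n = len(rows)
    L = len(rows[0])
    raw = np.zeros(n)
    for c in range(L):
        col = [row[c] for row in rows]
        counts: dict[str, int] = {}
        for ch in col:
            if ch in AA_INDEX:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(col):
            if ch in counts:
                raw[i] += 1.0 / (r * counts[ch])
    total = raw.sum()
    if total == 0:
        return np.ones(n)
    return raw * (n / total)


def build_pssm(
    alignment: Alignment,
    alpha: float = 1.0,
    background: dict[str, float] | None = None,
    weighting: str = "henikoff",
) -> PSSM:
    """Build the log-odds profile over the query-mapped alignment columns.

    Per column c and amino acid a:
    ``p(a|c) = (w_count(a,c) + alpha*q_a) / (sum_b w_count(b,c) + alpha)``
    and ``score(c,a) = log2(p(a|c)/q_a)``, with q the background (uniform by
    default). ``weighting`` is ``"henikoff"`` (unique-row position-based
    weights) or ``"none"`` (every unique row weight 1).
    """
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be > 0")
    if not alignment.column_map:
        raise ValueError("alignment has zero non-gap query columns")
    if background is None:
        q = np.full(20, 1.0 / 20.0)
    else:
        q = np.array([background[a] for a in AMINO_ACIDS], dtype=float)
        if abs(q.sum() - 1.0) > 1e-6 or (q <= 0).any():
            raise ValueError("background must be a positive distribution over 20 aas")

    # collapse exact duplicate rows so they cannot tilt the profile
    unique_rows: list[str] = []
    seen: set[str] = set()
    for _, seq in alignment.sequences:
        if seq not in seen:
            seen.add(seq)
            unique_rows.append(seq)
    if weighting == "henikoff":
        weights = _henikoff_weights(unique_rows)
    elif weighting == "none":
        weights = np.ones(len(unique_rows))
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")

    L = len(alignment.column_map)
    wcounts = np.zeros((L, 20))
    for col, pos in alignment.column_map.items():
        for row, w in zip(unique_rows, weights):
            ch = row[col - 1]
            idx = AA_INDEX.get(ch)
            if idx is not None:
                wcounts[pos - 1, idx] += w
    totals = wcounts.sum(axis=1)
    probs = (wcounts + alpha * q[None, :]) / (totals[:, None] + alpha)
    scores = np.log2(probs / q[None, :])
    params = {
        "alpha": alpha,
        "background": "uniform" if background is None else dict(background),
        "weighting": weighting,
        "n_rows": alignment.n_rows,
        "n_unique_rows": len(unique_rows),
        "log_base": 2,
    }
    return PSSM(scores, AMINO_ACIDS, totals, params)


def enumerate_candidates(
    pssm: PSSM, sequence: str, mask: ConfidenceMask
) -> list[MutationCandidate]:
    """All mutations at designable positions with PSSM score >= 0.

    Strictly negative scores are eliminated; a boundary score of exactly
    zero is retained. Output is sorted by (position, mutant amino acid).
    """
    if len(sequence) != pssm.length:
        raise ValueError(
            f"sequence length {len(sequence)} != PSSM length {pssm.length}"
        )
    if mask.length != pssm.length:
        raise ValueError("mask length != PSSM length")
    out: list[MutationCandidate] = []
    for pos in designable_positions(mask):
        wt = sequence[pos - 1]
        if wt not in AA_INDEX:
            logger.warning("position %d: wild-type %r not canonical, skipped", pos, wt)
            continue
        for m in pssm.alphabet:
            if m == wt:
                continue
            s = pssm.score(pos, m)
            if s >= 0.0:
                out.append(MutationCandidate(pos, wt, m, s))
    return out
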