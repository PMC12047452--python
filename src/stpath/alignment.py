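"""Gap-free-penalty pathway alignment over ST-code sequences.

Two pathways are compared through their ST-code sequences alone.  The raw
score is the maximum, over all monotone matchings of the two sequences, of
the summed code similarities σ; skipping a step on either side (a gap)
costs nothing.  The normalized similarity divides the raw score by the
longer pathway's length, so it lies in [0, 1] and reaches 1 exactly when
the two code sequences are identical.

Because σ is non-negative and gaps are free, the Smith–Waterman local
optimum coincides with the global dynamic-programming value: the score
matrix is monotone non-decreasing along both axes, so the bottom-right
cell is also the matrix maximum.  We implement the global recurrence

    H[i][j] = max(H[i-1][j-1] + σ(a_i, b_j), H[i-1][j], H[i][j-1])

with H[0][·] = H[·][0] = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .pathway_io import Pathway
from .st_core import st_similarity

__all__ = ["AlignmentResult", "align_pathways", "brute_force_score", "rank_against_collection"]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning a query pathway against a subject pathway.

    ``matches`` lists one optimal monotone matching as (query index,
    subject index, σ) triples with both index sequences strictly
    increasing; ``raw_score`` is the σ-sum of those matches and
    ``similarity`` = raw_score / max(L1, L2).
    """

    query_id: str
    subject_id: str
    raw_score: float
    similarity: float
    query_length: int
    subject_length: int
    matches: tuple[tuple[int, int, float], ...]


def _score_matrix(pw1: Pathway, pw2: Pathway) -> np.ndarray:
    a, b = pw1.codes, pw2.codes
    sigma = np.empty((len(a), len(b)))
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            sigma[i, j] = st_similarity(ca, cb)
    return sigma


def align_pathways(pw1: Pathway, pw2: Pathway) -> AlignmentResult:
    """Align two nonempty pathways, returning score and one optimal matching.

    Traceback tie-breaking prefers the diagonal move, then the query gap,
    then the subject gap, so the reported matching is canonical; the score
    itself never depends on the tie-break.
    """
    n1, n2 = len(pw1), len(pw2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot align an empty pathway (normalization undefined)")
    sigma = _score_matrix(pw1, pw2)
    H = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        Hi, Hprev, srow = H[i], H[i - 1], sigma[i - 1]
        for j in range(1, n2 + 1):
            Hi[j] = max(Hprev[j - 1] + srow[j - 1], Hprev[j], Hi[j - 1])
    raw = float(H[n1, n2])

    matches: list[tuple[int, int, float]] = []
    i, j = n1, n2
    while i > 0 and j > 0:
        s = sigma[i - 1, j - 1]
        if H[i, j] == H[i - 1, j - 1] + s:
            if s > 0:
                matches.append((i - 1, j - 1, float(s)))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j]:
            i -= 1
        else:
            j -= 1
    matches.reverse()

    return AlignmentResult(
        query_id=pw1.id,
        subject_id=pw2.id,
        raw_score=raw,
        similarity=raw / max(n1, n2),
        query_length=n1,
        subject_length=n2,
        matches=tuple(matches),
    )


def brute_force_score(pw1: Pathway, pw2: Pathway, max_len: int = 8) -> float:
    """Maximum σ-sum over explicitly enumerated monotone matchings.

    Independent oracle for :func:`align_pathways`: enumerates every subset
    of query indices and every order-preserving assignment to subject
    indices.  Exponential — restricted to short pathways.
    """
    n1, n2 = len(pw1), len(pw2)
    if n1 > max_len or n2 > max_len:
        raise ValueError(f"brute force limited to pathways of length <= {max_len}")
    sigma = _score_matrix(pw1, pw2)
    best = 0.0
    for k in range(1, min(n1, n2) + 1):
        for qs in itertools.combinations(range(n1), k):
            for ss in itertools.combinations(range(n2), k):
                best = max(best, sum(sigma[i, j] for i, j in zip(qs, ss)))
    return best


def rank_against_collection(
    query: Pathway, collection: list[Pathway]
) -> list[AlignmentResult]:
    """Align the query against every subject, best similarity first.

    Ties are broken by subject id ascending so the ordering is
    deterministic — mirroring a results page sorted from high to low.
    """
    if not collection:
        raise ValueError("subject collection is empty")
    results = [align_pathways(query, subject) for subject in collection]
    results.sort(key=lambda r: (-r.similarity, r.subject_id))
    return results
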