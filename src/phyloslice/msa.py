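"""Internal progressive multiple-sequence aligner.

A dependency-free engine used for protein-guided locus alignments and for
the rapid alignments behind rate-based taxon scoring.  The design is the
classic progressive scheme: a guide order from pairwise similarities
(greedy joining of the closest pair), pairwise profile-profile alignment
with affine gaps under a sum-of-pairs column score, and support for
profile-adding new sequences to a fixed alignment.

``quick=True`` estimates the guide order from k-mer similarity instead of
full pairwise alignment scores — one cheap pass, for rate scoring over
many loci.  External aligners can replace this engine where production
fidelity matters; the surrounding two-stage protocol is engine-agnostic.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = ["align_sequences", "add_to_alignment"]

_PROT_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_DNA_ALPHABET = "ACGTN"

_GAP = "-"


def _subst_matrix(is_protein: bool) -> tuple[str, np.ndarray, float, float]:
    if is_protein:
        blosum = substitution_matrices.load("BLOSUM62")
        k = len(_PROT_ALPHABET)
        S = np.zeros((k, k))
        for i, a in enumerate(_PROT_ALPHABET):
            for j, b in enumerate(_PROT_ALPHABET):
                S[i, j] = blosum[a][b]
        return _PROT_ALPHABET, S, -10.0, -0.5
    k = len(_DNA_ALPHABET)
    S = np.full((k, k), -4.0)
    np.fill_diagonal(S, 5.0)
    S[-1, :] = S[:, -1] = 0.0  # N is neutral
    return _DNA_ALPHABET, S, -10.0, -1.0



def _profile(rows: Sequence[str], alphabet: str) -> np.ndarray:
    """Column frequency matrix (L x K); gaps contribute nothing."""
    k = len(alphabet)
    length = len(rows[0])
    prof = np.zeros((length, k))
    for row in rows:
        for pos, c in enumerate(row):
            if c != _GAP:
                prof[pos, alphabet.find(c) if c in alphabet else k - 1] += 1
    prof /= len(rows)
    return prof


def _gotoh_profiles(
    ca: np.ndarray, cb: np.ndarray, S: np.ndarray,
    gap_open: float, gap_ext: float,
) -> list[tuple[int, int]]:
    """Affine-gap global alignment of two profiles.

    Returns the merge path as (i, j) pairs where -1 marks a gap.
    """
    C = ca @ S @ cb.T  # column-vs-column expected scores
    la, lb = C.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + gap_ext * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + gap_ext * (j - 1)
    # traceback matrices: 0=M, 1=X, 2=Y
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    Crows = C  # local alias
    for i in range(1, la + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        Ci = Crows[i - 1]
        tbm_i, tbx_i, tby_i = tb_m[i], tb_x[i], tb_y[i]
        for j in range(1, lb + 1):
            s = Ci[j - 1]
            a, b, c = Mi1[j - 1], Xi1[j - 1], Y[i - 1][j - 1]
            if a >= b and a >= c:
                Mi[j] = a + s; tbm_i[j] = 0
            elif b >= c:
                Mi[j] = b + s; tbm_i[j] = 1
            else:
                Mi[j] = c + s; tbm_i[j] = 2
            a, b = Mi1[j] + gap_open, Xi1[j] + gap_ext
            if a >= b:
                Xi[j] = a; tbx_i[j] = 0
            else:
                Xi[j] = b; tbx_i[j] = 1
            a, b = Mi[j - 1] + gap_open, Yi[j - 1] + gap_ext
            if a >= b:
                Yi[j] = a; tby_i[j] = 0
            else:
                Yi[j] = b; tby_i[j] = 2
    # traceback from the best of the three at (la, lb)
    i, j = la, lb
    state = int(np.argmax([M[la, lb], X[la, lb], Y[la, lb]]))
    path: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if i == 0:
            path.append((-1, j - 1)); j -= 1; continue
        if j == 0:
            path.append((i - 1, -1)); i -= 1; continue
        if state == 0:
            prev = tb_m[i, j]
            path.append((i - 1, j - 1)); i -= 1; j -= 1
            state = prev
        elif state == 1:
            prev = tb_x[i, j]
            path.append((i - 1, -1)); i -= 1
            state = prev
        else:
            prev = tb_y[i, j]
            path.append((-1, j - 1)); j -= 1
            state = prev
    path.reverse()
    return path


def _apply_path(rows: Sequence[str], side: int,
                path: list[tuple[int, int]]) -> list[str]:
    out = []
    for row in rows:
        chars = []
        for pair in path:
            idx = pair[side]
            chars.append(_GAP if idx < 0 else row[idx])
        out.append("".join(chars))
    return out


def _kmer_sets(seqs: Sequence[str], k: int) -> list[set[str]]:
    return [{s[i:i + k] for i in range(len(s) - k + 1)} or {s} for s in seqs]


def _pairwise_similarity(
    seqs: Sequence[str], is_protein: bool, quick: bool
) -> np.ndarray:
    n = len(seqs)
    sim = np.zeros((n, n))
    if quick:
        k = 3 if is_protein else 5
        sets = _kmer_sets(seqs, k)
        for i in range(n):
            for j in range(i + 1, n):
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j]) or 1
                sim[i, j] = sim[j, i] = inter / union
        return sim
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if is_protein:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -10, -0.5
    else:
        aligner.match_score, aligner.mismatch_score = 5, -4
        aligner.open_gap_score, aligner.extend_gap_score = -10, -1
    for i in range(n):
        for j in range(i + 1, n):
            denom = max(len(seqs[i]), len(seqs[j])) or 1
            sim[i, j] = sim[j, i] = float(
                aligner.score(_clean(seqs[i], is_protein),
                              _clean(seqs[j], is_protein))) / denom
    return sim


def _clean(seq: str, is_protein: bool) -> str:
    alphabet = _PROT_ALPHABET if is_protein else _DNA_ALPHABET
    unknown = alphabet[-1]
    return "".join(c if c in alphabet else unknown for c in seq.upper())


def align_sequences(
    seqs: Sequence[str],
    is_protein: bool = False,
    quick: bool = False,
) -> list[str]:
    """Progressively align sequences; returns gapped rows in input order."""
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return [seqs[0]]
    if any(not s for s in seqs):
        raise ValueError("cannot align an empty sequence")
    alphabet, S, gap_open, gap_ext = _subst_matrix(is_protein)
    sim = _pairwise_similarity(seqs, is_protein, quick)

    # clusters: mapping cluster id -> (member indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    # greedy joining: always merge the closest pair (max-link between clusters)
    while len(clusters) > 1:
        ids = sorted(clusters)
        best: Optional[tuple[float, int, int]] = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                link = max(
                    sim[x, y]
                    for x in clusters[a][0] for y in clusters[b][0]
                )
                if best is None or link > best[0]:
                    best = (link, a, b)
        assert best is not None
        _, a, b = best
        members_a, rows_a = clusters.pop(a)
        members_b, rows_b = clusters.pop(b)
        pa = _profile(rows_a, alphabet)
        pb = _profile(rows_b, alphabet)
        path = _gotoh_profiles(pa, pb, S, gap_open, gap_ext)
        merged_rows = _apply_path(rows_a, 0, path) + _apply_path(rows_b, 1, path)
        clusters[a] = (members_a + members_b, merged_rows)

    members, rows = next(iter(clusters.values()))
    ordered = [""] * len(seqs)
    for member, row in zip(members, rows):
        ordered[member] = row
    return ordered


def add_to_alignment(
    alignment_rows: Sequence[str],
    new_seqs: Sequence[str],
    is_protein: bool = False,
) -> tuple[list[str], list[str]]:
    """Profile-align new sequences to a fixed alignment, one at a time.

    The existing rows change only by insertion of columns that are gaps in
    all of them; their mutual gap structure is preserved.  Returns
    ``(updated_existing_rows, new_rows)``.
    """
    alphabet, S, gap_open, gap_ext = _subst_matrix(is_protein)
    existing = list(alignment_rows)
    added: list[str] = []
    for seq in new_seqs:
        prof = _profile(existing + added, alphabet) if (existing or added) else None
        if prof is None:
            added.append(seq)
            continue
        pb = _profile([seq], alphabet)
        path = _gotoh_profiles(prof, pb, S, gap_open, gap_ext)
        existing = _apply_path(existing, 0, path)
        added = _apply_path(added, 0, path)
        added.extend(_apply_path([seq], 1, path))
    return existing, added
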