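"""Glocal Viterbi alignment of a protein sequence against a profile HMM.

The alignment is global in the model (every model position is visited, as a
match or a delete state) and local in the sequence (the aligned segment may
start and end anywhere; flanking residues are free under the background).
Scores are log-odds in bits:

    score = log2 P(path emits segment | profile) - log2 P(segment | background)

Match and insert emissions are scored as log2(e(a)/bg(a)); the ambiguity
code X emits with background probability (log-odds 0). Transitions between
model positions carry their log2 probabilities; entry into position 1
(match or delete) and exit from position M are free, so the bit score is a
pure segment-vs-background log-odds ratio with no length model.

Delete chains within one sequence column are resolved with a prefix-maximum
recursion so the whole dynamic programme is vectorized over model positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AA_INDEX, ProfileHMM

NEG = -1.0e30  # effectively -inf without inf-inf NaN hazards

# pointer codes for traceback
_FROM_M, _FROM_I, _FROM_D, _BEGIN = 0, 1, 2, 3


@dataclass
class GlocalAlignment:
    """Best glocal path of one sequence against one profile."""

    score_bits: float
    #: 1-based residue position per match column; 0 marks a delete state.
    match_positions: np.ndarray
    #: first and last emitted residue (1-based), inserts included
    ali_start: int
    ali_end: int

    @property
    def n_match_columns(self) -> int:
        return int(np.count_nonzero(self.match_positions))

    @property
    def hmm_start(self) -> int:
        nz = np.nonzero(self.match_positions)[0]
        return int(nz[0]) + 1

    @property
    def hmm_end(self) -> int:
        nz = np.nonzero(self.match_positions)[0]
        return int(nz[-1]) + 1


def _log2_safe(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, NEG, dtype=float)
    pos = p > 0
    out[pos] = np.log2(p[pos])
    return out


class ProfileScorer:
    """Precomputed log-odds tables for one profile, reusable across queries."""

    def __init__(self, profile: ProfileHMM):
        self.profile = profile
        self.M = profile.M
        bg = profile.background
        # emission log-odds; X emits with background probability (odds 0)
        self.em = _log2_safe(profile.match_emissions / bg)
        self.em_x = np.zeros(self.M)
        self.ins = _log2_safe(profile.insert_emissions / bg)
        self.ins_x = np.zeros(self.M)
        t = profile.transitions
        (self.tMM, self.tMI, self.tMD, self.tIM, self.tII, self.tDM, self.tDD) = (
            _log2_safe(t[:, j]) for j in range(7)
        )
        # cumulative delete-chain cost: cumDD[k] = cost of D_1 -> ... -> D_{k+1}
        self.cumDD = np.concatenate([[0.0], np.cumsum(self.tDD[: self.M - 1])])

    def encode(self, sequence: str) -> np.ndarray:
        return np.array([AA_INDEX.get(c, -1) for c in sequence], dtype=np.int64)


def viterbi_glocal(
    scorer: ProfileScorer,
    encoded: np.ndarray,
    mask: np.ndarray | None = None,
) -> GlocalAlignment | None:
    """Best glocal alignment of ``encoded`` against the profile.

    ``mask`` marks residues that may not be emitted (used for iterative
    multi-hit extraction). Returns ``None`` when no path emits at least one
    residue with finite score.
    """
    M, L = scorer.M, len(encoded)
    if L == 0:
        return None
    VM = np.full(M, NEG)
    VI = np.full(M, NEG)
    VD = np.full(M, NEG)
    ptrM = np.empty((L, M), dtype=np.int8)
    ptrI = np.empty((L, M), dtype=np.int8)
    ptrD = np.empty((L, M), dtype=np.int16)  # delete-chain start index
    end_scores = np.full(L, NEG)
    end_state = np.zeros(L, dtype=np.int8)  # 0: M_M, 1: D_M

    cumDD = scorer.cumDD
    for i in range(L):
        a = encoded[i]
        if mask is not None and mask[i]:
            em_col = np.full(M, NEG)
            ins_col = np.full(M, NEG)
        elif a < 0:  # X: background emission
            em_col = scorer.em_x
            ins_col = scorer.ins_x
        else:
            em_col = scorer.em[:, a]
            ins_col = scorer.ins[:, a]

        # --- match states (need previous-column values, shifted by one row)
        candM = np.full(M, NEG)
        candI = np.full(M, NEG)
        candD = np.full(M, NEG)
        candM[1:] = VM[:-1] + scorer.tMM[:-1]
        candI[1:] = VI[:-1] + scorer.tIM[:-1]
        candD[1:] = VD[:-1] + scorer.tDM[:-1]
        candB = np.full(M, NEG)
        candB[0] = 0.0  # free glocal entry into M_1 at any i
        stacked = np.stack([candM, candI, candD, candB])
        ptrM[i] = np.argmax(stacked, axis=0)
        newVM = em_col + stacked[ptrM[i], np.arange(M)]

        # --- insert states (same model position, previous column)
        insM = VM + scorer.tMI
        insI = VI + scorer.tII
        take_i = insI > insM
        ptrI[i] = np.where(take_i, _FROM_I, _FROM_M)
        newVI = ins_col + np.where(take_i, insI, insM)

        # --- delete chain within this column, via prefix maximum:
        # chain entered at index m (0 = free entry into D_1, m>=1 = from
        # M_m), extended by DD transitions to the current index.
        value = np.empty(M)
        value[0] = 0.0
        value[1:] = newVM[:-1] + scorer.tMD[:-1]
        adj = value - cumDD
        run = np.maximum.accumulate(adj)
        start = np.where(adj >= run, np.arange(M), 0)
        start = np.maximum.accumulate(start)
        ptrD[i] = start
        newVD = run + cumDD

        VM, VI, VD = newVM, newVI, newVD
        if VM[M - 1] >= VD[M - 1]:
            end_scores[i], end_state[i] = VM[M - 1], 0
        else:
            end_scores[i], end_state[i] = VD[M - 1], 1

    best_i = int(np.argmax(end_scores))
    best = float(end_scores[best_i])
    if best <= NEG / 2:
        return None

    # --- traceback
    match_positions = np.zeros(M, dtype=np.int64)
    emitted: list[int] = []
    state = "D" if end_state[best_i] else "M"
    k, i = M - 1, best_i
    while True:
        if state == "M":
            match_positions[k] = i + 1
            emitted.append(i + 1)
            p = ptrM[i, k]
            if p == _BEGIN:
                break
            i -= 1
            if p == _FROM_M:
                k -= 1
            elif p == _FROM_I:
                state = "I"
                k -= 1
            else:
                state = "D"
                k -= 1
        elif state == "I":
            emitted.append(i + 1)
            p = ptrI[i, k]
            i -= 1
            if p == _FROM_M:
                state = "M"
        else:  # delete chain: jump to its start in the same column
            m = int(ptrD[i, k])
            if m == 0:
                break
            k = m - 1
            state = "M"
    if not emitted:
        return None
    return GlocalAlignment(
        score_bits=best,
        match_positions=match_positions,
        ali_start=min(emitted),
        ali_end=max(emitted),
    )
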