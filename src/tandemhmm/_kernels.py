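"""Numba kernels for the two dynamic programmes in the hot path.

Both are called once per read, so they are compiled (and cached on disk)
rather than written as vectorised numpy, which would still pay a Python-loop
cost per observation position.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30  # proxy for log(0); avoids -inf arithmetic inside kernels


@njit(cache=True)
def viterbi_kernel(log_start, log_trans, log_emit, obs):
    """Max-probability state path for a categorical-emission HMM.

    Parameters are log-space start vector (N,), transition matrix (N, N),
    emission matrix (N, M) and the observation index array (L,).  Ties are
    broken toward the lower state index at every step (argmax returns the
    first maximiser), which makes decoding deterministic.

    Returns ``(path, log_likelihood)``.
    """
    n_states = log_start.shape[0]
    length = obs.shape[0]
    delta = np.empty(n_states, dtype=np.float64)
    for s in range(n_states):
        delta[s] = log_start[s] + log_emit[s, obs[0]]
    back = np.zeros((length, n_states), dtype=np.int16)
    work = np.empty(n_states, dtype=np.float64)
    for t in range(1, length):
        sym = obs[t]
        prev = delta.copy()
        for j in range(n_states):
            best = NEG_INF
            arg = 0
            for i in range(n_states):
                v = prev[i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            work[j] = best + log_emit[j, sym]
            back[t, j] = arg
        delta[:] = work
    best = NEG_INF
    last = 0
    for s in range(n_states):
        if delta[s] > best:
            best = delta[s]
            last = s
    path = np.empty(length, dtype=np.int16)
    path[length - 1] = last
    for t in range(length - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best


# Traceback move codes for the banded aligner.
DIAG = 1      # consume query + template
GAP_TMPL = 2  # consume query only (gap in template: read insertion)
GAP_READ = 3  # consume template only (gap in read: read deletion)


@njit(cache=True)
def banded_global_align(q, t, match, mismatch, gap_in_perf, gap_in_read, band,
                        fit_template):
    """Banded alignment of a read region to a template, unequal gap costs.

    ``q``/``t`` are uint8-encoded query (read region) and template.  A gap
    in the template (scored ``gap_in_perf``) absorbs a read insertion; a gap
    in the read (scored ``gap_in_read``, much more negative) absorbs a read
    deletion.  With ``fit_template`` nonzero the template's leading and
    trailing overhang is free (the query aligns end-to-end inside the
    template, which is deliberately built longer than the region); the band
    is then centred on the main diagonal.  Otherwise the alignment is fully
    global and the band is centred on the corner-to-corner diagonal so
    length differences stay reachable.  Traceback ties prefer diagonal,
    then template gap, then read gap.

    Returns ``(score, start_j, end_j, moves)`` where ``moves`` is the move
    list from (0, start_j) to (n, end_j); ``score`` is ``NEG_INF`` when the
    band cannot connect the required corners.
    """
    n = q.shape[0]
    m = t.shape[0]
    if fit_template != 0:
        slope = 1.0
    else:
        slope = m / n if n > 0 else 0.0
    # score[i, j - lo(i)] over the band; pointer matrix alongside.
    width = 2 * band + 1
    score = np.full((n + 1, width), NEG_INF, dtype=np.float64)
    ptr = np.zeros((n + 1, width), dtype=np.int8)
    lo = np.empty(n + 1, dtype=np.int64)
    for i in range(n + 1):
        centre = int(round(i * slope))
        l = centre - band
        if l < 0:
            l = 0
        if l > m:
            l = m
        lo[i] = l
    # Row 0: leading template positions — free overhang in fit mode,
    # leading read gaps otherwise.
    for j in range(lo[0], min(m, lo[0] + width - 1) + 1):
        score[0, j - lo[0]] = 0.0 if fit_template != 0 else j * gap_in_read
        ptr[0, j - lo[0]] = GAP_READ
    for i in range(1, n + 1):
        jlo = lo[i]
        jhi = min(m, jlo + width - 1)
        for j in range(jlo, jhi + 1):
            best = NEG_INF
            move = 0
            if i >= 1 and j >= 1 and lo[i - 1] <= j - 1 <= min(m, lo[i - 1] + width - 1):
                s = score[i - 1, j - 1 - lo[i - 1]]
                if s > NEG_INF / 2:
                    s += match if q[i - 1] == t[j - 1] else mismatch
                    if s > best:
                        best = s
                        move = DIAG
            if lo[i - 1] <= j <= min(m, lo[i - 1] + width - 1):
                s = score[i - 1, j - lo[i - 1]]
                if s > NEG_INF / 2:
                    s += gap_in_perf
                    if s > best:
                        best = s
                        move = GAP_TMPL
            if j >= 1 and jlo <= j - 1:
                s = score[i, j - 1 - jlo]
                if s > NEG_INF / 2:
                    s += gap_in_read
                    if s > best:
                        best = s
                        move = GAP_READ
            score[i, j - jlo] = best
            ptr[i, j - jlo] = move
    empty = np.empty(0, dtype=np.int8)
    if fit_template != 0:
        # Free trailing overhang: best cell anywhere in the last banded row.
        end_j = -1
        best_end = NEG_INF
        for j in range(lo[n], min(m, lo[n] + width - 1) + 1):
            if score[n, j - lo[n]] > best_end:
                best_end = score[n, j - lo[n]]
                end_j = j
        if end_j < 0 or best_end <= NEG_INF / 2:
            return NEG_INF, 0, 0, empty
    else:
        if not (lo[n] <= m <= min(m, lo[n] + width - 1)) or score[n, m - lo[n]] <= NEG_INF / 2:
            return NEG_INF, 0, 0, empty
        end_j = m
        best_end = score[n, m - lo[n]]
    # Traceback.
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i = n
    j = end_j
    while i > 0 or (j > 0 and fit_template == 0):
        mv = ptr[i, j - lo[i]]
        moves[k] = mv
        k += 1
        if mv == DIAG:
            i -= 1
            j -= 1
        elif mv == GAP_TMPL:
            i -= 1
        elif mv == GAP_READ:
            j -= 1
        else:
            return NEG_INF, 0, 0, empty
    return best_end, j, end_j, moves[:k][::-1].copy()
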