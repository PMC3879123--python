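"""Numba kernels for the per-tick update of the crypt lattice.

The lattice state lives in flat numpy arrays so that the inner loops compile
with numba:

``heights``  int64[C]          occupied rows per column (top-anchored stacks)
``fdat``     float64[NF,C,R]   per-cell float fields (see F_* indices)
``idat``     int64[NI,C,R]     per-cell integer fields (see I_* indices)

Row 0 is the crypt top (lumen edge); a column of height ``h`` occupies rows
``0..h-1`` with no holes.  The kernels are the single implementation of the
structural moves (death pull-up, division cascade); the Python wrappers in
:mod:`cryptsim.lattice` call them directly.

Randomness uses numba's internal ``np.random`` state, seeded through
:func:`seed_rng`; a run seeded once and stepped repeatedly is exactly
reproducible.
"""

import numpy as np
from numba import njit

# float per-cell fields
NF = 7
F_DIVP = 0  # current divide probability
F_DIEP = 1  # current die probability
F_DFAC = 2  # multiplicative divide modifier (mutant phenotype)
F_DOFF = 3  # additive divide modifier
F_KFAC = 4  # multiplicative die modifier
F_KOFF = 5  # additive die modifier
F_SNAP = 6  # divide probability snapshot used for chemotherapy kills

# integer per-cell fields
NI = 3
I_CLONE = 0  # founder label (never a fresh label after initialization)
I_MUT = 1  # mutant lineage flag
I_VID = 2  # per-tick visit id (scratch, -1 outside the kernel)

# report slots written by step_kernel
NREP = 10
R_TOTAL = 0
R_Q = 1
R_P = 2
R_D = 3
R_MUT = 4
R_CLONES = 5
R_DEATH = 6
R_CHEMO = 7
R_CHEMO_HEALTHY = 8
R_BIRTHS = 9

STATUS_OK = 0
STATUS_CAPACITY = 1


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def remove_pullup(heights, fdat, idat, pos_col, pos_row, c, r):
    """Remove the cell at (c, r); cells below shift up one row."""
    h = heights[c]
    for rr in range(r, h - 1):
        for k in range(NF):
            fdat[k, c, rr] = fdat[k, c, rr + 1]
        for k in range(NI):
            idat[k, c, rr] = idat[k, c, rr + 1]
        vid = idat[I_VID, c, rr]
        if 0 <= vid < pos_row.shape[0]:
            pos_row[vid] = rr
    idat[I_VID, c, h - 1] = -1
    idat[I_CLONE, c, h - 1] = -1
    heights[c] = h - 1


@njit(cache=True)
def insert_cascade(heights, fdat, idat, pos_col, pos_row, c, r, step_dir, newf, newi):
    """Insert a progeny cell at (c + step_dir, r + 1) with displacement.

    The occupant of a cascade target is displaced one column over (wrapped)
    and one row down, iterating until a displaced cell lands at the first
    empty position at the bottom of its target column.  Returns STATUS_OK or
    STATUS_CAPACITY if the row capacity of the arrays would be exceeded.
    """
    C = heights.shape[0]
    rcap = fdat.shape[2]
    curf = newf.copy()
    curi = newi.copy()
    guard = 0
    while True:
        guard += 1
        if guard > C * rcap + 2:
            return STATUS_CAPACITY
        c = (c + step_dir) % C
        r = r + 1
        if r >= heights[c]:
            rr = heights[c]  # first empty position at the bottom
            if rr >= rcap:
                return STATUS_CAPACITY
            for k in range(NF):
                fdat[k, c, rr] = curf[k]
            for k in range(NI):
                idat[k, c, rr] = curi[k]
            vid = curi[I_VID]
            if 0 <= vid < pos_row.shape[0]:
                pos_col[vid] = c
                pos_row[vid] = rr
            heights[c] = rr + 1
            return STATUS_OK
        # swap the moving cell with the occupant; the occupant cascades on
        for k in range(NF):
            tmp = fdat[k, c, r]
            fdat[k, c, r] = curf[k]
            curf[k] = tmp
        for k in range(NI):
            itmp = idat[k, c, r]
            idat[k, c, r] = curi[k]
            curi[k] = itmp
        vid = idat[I_VID, c, r]
        if 0 <= vid < pos_row.shape[0]:
            pos_col[vid] = c
            pos_row[vid] = r


@njit(cache=True)
def step_kernel(
    heights,
    fdat,
    idat,
    clone_seen,
    div_min,
    div_max,
    div_pow,
    die_min,
    die_max,
    die_pow,
    grad_len,
    die_grad_len,
    niche_row,
    niche_band,
    diff_threshold,
    f_q,
    f_p,
    f_d,
    f_die,
    polar,
    chemo_active,
    lethality,
    divide_mult,
    out,
):
    """Advance the crypt one time unit.

    Phase 1 visits every cell alive at the start of the tick exactly once in
    a fresh uniformly random order; each visited cell draws chemotherapy
    death (if a dose is active), then normal death, then division.  Newborn
    progeny are not visited in the tick of their birth.  Phase 2 then
    synchronously updates every cell's divide probability by delayed
    feedback toward its positional target (strength chosen by the cell's
    pre-update type label) and recomputes die probabilities from position.
    The report buffer ``out`` receives end-of-tick counts.

    ``grad_len`` / ``die_grad_len`` select how the divide and die gradients
    span the crypt: -2 rescales to the crypt's mean column height (the
    gradient length follows the total number of cells), -1 rescales to each
    column's own height, 0 to the current deepest column, and positive
    values fix the span in rows.  Cells deeper than the span sit at the
    gradient bottom, where the divide gradient is maximal and the die
    gradient zero.  The stem-cell niche is
    anchored at absolute depth: every cell at row >= ``niche_row`` (and, if
    ``niche_band`` > 0, above ``niche_row + niche_band``) responds to the
    quiescent divide target (0) instead of the divide gradient.
    """
    C = heights.shape[0]
    n0 = 0
    for c in range(C):
        n0 += heights[c]

    deaths_normal = 0
    deaths_chemo = 0
    deaths_chemo_healthy = 0
    births = 0
    status = STATUS_OK

    if n0 > 0:
        # ---- phase 1: randomized pass over the tick-start population
        pos_col = np.empty(n0, np.int64)
        pos_row = np.empty(n0, np.int64)
        i = 0
        for c in range(C):
            for r in range(heights[c]):
                idat[I_VID, c, r] = i
                pos_col[i] = c
                pos_row[i] = r
                i += 1
        order = np.arange(n0)
        for j in range(n0 - 1, 0, -1):
            k = np.random.randint(0, j + 1)
            t = order[j]
            order[j] = order[k]
            order[k] = t

        newf = np.empty(NF, np.float64)
        newi = np.empty(NI, np.int64)
        for oi in range(n0):
            vid = order[oi]
            c = pos_col[vid]
            if c < 0:
                continue  # killed earlier this tick
            r = pos_row[vid]
            if chemo_active != 0:
                pk = fdat[F_SNAP, c, r] * lethality
                if pk > 1.0:
                    pk = 1.0
                # cells the dose cannot kill draw nothing, so a null dose
                # leaves the random stream (and trajectory) untouched
                if pk > 0.0 and np.random.random() < pk:
                    deaths_chemo += 1
                    if idat[I_MUT, c, r] == 0:
                        deaths_chemo_healthy += 1
                    pos_col[vid] = -1
                    remove_pullup(heights, fdat, idat, pos_col, pos_row, c, r)
                    continue
            if np.random.random() < fdat[F_DIEP, c, r]:
                deaths_normal += 1
                pos_col[vid] = -1
                remove_pullup(heights, fdat, idat, pos_col, pos_row, c, r)
                continue
            if np.random.random() < fdat[F_DIVP, c, r]:
                births += 1
                step_dir = 1
                if polar == 0 and np.random.random() < 0.5:
                    step_dir = -1
                for k in range(NF):
                    newf[k] = fdat[k, c, r]
                newf[F_SNAP] = fdat[F_DIVP, c, r]  # birth-time chemo snapshot
                newi[I_CLONE] = idat[I_CLONE, c, r]
                newi[I_MUT] = idat[I_MUT, c, r]
                newi[I_VID] = -1
                st = insert_cascade(
                    heights, fdat, idat, pos_col, pos_row, c, r, step_dir, newf, newi
                )
                if st != STATUS_OK:
                    status = st
                    break

    # ---- phase 2: synchronous feedback toward post-movement targets
    depth = 0
    for c in range(C):
        if heights[c] > depth:
            depth = heights[c]

    n_total = 0
    n_q = 0
    n_p = 0
    n_d = 0
    n_mut = 0
    n_clones = 0

    if depth > 0:
        for k in range(clone_seen.shape[0]):
            clone_seen[k] = 0

        mean_h = 0.0
        for c in range(C):
            mean_h += heights[c]
        mean_h /= C
        if mean_h < 1.0:
            mean_h = 1.0

        for c in range(C):
            h = heights[c]
            if grad_len > 0:
                span = float(grad_len)
            elif grad_len == 0:
                span = float(depth)
            elif grad_len == -1:
                span = float(h)  # per-column rescaling
            else:
                span = mean_h  # gradient length follows total cells
            if die_grad_len > 0:
                die_span = float(die_grad_len)
            elif die_grad_len == 0:
                die_span = float(depth)
            elif die_grad_len == -1:
                die_span = float(h)
            else:
                die_span = mean_h
            for r in range(h):
                n_total += 1
                y = (r + 0.5) / span
                if y > 1.0:
                    y = 1.0
                yk = (r + 0.5) / die_span
                if yk > 1.0:
                    yk = 1.0
                p = fdat[F_DIVP, c, r]
                if niche_row >= 0:
                    nrow = niche_row  # anchored at anatomical depth
                else:
                    nrow = span + niche_row  # moves with the gradient span
                in_niche = r >= nrow and (niche_band <= 0 or r < nrow + niche_band)
                # feedback strength from the pre-update type label
                if in_niche:
                    f = f_q
                elif p >= diff_threshold:
                    f = f_p
                else:
                    f = f_d
                # mutants are insensitive to the niche's quiescence signal
                # (constitutive pathway activation) and always read the
                # divide gradient
                if in_niche and idat[I_MUT, c, r] == 0:
                    base = 0.0
                else:
                    base = div_min + (div_max - div_min) * y**div_pow
                tgt = base * divide_mult * fdat[F_DFAC, c, r] + fdat[F_DOFF, c, r]
                if tgt > 1.0:
                    tgt = 1.0
                elif tgt < 0.0:
                    tgt = 0.0
                p = p + f * (tgt - p)
                fdat[F_DIVP, c, r] = p
                die_base = die_min + (die_max - die_min) * (1.0 - yk) ** die_pow
                dtg = die_base * fdat[F_KFAC, c, r] + fdat[F_KOFF, c, r]
                if dtg > 1.0:
                    dtg = 1.0
                elif dtg < 0.0:
                    dtg = 0.0
                fk = f if f_die < 0.0 else f_die  # die delay: per-type or fixed
                fdat[F_DIEP, c, r] = fdat[F_DIEP, c, r] + fk * (
                    dtg - fdat[F_DIEP, c, r]
                )
                # end-of-tick classification (Ki-67-like: dividing cells in
                # the niche are active stem cells, counted as proliferating)
                if p >= diff_threshold:
                    n_p += 1
                elif in_niche:
                    n_q += 1
                else:
                    n_d += 1
                if idat[I_MUT, c, r] != 0:
                    n_mut += 1
                cl = idat[I_CLONE, c, r]
                if 0 <= cl < clone_seen.shape[0] and clone_seen[cl] == 0:
                    clone_seen[cl] = 1
                    n_clones += 1
                idat[I_VID, c, r] = -1

    out[R_TOTAL] = n_total
    out[R_Q] = n_q
    out[R_P] = n_p
    out[R_D] = n_d
    out[R_MUT] = n_mut
    out[R_CLONES] = n_clones
    out[R_DEATH] = deaths_normal
    out[R_CHEMO] = deaths_chemo
    out[R_CHEMO_HEALTHY] = deaths_chemo_healthy
    out[R_BIRTHS] = births
    return status
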