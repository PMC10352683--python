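"""Numba kernels for the lattice engine.

The per-step work is split into two compiled passes over the
structure-of-arrays state:

* :func:`gene_class_kernel` — timeline stages 1–6: the gene-expression
  network, the expression update, genetic instability, the phenotype
  update, class transitions (mutation status, cancer-stem conversion)
  and dedifferentiation.  These stages are local to each cell; the
  dedifferentiation trigger uses neighbor counts snapshotted at the
  start of the step, so the pass is effectively synchronous.
* :func:`action_kernel` — timeline stage 7: each cell samples one
  phenotypic action and executes it, in a fresh uniformly random cell
  permutation with first-actor-claims conflict resolution.

Randomness inside the kernels comes from an inline xorshift64* stream,
seeded per step (via a splitmix64 scramble) from the simulation's master
generator.  This keeps whole trajectories bit-reproducible for a given
configuration and seed while making the tens of random draws per cell
per step cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _seed_state(seed):
    """Scramble a small integer seed into a nonzero 64-bit PRNG state."""
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(1)
    return z


@njit(cache=True, inline="always")
def _rand(st):
    """Uniform double in [0, 1) from a xorshift64* state array."""
    x = st[0]
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    st[0] = x
    return float((x * _U64(0x2545F4914F6CDD1D)) >> _U64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _randint8(st):
    """Unbiased integer in 0..7."""
    x = st[0]
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    st[0] = x
    return np.int64(((x * _U64(0x2545F4914F6CDD1D)) >> _U64(32)) & _U64(7))

# cell-class codes (kept in sync with fieldca.cell_rules)
_NTC, _MNTC, _NSC, _MNSC, _CSC, _TC, _EMPTY = 0, 1, 2, 3, 4, 5, 6

# action codes
_PROLIF, _QUIESCE, _APOPT, _DIFF = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _gamma(x, nu):
    return x / (1.0 + nu * x * x)


@njit(cache=True, inline="always")
def _shift_phenotype(P, k, init_table, old_s, new_s):
    """Move a cell's phenotype vector to a new class baseline, keeping its
    accumulated deviations; clip and renormalize."""
    total = 0.0
    for a in range(4):
        v = P[k, a] + init_table[new_s, a] - init_table[old_s, a]
        if v < 0.0:
            v = 0.0
        P[k, a] = v
        total += v
    if total > 0.0:
        for a in range(4):
            P[k, a] /= total
    else:
        for a in range(4):
            P[k, a] = init_table[new_s, a]


@njit(cache=True, fastmath=True)
def gene_class_kernel(
    seed,
    cls,
    age,
    E,
    P,
    conc,  # (C, n) active carcinogen concentration per site
    wx_carc,  # (G, C)
    wy_rows,  # (nnz,) row indices of nonzero WY entries
    wy_cols,  # (nnz,) column indices
    wy_vals,  # (nnz,) values
    Tvec,  # (G,)
    pairs,  # (npairs, 2) directed instability pairs
    U,  # (4, G)
    D,  # (4, G)
    init_table,  # (6, 4)
    stem_nb,  # (n,) stem-class neighbor counts (start-of-step snapshot)
    empty_nb,  # (n,) empty neighbor counts (snapshot)
    nu,
    beta,
    p_sign,
    scale,
    age_weight,
    M_bar,
    Upsilon,
    p_inst,
    inst_cap,
    p_ph,
    csc_prob,
    restrict_csc,
    dediff_prob,
    stem_thresh,
    empty_thresh,
    empty_at_least,
):
    st = np.empty(1, dtype=np.uint64)
    st[0] = _seed_state(seed)
    n = cls.shape[0]
    G = E.shape[1]
    C = conc.shape[0]
    npairs = pairs.shape[0]
    nnz = wy_vals.shape[0]
    H = np.empty(G)
    A = np.empty(G)
    for k in range(n):
        s = cls[k]
        if s == _EMPTY:
            continue

        # --- stage 1: gene network -------------------------------------
        for j in range(G):
            arg = 0.0
            for i in range(C):
                arg += wx_carc[j, i] * conc[i, k]
            sgn = 1.0 if _rand(st) < p_sign else -1.0
            arg += sgn * age_weight * age[k]
            H[j] = _gamma(arg, nu)

        # --- stage 2: expression update --------------------------------
        for j in range(G):
            A[j] = 0.0
        for m in range(nnz):
            A[wy_rows[m]] += wy_vals[m] * H[wy_cols[m]]
        for j in range(G):
            acc = A[j]
            e = E[k, j]
            if e >= M_bar:
                acc += beta
            elif e <= -M_bar:
                acc -= beta
            y = _gamma(acc, nu)
            E[k, j] = e + _rand(st) * y * scale

        # --- stage 3: genetic instability ------------------------------
        for pidx in range(npairs):
            if _rand(st) < p_inst:
                i = pairs[pidx, 0]
                j = pairs[pidx, 1]
                u = _rand(st)
                ei = E[k, i]
                pm = ei >= M_bar if Tvec[i] == 1 else ei <= -M_bar
                if pm:
                    if Tvec[j] == 1:
                        E[k, j] += u * inst_cap
                    else:
                        E[k, j] -= u * inst_cap
                else:
                    ej = E[k, j]
                    step = u * inst_cap
                    if ej > step:
                        E[k, j] = ej - step
                    elif ej < -step:
                        E[k, j] = ej + step
                    else:
                        E[k, j] = 0.0

        # --- stage 4: phenotype update ---------------------------------
        changed = False
        for j in range(G):
            ej = E[k, j]
            if ej >= M_bar:
                up = True
            elif ej <= -M_bar:
                up = False
            else:
                continue
            if _rand(st) >= p_ph:
                continue
            if up:
                dp = U[0, j]
                dq = U[1, j]
                da = U[2, j]
                dd = U[3, j]
            else:
                dp = D[0, j]
                dq = D[1, j]
                da = D[2, j]
                dd = D[3, j]
            P[k, 0] += dp
            P[k, 2] += da
            P[k, 3] += dd
            P[k, 1] += dq - (dp + da + dd)
            changed = True
        if changed:
            total = 0.0
            for a in range(4):
                if P[k, a] < 0.0:
                    P[k, a] = 0.0
                total += P[k, a]
            if total > 0.0:
                for a in range(4):
                    P[k, a] /= total

        # --- stage 5: class transitions --------------------------------
        cnt = 0
        for j in range(G):
            if Tvec[j] == 1:
                if E[k, j] >= M_bar:
                    cnt += 1
            elif E[k, j] <= -M_bar:
                cnt += 1
        mutated = cnt >= Upsilon
        s = cls[k]
        new_s = s
        if s == _NTC and mutated:
            new_s = _MNTC
        elif s == _MNTC and not mutated:
            new_s = _NTC
        elif s == _NSC and mutated:
            new_s = _MNSC
        elif s == _MNSC and not mutated:
            new_s = _NSC
        if new_s != s:
            _shift_phenotype(P, k, init_table, s, new_s)
            cls[k] = new_s
            s = new_s

        if s == _MNSC or (s == _NSC and not restrict_csc):
            if _rand(st) < csc_prob:
                _shift_phenotype(P, k, init_table, s, _CSC)
                cls[k] = _CSC
                s = _CSC

        # --- stage 6: dedifferentiation --------------------------------
        if s == _NTC or s == _MNTC or s == _TC:
            if empty_at_least:
                trig = stem_nb[k] <= stem_thresh or empty_nb[k] >= empty_thresh
            else:
                trig = stem_nb[k] <= stem_thresh or empty_nb[k] <= empty_thresh
            if trig and _rand(st) < dediff_prob:
                if s == _NTC:
                    new_s = _NSC
                elif s == _MNTC:
                    new_s = _MNSC
                else:
                    new_s = _CSC
                _shift_phenotype(P, k, init_table, s, new_s)
                cls[k] = new_s


@njit(cache=True, inline="always")
def _fitness(cls_k, age_k, P, k, wp, wa, wage, bonus, c_tilde, c1, c2):
    if cls_k == _NSC or cls_k == _MNSC or cls_k == _CSC:
        lifespan = c2
    else:
        lifespan = c1
    f = wp * P[k, 0] - wa * P[k, 2] - wage * age_k * c_tilde / lifespan
    if cls_k == _CSC or cls_k == _TC:
        f += bonus
    return f


@njit(cache=True, inline="always")
def _copy_cell(src, dst, cls, age, E, P, tac, tacgen, lin):
    cls[dst] = cls[src]
    age[dst] = age[src]
    for j in range(E.shape[1]):
        E[dst, j] = E[src, j]
    for a in range(4):
        P[dst, a] = P[src, a]
    tac[dst] = tac[src]
    tacgen[dst] = tacgen[src]
    lin[dst] = lin[src]


@njit(cache=True, inline="always")
def _clear_cell(k, cls, age, E, P, tac, tacgen, lin):
    cls[k] = _EMPTY
    age[k] = 0
    for j in range(E.shape[1]):
        E[k, j] = 0.0
    for a in range(4):
        P[k, a] = 0.0
    tac[k] = 0
    tacgen[k] = 0
    lin[k] = -1


@njit(cache=True, fastmath=True)
def action_kernel(
    seed,
    N,
    cls,
    age,
    E,
    P,
    tac,
    tacgen,
    lin,
    init_table,
    theta,
    move_prob,
    kill_prob,
    tac_boost,
    wp,
    wa,
    wage,
    bonus,
    c_tilde,
    c1,
    c2,
):
    """Stage 7: sample and execute one phenotypic action per cell.

    Returns the per-action counts of chosen actions (length 4).  Cells
    are visited in a fresh random permutation; a site acted upon this
    stage (newly born, moved-in, or already processed) is claimed and
    skipped for the rest of the stage.
    """
    st = np.empty(1, dtype=np.uint64)
    st[0] = _seed_state(seed)
    n = N * N
    counts = np.zeros(4, dtype=np.int64)

    # Moore neighborhood excluding the focal cell
    dxs = np.array([-1, 0, 1, -1, 1, -1, 0, 1])
    dys = np.array([-1, -1, -1, 0, 0, 1, 1, 1])

    # Fisher-Yates permutation
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = np.int64(_rand(st) * (i + 1))
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp

    done = np.zeros(n, dtype=np.uint8)

    for idx in range(n):
        k = perm[idx]
        if done[k] == 1 or cls[k] == _EMPTY:
            continue
        done[k] = 1
        s = cls[k]

        # action probabilities with the transit-amplifying boost
        p0 = P[k, 0]
        p1 = P[k, 1]
        p2 = P[k, 2]
        p3 = P[k, 3]
        if tac[k] == 1:
            boost = tac_boost if p1 > tac_boost else p1
            p0 += boost
            p1 -= boost

        r = _rand(st) * (p0 + p1 + p2 + p3)
        if r < p0:
            action = _PROLIF
        elif r < p0 + p1:
            action = _QUIESCE
        elif r < p0 + p1 + p2:
            action = _APOPT
        else:
            action = _DIFF
        counts[action] += 1

        if action == _QUIESCE:
            if _rand(st) < move_prob:
                nb = _randint8(st)
                x = k % N
                y = k // N
                tx = (x + dxs[nb]) % N
                ty = (y + dys[nb]) % N
                tgt = ty * N + tx
                if cls[tgt] == _EMPTY:
                    _copy_cell(k, tgt, cls, age, E, P, tac, tacgen, lin)
                    _clear_cell(k, cls, age, E, P, tac, tacgen, lin)
                    done[tgt] = 1
                elif s == _CSC or s == _TC:
                    vict = cls[tgt]
                    ok = True
                    if vict == _CSC or vict == _TC:
                        fv = _fitness(vict, age[tgt], P, tgt, wp, wa, wage, bonus, c_tilde, c1, c2)
                        fm = _fitness(s, age[k], P, k, wp, wa, wage, bonus, c_tilde, c1, c2)
                        ok = fv < fm
                    if ok and _rand(st) < kill_prob:
                        _copy_cell(k, tgt, cls, age, E, P, tac, tacgen, lin)
                        _clear_cell(k, cls, age, E, P, tac, tacgen, lin)
                        done[tgt] = 1
            continue

        if action == _APOPT:
            _clear_cell(k, cls, age, E, P, tac, tacgen, lin)
            continue

        if action == _DIFF and not (s == _NSC or s == _MNSC or s == _CSC):
            # differentiation mass acquired by a non-stem cell through
            # phenotype increments has no target class; treat as rest
            continue

        # proliferation or differentiation: place a daughter
        nb = _randint8(st)
        x = k % N
        y = k // N
        tx = (x + dxs[nb]) % N
        ty = (y + dys[nb]) % N
        tgt = ty * N + tx

        success = False
        if cls[tgt] == _EMPTY:
            success = True
        else:
            ft = _fitness(cls[tgt], age[tgt], P, tgt, wp, wa, wage, bonus, c_tilde, c1, c2)
            fp = _fitness(s, age[k], P, k, wp, wa, wage, bonus, c_tilde, c1, c2)
            if ft < fp:
                success = True
            elif (s == _CSC or s == _TC) and _rand(st) < kill_prob:
                success = True
        if not success:
            continue

        if action == _PROLIF:
            _copy_cell(k, tgt, cls, age, E, P, tac, tacgen, lin)
            age[k] = 0
            age[tgt] = 0
            done[tgt] = 1
            if tac[k] == 1:
                g = tacgen[k] + 1
                if g >= theta:
                    tac[k] = 0
                    tacgen[k] = 0
                    tac[tgt] = 0
                    tacgen[tgt] = 0
                else:
                    tacgen[k] = g
                    tacgen[tgt] = g
        else:  # differentiation: daughter is a transit-amplifying cell
            if s == _NSC:
                child_cls = _NTC
            elif s == _MNSC:
                child_cls = _MNTC
            else:
                child_cls = _TC
            _copy_cell(k, tgt, cls, age, E, P, tac, tacgen, lin)
            cls[tgt] = child_cls
            _shift_phenotype(P, tgt, init_table, s, child_cls)
            tac[tgt] = 1
            tacgen[tgt] = 0
            age[k] = 0
            age[tgt] = 0
            done[tgt] = 1

    return counts
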