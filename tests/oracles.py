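"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain nested loops over residues, straight
from the counting/allocation definitions, sharing no code with the package
internals. Slow on purpose; only ever applied to small inputs (except the
metric oracles, which are O(n^2) pair scans).
"""

import numpy as np


def _mu_ok(labels, table, idx, env):
    if isinstance(labels, str):
        return labels == env
    return labels[table.keys[idx]] == env


def _residue_lists(table):
    """Per-chain lists of global row indices, in chain order."""
    chains = []
    for ci in range(len(table.chain_ids)):
        chains.append([g for g in range(table.n_residues)
                       if table.chain_of[g] == ci])
    return chains


def oracle_count(table, labels, combo, env, config):
    """Brute-force raw counts of one combo/environment for one structure."""
    dims = tuple(config.descriptor_dim(l) for l in combo)
    counts = np.zeros(dims, dtype=np.int64)
    W = config.window
    s, t, a = table.s, table.t, table.a

    def ok(idx, letters):
        if not _mu_ok(labels, table, idx, env):
            return False
        return all(t[idx] >= 0 if l == "t" else True for l in letters)

    chains = _residue_lists(table)
    if "d" in combo:
        for pi, pj, db in zip(table.pair_i, table.pair_j, table.pair_dbin):
            if len(combo) == 2:
                x = combo.replace("d", "")
                d_axis = combo.index("d")
                if ok(pi, x) and ok(pj, x):
                    for end in (pi, pj):
                        idx = [None, None]
                        idx[d_axis] = db
                        idx[1 - d_axis] = {"s": s, "t": t, "a": a}[x][end]
                        counts[tuple(idx)] += 1
            else:
                x, _, y = combo
                vx = {"s": s, "t": t, "a": a}[x]
                vy = {"s": s, "t": t, "a": a}[y]
                for e1, e2 in ((pi, pj), (pj, pi)):
                    if ok(e1, x) and ok(e2, y):
                        counts[vx[e1], db, vy[e2]] += 1
        return counts

    v = {"s": s, "t": t, "a": a}
    for chain in chains:
        n = len(chain)
        if len(combo) == 2 and combo[0] == combo[1]:       # ss, tt, aa
            x = combo[0]
            for i in range(n):
                for j in range(i + 1, n):
                    if config.pair_min_sep <= j - i <= W:
                        gi, gj = chain[i], chain[j]
                        if ok(gi, x) and ok(gj, x):
                            counts[v[x][gi], v[x][gj]] += 1
                            counts[v[x][gj], v[x][gi]] += 1
        elif len(combo) == 2:                              # st, sa
            p, c = combo
            for i in range(n):
                for j in range(n):
                    if abs(i - j) <= W:
                        gi, gj = chain[i], chain[j]
                        if ok(gi, c) and ok(gj, p):
                            counts[v[p][gj], v[c][gi]] += 1
        elif combo[0] == combo[1]:                         # sst, ssa
            p, _, c = combo
            for i in range(n):
                gi = chain[i]
                if not ok(gi, c):
                    continue
                for j in range(n):
                    for k in range(j + 1, n):
                        if abs(i - j) <= W and abs(i - k) <= W:
                            gj, gk = chain[j], chain[k]
                            if ok(gj, p) and ok(gk, p):
                                counts[v[p][gj], v[p][gk], v[c][gi]] += 1
                                counts[v[p][gk], v[p][gj], v[c][gi]] += 1
        else:                                              # saa, stt
            c, x, _ = combo
            for k in range(n):
                gk = chain[k]
                if not ok(gk, c):
                    continue
                for i in range(n):
                    for j in range(i + 1, n):
                        if abs(i - k) <= W and abs(j - k) <= W:
                            gi, gj = chain[i], chain[j]
                            if ok(gi, x) and ok(gj, x):
                                counts[v[c][gk], v[x][gi], v[x][gj]] += 1
                                counts[v[c][gk], v[x][gj], v[x][gi]] += 1
    return counts


def oracle_potential(raw_counts, pseudocount, kT=1.0):
    """Direct inverse-Boltzmann evaluation from regularized counts."""
    reg = raw_counts.astype(float) + pseudocount
    F = reg / reg.sum()
    if F.ndim == 2:
        fx = F.sum(axis=1)
        fy = F.sum(axis=0)
        out = np.zeros_like(F)
        for x in range(F.shape[0]):
            for y in range(F.shape[1]):
                out[x, y] = -kT * np.log(F[x, y] / (fx[x] * fy[y]))
        return out
    fx = F.sum(axis=(1, 2))
    fy = F.sum(axis=(0, 2))
    fz = F.sum(axis=(0, 1))
    fxy = F.sum(axis=2)
    fxz = F.sum(axis=1)
    fyz = F.sum(axis=0)
    out = np.zeros_like(F)
    for x in range(F.shape[0]):
        for y in range(F.shape[1]):
            for z in range(F.shape[2]):
                out[x, y, z] = -kT * np.log(
                    F[x, y, z] * fx[x] * fy[y] * fz[z]
                    / (fxy[x, y] * fxz[x, z] * fyz[y, z]))
    return out


def oracle_energy(table, combo, values, config):
    """Brute-force per-residue allocation of a potential table.

    Allocation: single-carrier combos give the full dW to the center; pair
    combos split half/half; symmetrized orders each carry half of dW; each
    distance endpoint observation carries dW/2, split half/half.
    Returns (per-residue energies, total interaction sum).
    """
    W = config.window
    s, t, a = table.s, table.t, table.a
    v = {"s": s, "t": t, "a": a}
    n = table.n_residues
    out = np.zeros(n)
    total = 0.0

    def defined(idx, letters):
        return all(t[idx] >= 0 if l == "t" else True for l in letters)

    chains = _residue_lists(table)
    if "d" in combo:
        for pi, pj, db in zip(table.pair_i, table.pair_j, table.pair_dbin):
            if len(combo) == 2:
                x = combo.replace("d", "")
                d_axis = combo.index("d")
                if defined(pi, x) and defined(pj, x):
                    for end in (pi, pj):
                        idx = [None, None]
                        idx[d_axis] = db
                        idx[1 - d_axis] = v[x][end]
                        e = values[tuple(idx)] / 2.0
                        out[pi] += e / 2.0
                        out[pj] += e / 2.0
                        total += e
            else:
                x, _, y = combo
                for e1, e2 in ((pi, pj), (pj, pi)):
                    if defined(e1, x) and defined(e2, y):
                        e = values[v[x][e1], db, v[y][e2]] / 2.0
                        out[e1] += e / 2.0
                        out[e2] += e / 2.0
                        total += e
        return out, total

    for chain in chains:
        m = len(chain)
        if len(combo) == 2 and combo[0] == combo[1]:
            x = combo[0]
            for i in range(m):
                for j in range(i + 1, m):
                    if config.pair_min_sep <= j - i <= W:
                        gi, gj = chain[i], chain[j]
                        if defined(gi, x) and defined(gj, x):
                            e = values[v[x][gi], v[x][gj]]
                            out[gi] += e / 2.0
                            out[gj] += e / 2.0
                            total += e
        elif len(combo) == 2:
            p, c = combo
            for i in range(m):
                for j in range(m):
                    if abs(i - j) <= W:
                        gi, gj = chain[i], chain[j]
                        if defined(gi, c) and defined(gj, p):
                            e = values[v[p][gj], v[c][gi]]
                            out[gi] += e
                            total += e
        elif combo[0] == combo[1]:
            p, _, c = combo
            for i in range(m):
                gi = chain[i]
                if not defined(gi, c):
                    continue
                for j in range(m):
                    for k in range(j + 1, m):
                        if abs(i - j) <= W and abs(i - k) <= W:
                            gj, gk = chain[j], chain[k]
                            if defined(gj, p) and defined(gk, p):
                                e = values[v[p][gj], v[p][gk], v[c][gi]]
                                out[gi] += e
                                total += e
        else:
            c, x, _ = combo
            for k in range(m):
                gk = chain[k]
                if not defined(gk, c):
                    continue
                for i in range(m):
                    for j in range(i + 1, m):
                        if abs(i - k) <= W and abs(j - k) <= W:
                            gi, gj = chain[i], chain[j]
                            if defined(gi, x) and defined(gj, x):
                                e = values[v[c][gk], v[x][gi], v[x][gj]]
                                out[gi] += e / 2.0
                                out[gj] += e / 2.0
                                total += e
    return out, total


def oracle_bacc(pred, truth):
    tp = fn = tn = fp = 0
    for p, o in zip(pred, truth):
        if o == 1:
            tp += p == 1
            fn += p == 0
        else:
            tn += p == 0
            fp += p == 1
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def oracle_auc(scores, labels):
    """Probability a random positive outscores a random negative; ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def oracle_best_threshold_bacc(scores, labels):
    """Exhaustive scan over all midpoints; returns the maximal BACC."""
    u = np.unique(scores)
    best = 0.0
    for k in range(len(u) - 1):
        thr = (u[k] + u[k + 1]) / 2
        pred = (np.asarray(scores) >= thr).astype(int)
        best = max(best, oracle_bacc(pred, labels))
    return best
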