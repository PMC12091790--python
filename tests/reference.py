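"""Independent brute-force reference for the probability-flow update.

Transcribes the eight joint transition equations term by term with plain
Python scalar loops — no vectorisation, no shared code paths with the
engine — to serve as a small-system oracle.  State columns follow
``mumseir.STATE_COLS``: MS, ME, MI, MR, US, UE, UI, UR.
"""

import math


def reference_mmca_step(state, upper, lower, p, t):
    """One step of the eight-state update, scalar transcription."""
    n = len(state)
    beta_u, beta_m = p.beta_U, p.k * p.beta_U
    sigma, mu = p.sigma, p.mu

    z = sum(s[1] + s[2] + s[5] + s[6] for s in state) / n
    m = 1.0 / (1.0 + math.exp(-p.delta * (z - 0.5)))
    w = m if (p.theta - z) > 0 else 0.0
    r = 0.0 if z == 0 else p.eta * z**p.alpha
    cost = p.c0
    for tau in range(1, t + 1):
        cost += p.a ** (t - tau) * p.phi * math.exp(-t / p.eta)

    q_u, q_m, b, p_m = [], [], [], []
    for i in range(n):
        qu = qm = 1.0
        for j in range(n):
            if lower[i][j]:
                mass = state[j][1] + state[j][2] + state[j][5] + state[j][6]
                qu *= 1.0 - mass * beta_u
                qm *= 1.0 - mass * beta_m
        q_u.append(qu)
        q_m.append(qm)
        b.append(qm - qu)
        p_m.append(state[i][0] + state[i][1] + state[i][2] + state[i][3])

    payoff = []
    for i in range(n):
        d = -cost * p_m[i] + b[i] * p_m[i]
        for j in range(n):
            if upper[i][j]:
                d += b[j] * p_m[j]
        payoff.append(d)

    adopt, drop = [], []
    for i in range(n):
        neigh = [payoff[j] for j in range(n) if upper[i][j]]
        dbar = sum(neigh) / len(neigh) if neigh else payoff[i]
        f = 1.0 / (1.0 + math.exp(-(payoff[i] - dbar) / p.omega))
        adopt.append(p.zeta * f + (1 - p.zeta) * (1 - r))  # U -> M
        drop.append(p.zeta * f + (1 - p.zeta) * r)         # M -> U

    out = []
    for i in range(n):
        ms, me, mi, mr, us, ue, ui, ur = state[i]
        gm, gu = drop[i], adopt[i]  # slots of the printed equations
        qm, qu = q_m[i], q_u[i]
        nms = (ms * gm * qm * (1 - w) + ms * (1 - gm) * qm
               + us * (1 - gu) * qm * (1 - w) + us * gu * qm)
        nme = (ms * gm * (1 - qm) * (1 - w) + ms * (1 - gm) * (1 - qm)
               + us * (1 - gu) * (1 - qm) * (1 - w) + us * gu * (1 - qm)
               + ue * gu * (1 - sigma) + me * (1 - gm) * (1 - sigma)
               + ue * (1 - gu) * (1 - sigma) * (1 - w)
               + me * gm * (1 - sigma) * (1 - w))
        nmi = (mi * gm * (1 - mu) * (1 - w) + mi * (1 - gm) * (1 - mu)
               + ue * gu * sigma + ue * (1 - gu) * (1 - w) * sigma
               + ui * gu * (1 - mu) + ui * (1 - gu) * (1 - w) * (1 - mu)
               + me * (1 - gm) * sigma + me * gm * sigma * (1 - w))
        nus = ms * gm * qu * w + us * (1 - gu) * qu * w
        nue = (ms * gm * (1 - qu) * w + us * (1 - gu) * (1 - qu) * w
               + ue * (1 - gu) * w * (1 - sigma) + me * gm * (1 - sigma) * w)
        nui = (me * gm * sigma * w + ue * (1 - gu) * sigma * w
               + mi * gm * (1 - mu) * w + ui * (1 - gu) * (1 - mu) * w)
        nur = (mr * gm * w + ur * (1 - gu) * w
               + ui * (1 - gu) * w * mu + mi * gm * mu * w)
        nmr = (mi * gm * mu * (1 - w) + mi * (1 - gm) * mu
               + ui * (1 - gu) * mu * (1 - w) + ui * gu * mu
               + mr * gm * (1 - w) + mr * (1 - gm)
               + ur * (1 - gu) * (1 - w) + ur * gu)
        out.append([nms, nme, nmi, nmr, nus, nue, nui, nur])
    return out
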