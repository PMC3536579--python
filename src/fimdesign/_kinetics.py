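"""JIT-compiled right-hand sides for the six-gene network ODEs.

State layout (12 variables, interleaved per gene g = 0..5):
    y[2g]   = mRNA_g
    y[2g+1] = protein_g

Free-parameter layout (29 entries):
    0..5   pro{1..6}_strength
    6..11  rbs{1..6}_strength
    12..19 K{1..8}
    20..27 h{1..8}
    28     p_deg_rate

Regulation is a product of Hill terms over the incoming edges of each gene:
activation u/(1+u), inhibition 1/(1+u) with u = (p_reg/K)^h.  The functions
below receive *effective* parameter arrays, i.e. after perturbation factors
(delete/overexpress) and per-gene mRNA degradation overrides (knockdown)
have been applied.
"""

import numpy as np
from numba import njit

# protein index is 2*reg+1; targets/regulators are 0-based gene indices
N_STATES = 12
N_PARAMS = 29

_HUGE = 1e300


@njit(cache=True)
def rhs(t, y, pro, rbs, K, h, pdeg, mdeg, etarget, ereg, esign):
    """Time derivative of the 12 concentrations."""
    cod = pro.copy()
    for e in range(etarget.shape[0]):
        p = y[2 * ereg[e] + 1]
        if p < 0.0:
            p = 0.0
        u = (p / K[e]) ** h[e]
        if u > _HUGE:
            H = 1.0 if esign[e] == 1 else 0.0
        elif esign[e] == 1:
            H = u / (1.0 + u)
        else:
            H = 1.0 / (1.0 + u)
        cod[etarget[e]] *= H
    dy = np.empty(N_STATES)
    for g in range(6):
        dy[2 * g] = cod[g] - mdeg[g] * y[2 * g]
        dy[2 * g + 1] = rbs[g] * y[2 * g] - pdeg * y[2 * g + 1]
    return dy


@njit(cache=True)
def rhs_forward(t, Y, pro, rbs, K, h, pdeg, mdeg, etarget, ereg, esign):
    """Augmented system: concentrations plus sensitivities d y / d log theta.

    Y = [y (12), S.ravel() (12*29)] with S[i, mu] = dy_i/dlog theta_mu.
    dS/dt = A S + B where A = df/dy and B[:, mu] = df/dlog theta_mu,
    both evaluated at the effective (perturbed) parameters.  Multiplicative
    perturbation factors leave log-derivatives unchanged; deleted genes get
    identically zero columns because their production terms vanish.
    """
    ne = etarget.shape[0]
    y = Y[:N_STATES]
    S = Y[N_STATES:].reshape(N_STATES, N_PARAMS)

    # per-edge Hill terms and their derivatives
    H = np.empty(ne)
    dH_dp = np.empty(ne)       # d H / d p_reg
    dH_dlogK = np.empty(ne)
    dH_dlogh = np.empty(ne)
    for e in range(ne):
        p = y[2 * ereg[e] + 1]
        if p < 0.0:
            p = 0.0
        x = p / K[e]
        u = x ** h[e]
        if u > _HUGE or x <= 0.0:
            # saturated or pinned Hill term: derivative numerically zero
            if u > _HUGE:
                H[e] = 1.0 if esign[e] == 1 else 0.0
            else:  # x == 0
                H[e] = 0.0 if esign[e] == 1 else 1.0
            dH_dp[e] = 0.0
            dH_dlogK[e] = 0.0
            dH_dlogh[e] = 0.0
            continue
        denom = (1.0 + u) * (1.0 + u)
        Du = 1.0 / denom if esign[e] == 1 else -1.0 / denom
        H[e] = u / (1.0 + u) if esign[e] == 1 else 1.0 / (1.0 + u)
        dH_dp[e] = Du * h[e] * u / p if p > 0.0 else 0.0
        dH_dlogK[e] = -Du * h[e] * u
        dH_dlogh[e] = Du * h[e] * u * np.log(x) if u > 0.0 else 0.0

    # product of incoming Hill terms per gene, and cod
    prodH = np.ones(6)
    for e in range(ne):
        prodH[etarget[e]] *= H[e]
    cod = pro * prodH

    A = np.zeros((N_STATES, N_STATES))
    B = np.zeros((N_STATES, N_PARAMS))
    for g in range(6):
        A[2 * g, 2 * g] = -mdeg[g]
        A[2 * g + 1, 2 * g] = rbs[g]
        A[2 * g + 1, 2 * g + 1] = -pdeg
        B[2 * g, g] = cod[g]                      # d/dlog pro_g
        B[2 * g + 1, 6 + g] = rbs[g] * y[2 * g]   # d/dlog rbs_g
        B[2 * g + 1, 28] = -pdeg * y[2 * g + 1]   # d/dlog p_deg_rate

    for e in range(ne):
        tg = etarget[e]
        # product of the *other* incoming Hill terms of the target gene
        other = 1.0
        for e2 in range(ne):
            if e2 != e and etarget[e2] == tg:
                other *= H[e2]
        scale = pro[tg] * other
        A[2 * tg, 2 * ereg[e] + 1] += scale * dH_dp[e]
        B[2 * tg, 12 + e] = scale * dH_dlogK[e]
        B[2 * tg, 20 + e] = scale * dH_dlogh[e]

    dY = np.empty(Y.shape[0])
    for g in range(6):
        dY[2 * g] = cod[g] - mdeg[g] * y[2 * g]
        dY[2 * g + 1] = rbs[g] * y[2 * g] - pdeg * y[2 * g + 1]
    dS = A @ S + B
    dY[N_STATES:] = dS.ravel()
    return dY
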