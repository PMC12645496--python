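"""Independent scalar oracle for the model right-hand side.

Deliberately naive term-by-term transcription, one equation per block,
using only Python floats and dict states.  Kept separate from the
package so it can serve as a duplicate-implementation cross-check for
the vectorized production code (corrected default variants only).
"""

import math


def oracle_pd_effect(c_pac, c_trail, p):
    ep = p["Emax_PAC"] * c_pac ** p["gamma_PAC"] / (
        p["EC50_PAC"] ** p["gamma_PAC"] + c_pac ** p["gamma_PAC"])
    et = p["Emax_TRAIL"] * c_trail ** p["gamma_TRAIL"] / (
        p["EC50_TRAIL"] ** p["gamma_TRAIL"] + c_trail ** p["gamma_TRAIL"])
    return ep + et + p["Psi"] * ep * et


def oracle_rhs(state, p):
    """state: dict with keys Q, G1, A (list of j floats), I, V, C, P,
    PA, PPAC, Pe, T, TP, TA.  Returns a dict of derivatives."""
    Q = state["Q"]
    G1 = state["G1"]
    A = list(state["A"])
    j = len(A)
    I = state["I"]
    V = state["V"]
    C = state["C"]
    P = state["P"]
    PA = state["PA"]
    PPAC = state["PPAC"]
    Pe = state["Pe"]
    T = state["T"]
    TP = state["TP"]
    TA = state["TA"]

    N = sum(A)
    E = oracle_pd_effect(PPAC, T, p)
    eta = p["kappa"] * V / (p["eta_half"] + V)

    d = {}
    # quiescent pool: mitotic return (doubling), exit to G1, phagocyte kill
    d["Q"] = (2.0 * p["ktr"] * A[j - 1]
              - p["a1"] * Q
              - p["kp"] * P / (1.0 + p["kQ"] * Q) * Q)
    # G1: entry from Q; exit to A1 at a2; drug-amplified apoptosis;
    # infection; phagocyte kill
    d["G1"] = (p["a1"] * Q
               - (p["a2"]
                  + p["d2"] * (1.0 + E)
                  + eta
                  + p["kp"] * P / (1.0 + p["ks"] * G1)) * G1)
    # transit chain
    dA = [0.0] * j
    common = (p["d3"] * (1.0 + E) + eta
              + p["kp"] * P / (1.0 + p["ks"] * G1))
    dA[0] = p["a2"] * G1 - p["ktr"] * A[0] - common * A[0]
    for i in range(1, j):
        dA[i] = p["ktr"] * (A[i - 1] - A[i]) - common * A[i]
    d["A"] = dA
    # infection of G1 + active cells; lysis
    d["I"] = eta * (G1 + N) - p["delta"] * I
    # burst, decay, consumption by infection events
    d["V"] = p["alpha"] * p["delta"] * I - p["omega"] * V - eta * (G1 + N)
    # cytokine: infected-cell-driven production, elimination
    cprod = p["Cprod_star"] + (p["Cprod_max"] - p["Cprod_star"]) * I / (
        p["psi_half"] + I)
    d["C"] = cprod - p["k_elim"] * C
    # phagocyte recruitment and death
    d["P"] = p["kcp"] * C / (p["C_half"] + C) - p["gamma_P"] * P
    # PAC-1: gut depot, plasma (two-compartment), peripheral
    d["PA"] = -p["ka"] * PA
    d["PPAC"] = (p["ka"] * PA / p["V_PAC"]
                 - (p["kep"] + p["k12P"]) * PPAC + p["k21P"] * Pe)
    d["Pe"] = p["k12P"] * PPAC - p["k21P"] * Pe
    # TRAIL TMDD with constant production holding T at T_star
    tp_eq = p["kon"] * p["R0"] * p["T_star"] / (
        p["kint"] + p["kon"] * p["T_star"])
    tprod = (p["kel"] * p["T_star"]
             + p["kon"] * p["T_star"] * (p["R0"] - tp_eq))
    d["T"] = (p["alpha_T"] * p["delta"] * I
              - p["kel"] * T
              - p["kon"] * T * (p["R0"] - TP)
              - p["k12"] * T
              + p["k21"] * TA / p["V"]
              + tprod)
    d["TP"] = p["kon"] * (p["R0"] - TP) * T - p["kint"] * TP
    d["TA"] = p["k12"] * p["V"] * T - p["k21"] * TA
    return d
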