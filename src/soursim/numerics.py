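"""Compiled kinetics kernel.

The Monod right-hand side is tiny but is evaluated millions of times during
population-based fitting and column operator splitting, so a numba-compiled
scalar-loop version is used when numba is importable; the batch module falls
back to the equivalent vectorized numpy implementation otherwise.  Both
compute exactly the same expression, including the smooth non-negativity
gate s(C) = C+^2 / (C^2 + delta^2) on every consumed species.
"""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly by every solver call
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

_CUT2 = 1e-24  # (1e-12 mol/l)^2 gate scale


@njit(cache=True)
def kinetics_rhs(
    y,
    out,
    n_cells,
    n_dyn,
    n_state,
    nu,
    donor_idx,
    acceptor_idx,
    inhib_idx,
    mu,
    Kd,
    Ka,
    I,
    b,
    consumed,
    grow,
):  # pragma: no cover - compiled; equivalence asserted against numpy path
    n_rxn = nu.shape[0]
    out[:] = 0.0
    for c in range(n_cells):
        base = c * n_state
        for j in range(n_rxn):
            X = y[base + n_dyn + j]
            if X < 0.0:
                X = 0.0
            Cd = y[base + donor_idx[j]]
            if Cd < 0.0:
                Cd = 0.0
            Ca = y[base + acceptor_idx[j]]
            if Ca < 0.0:
                Ca = 0.0
            r = mu[j] * X * Cd / (Cd + Kd[j]) * Ca / (Ca + Ka[j])
            if inhib_idx[j] >= 0:
                Ci = y[base + inhib_idx[j]]
                if Ci < 0.0:
                    Ci = 0.0
                r *= I[j] / (Ci + I[j])
            for s in range(n_dyn):
                if consumed[j, s]:
                    C = y[base + s]
                    Cp = C if C > 0.0 else 0.0
                    r *= Cp * Cp / (C * C + _CUT2)
            for s in range(n_dyn):
                if nu[j, s] != 0.0:
                    out[base + s] += nu[j, s] * r
            if grow:
                out[base + n_dyn + j] = r - b[j] * X
    return out
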