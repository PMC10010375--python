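"""Independent numerical oracles shared across test modules."""

import numpy as np
from scipy.linalg import solve_banded


def bvp_profile(r_eval, R, R_n, rho, c_b, n=6001):
    """Finite-difference solve of c'' + (2/r)c' = (rho/R)^2 c on [R_n, R].

    Second-order central differences with a ghost point enforcing zero
    flux at R_n and a Dirichlet condition c(R) = c_b; the independent
    check for the closed-form shell profile.
    """
    q2 = (rho / R) ** 2
    r = np.linspace(R_n, R, n)
    h = r[1] - r[0]
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    for i in range(1, n - 1):
        ab[0, i + 1] = 1.0 / h**2 + 1.0 / (r[i] * h)   # upper
        ab[1, i] = -2.0 / h**2 - q2                     # diag
        ab[2, i - 1] = 1.0 / h**2 - 1.0 / (r[i] * h)   # lower
    if R_n > 0:
        # zero flux at R_n via ghost point c[-1] = c[1]
        ab[1, 0] = -2.0 / h**2 - q2
        ab[0, 1] = 2.0 / h**2
    else:
        # symmetry at r = 0: c'' * 3 = q2 * c
        ab[1, 0] = -6.0 / h**2 - q2
        ab[0, 1] = 6.0 / h**2
    ab[1, n - 1] = 1.0
    ab[2, n - 2] = 0.0
    rhs[n - 1] = c_b
    c = solve_banded((1, 1), ab, rhs)
    return np.interp(r_eval, r, c)
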