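"""Independent references the circuit implementation is checked against.

Two routes that never touch the package's gate code:

* matrix-exponential unitaries built from Pauli generators with
  ``scipy.linalg.expm``;
* the closed-form amplitude recursions of the embedding written out
  termwise (sum/difference half-angles), exactly as they can be derived
  by hand for each gate.
"""

import numpy as np
from scipy.linalg import expm

I2 = np.eye(2)
PAULI_X = np.array([[0.0, 1.0], [1.0, 0.0]])
PAULI_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]])
PAULI_Z = np.diag([1.0, -1.0])


def u_rx_pair(x1, x2):
    """exp(-i/2 (x1 X(x)I + x2 I(x)X)) -- the data-encoding layer."""
    return expm(-0.5j * (x1 * np.kron(PAULI_X, I2) + x2 * np.kron(I2, PAULI_X)))


def u_zz(theta):
    return expm(-0.5j * theta * np.kron(PAULI_Z, PAULI_Z))


def u_ry_pair(ta, tb):
    return expm(-0.5j * (ta * np.kron(PAULI_Y, I2) + tb * np.kron(I2, PAULI_Y)))


def embed_unitary(x1, x2, thetas, n_layers=4, final_encoding=True):
    """Product of the layer unitaries, |x> = U |00>."""
    u = np.eye(4, dtype=complex)
    for layer in range(n_layers):
        u = u_rx_pair(x1, x2) @ u
        u = u_zz(thetas[3 * layer]) @ u
        u = u_ry_pair(thetas[3 * layer + 1], thetas[3 * layer + 2]) @ u
    if final_encoding:
        u = u_rx_pair(x1, x2) @ u
    return u


# --- closed-form amplitude recursions --------------------------------------


def rx_pair_on_00_closed_form(x1, x2):
    """(alpha, beta, gamma, delta) after Rx(x1), Rx(x2) act on |00>."""
    p, m = (x1 + x2) / 2.0, (x1 - x2) / 2.0
    alpha = 0.5 * np.cos(p) + 0.5 * np.cos(m)
    beta = -0.5j * np.sin(p) + 0.5j * np.sin(m)
    gamma = -0.5j * np.sin(p) - 0.5j * np.sin(m)
    delta = -0.5 * np.cos(m) + 0.5 * np.cos(p)
    return np.array([alpha, beta, gamma, delta])


def zz_closed_form(amps, theta):
    """Parity phases: alpha, delta pick up e^{-i theta/2}; beta, gamma e^{+i theta/2}."""
    a, b, c, d = amps
    return np.array(
        [
            np.exp(-0.5j * theta) * a,
            np.exp(0.5j * theta) * b,
            np.exp(0.5j * theta) * c,
            np.exp(-0.5j * theta) * d,
        ]
    )


def ry_pair_closed_form(amps, t2, t3):
    """Half-angle sum/difference recursion for Ry(t2) (x) Ry(t3)."""
    a, b, c, d = amps
    p, m = (t2 + t3) / 2.0, (t2 - t3) / 2.0
    cp, cm, sp, sm = np.cos(p), np.cos(m), np.sin(p), np.sin(m)
    alpha = (a - d) / 2 * cp + (a + d) / 2 * cm - (b + c) / 2 * sp + (b - c) / 2 * sm
    beta = (b + c) / 2 * cp + (b - c) / 2 * cm + (a - d) / 2 * sp - (a + d) / 2 * sm
    gamma = (b + c) / 2 * cp - (b - c) / 2 * cm + (a - d) / 2 * sp + (a + d) / 2 * sm
    delta = -(a - d) / 2 * cp + (a + d) / 2 * cm + (b + c) / 2 * sp + (b - c) / 2 * sm
    return np.array([alpha, beta, gamma, delta])


def embed_closed_form(x1, x2, thetas, n_layers=4, final_encoding=True):
    """Full embedding via the closed-form recursions only.

    The encoding layer acting on an arbitrary state is expressed through
    the same unitary route is avoided: Rx(x)(x)Rx(y) on a general state is
    reconstructed by linearity from its action on the four basis states,
    each of which reduces to the |00> recursion up to relabeling.
    """
    # action of Rx(x1)(x)Rx(x2) on each basis vector, from the |00> form:
    # Rx is symmetric, so columns follow by permuting (alpha,beta,gamma,delta).
    col0 = rx_pair_on_00_closed_form(x1, x2)
    a, b, c, d = col0
    enc = np.array(
        [
            [a, b, c, d],
            [b, a, d, c],
            [c, d, a, b],
            [d, c, b, a],
        ]
    ).T
    amps = np.array([1.0, 0.0, 0.0, 0.0], dtype=complex)
    for layer in range(n_layers):
        amps = enc @ amps
        amps = zz_closed_form(amps, thetas[3 * layer])
        amps = ry_pair_closed_form(amps, thetas[3 * layer + 1], thetas[3 * layer + 2])
    if final_encoding:
        amps = enc @ amps
    return amps
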