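"""Embed circuit inputs into two-qubit states and inspect their overlap.

The feature map repeats (Rx-encode, ZZ entangle, Ry rotate) four times
and re-encodes once more, so a sample passes through 14 circuit stages
and ends as 4 complex amplitudes on the 2-qubit basis.
"""

import numpy as np

import qmetric as qm

params = qm.QuantumParams(np.linspace(0.3, 2.9, 12))  # 12 trainable angles

stages = qm.embed(0.8, -0.5, params, return_trajectory=True)
state = stages[-1]
print(f"circuit stages: {len(stages)} (|x1> = |00> ... |x14> = |x>)")
print("final amplitudes (|00>,|01>,|10>,|11>):")
for basis, amp in zip(("00", "01", "10", "11"), state.amplitudes):
    print(f"  |{basis}>: {amp.real:+.4f}{amp.imag:+.4f}i")
print(f"norm: {np.linalg.norm(state.amplitudes):.12f}")

other = qm.embed(0.9, -0.4, params)
far = qm.embed(-2.0, 2.5, params)
print(f"overlap with nearby input   (0.9, -0.4): {qm.overlap(state, other):.4f}")
print(f"overlap with distant input (-2.0,  2.5): {qm.overlap(state, far):.4f}")
# Overlaps |<x|x'>|^2 are the fidelity kernel entries: close circuit
# inputs land close in Hilbert space, distant ones (ideally) do not.
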