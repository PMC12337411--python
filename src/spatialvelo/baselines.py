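"""Split/recombine utility for feeding batch-corrected counts to velocity methods.

Batch-correction tools return a single corrected expression matrix, but
velocity needs spliced and unspliced separately. The trick: correct the sum
M = S + U, keep the ratio R = S / (S + U) (0/0 -> 0), then redistribute the
corrected sum by the original ratio,

    S_corrected = M_tilde * R,      U_corrected = M_tilde * (1 - R),

which conserves S_corrected + U_corrected = M_tilde exactly and inverts the
split under identity correction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_counts", "recombine"]


def split_counts(S, U):
    """(M, R) = (S + U, S / (S + U)) with the 0/0 -> 0 convention."""
    S = np.asarray(S, dtype=float)
    U = np.asarray(U, dtype=float)
    if S.shape != U.shape:
        raise ValueError("S and U must have the same shape")
    if S.min() < 0 or U.min() < 0:
        raise ValueError("counts must be non-negative")
    M = S + U
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(M > 0, S / np.where(M > 0, M, 1.0), 0.0)
    return M, R


def recombine(M_corrected, R):
    """(S, U) = (M_tilde * R, M_tilde * (1 - R)); exact sum conservation.

    U is computed as M_tilde - S (algebraically identical to
    M_tilde * (1 - R)) so that S + U reproduces M_tilde bit-exactly.
    """
    M_corrected = np.asarray(M_corrected, dtype=float)
    R = np.asarray(R, dtype=float)
    if M_corrected.shape != R.shape:
        raise ValueError("shapes must match")
    if R.min() < 0 or R.max() > 1:
        raise ValueError("R must lie in [0, 1]")
    S = M_corrected * R
    U = M_corrected - S
    return S, U
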