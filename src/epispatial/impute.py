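"""Zero-preserving low-rank imputation (ALRA-style).

Sparse normalized expression is approximated at an adaptively chosen rank;
per gene, reconstructed values smaller than the magnitude of that gene's
most negative reconstructed entry are zeroed — the symmetric-error argument
that preserves biological zeros — and the surviving entries are rescaled to
match the original non-zero mean and standard deviation. Technical zeros
whose reconstruction survives the threshold come back positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["ImputationResult", "choose_rank", "alra"]


@dataclass
class ImputationResult:
    imputed: np.ndarray            # cells x genes, non-negative
    rank: int
    thresholds: np.ndarray         # per-gene zeroing threshold
    scale: np.ndarray              # per-gene sd ratio applied
    shift: np.ndarray              # per-gene mean shift applied


def choose_rank(
    singular_values: np.ndarray, n_noise_spacings: int = 20
) -> tuple[int, bool]:
    """Pick the approximation rank from singular-value spacings.

    Consecutive spacings d_i = s_i - s_{i+1} in the noise tail are roughly
    i.i.d.; their mean and sd are estimated from the last
    ``n_noise_spacings`` spacings, and the rank is the largest i whose
    spacing exceeds mean + 6 sd. Returns ``(k, signal_found)``; with no
    above-noise spacing, k = 1 and ``signal_found`` is False.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < n_noise_spacings + 2:
        raise ValueError(
            f"need at least {n_noise_spacings + 2} singular values, got {s.size}"
        )
    spacings = s[:-1] - s[1:]
    tail = spacings[-n_noise_spacings:]
    cutoff = tail.mean() + 6.0 * tail.std(ddof=0)
    above = np.nonzero(spacings > cutoff)[0]
    if above.size == 0:
        logger.warning("no signal detected in singular-value spacings; rank 1")
        return 1, False
    return int(above[-1]) + 1, True


def alra(
    matrix: np.ndarray | sp.spmatrix,
    k: int | None = None,
    n_noise_spacings: int = 20,
) -> ImputationResult:
    """Rank-``k`` zero-preserving imputation of a normalized matrix.

    With ``k=None`` the rank is chosen by :func:`choose_rank` from the
    full singular spectrum. All-zero genes stay all-zero; the output is
    non-negative.
    """
    A = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    if A.min() < 0:
        raise ValueError("input matrix must be non-negative")
    n, g = A.shape
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if k is None:
        k, _ = choose_rank(s, n_noise_spacings=n_noise_spacings)
    if not 1 <= k <= min(n, g):
        raise ValueError(f"rank k={k} outside [1, {min(n, g)}]")

    Ak = (U[:, :k] * s[:k]) @ Vt[:k]

    col_min = Ak.min(axis=0)
    thresholds = np.where(col_min < 0, np.abs(col_min), 0.0)
    out = np.where(Ak < thresholds[None, :], 0.0, Ak)

    # per-gene affine rescale of surviving entries to the original
    # non-zero mean/sd
    scale = np.ones(g)
    shift = np.zeros(g)
    orig_nonzero = A > 0
    for j in range(g):
        o_mask = orig_nonzero[:, j]
        i_mask = out[:, j] > 0
        if not o_mask.any():
            out[:, j] = 0.0  # all-zero gene stays all-zero
            continue
        if not i_mask.any():
            continue
        mu_o, sd_o = A[o_mask, j].mean(), A[o_mask, j].std(ddof=0)
        mu_i, sd_i = out[i_mask, j].mean(), out[i_mask, j].std(ddof=0)
        if sd_i > 0 and sd_o > 0:
            scale[j] = sd_o / sd_i
            shift[j] = mu_o - mu_i * scale[j]
            out[i_mask, j] = out[i_mask, j] * scale[j] + shift[j]
        else:
            shift[j] = mu_o - mu_i
            out[i_mask, j] = out[i_mask, j] + shift[j]
    np.clip(out, 0.0, None, out=out)

    return ImputationResult(
        imputed=out, rank=int(k), thresholds=thresholds, scale=scale, shift=shift
    )
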