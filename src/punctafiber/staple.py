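"""Multi-rater binary label fusion by STAPLE expectation-maximization.

Fuses R binary annotations of the same image into a consensus probability
map while estimating each rater's sensitivity p_j and specificity q_j.

E-step, per pixel i with rater decisions d_ij:

    a_i = prior_i * prod_j p_j^d_ij (1-p_j)^(1-d_ij)
    b_i = (1-prior_i) * prod_j (1-q_j)^d_ij q_j^(1-d_ij)
    W_i = a_i / (a_i + b_i)

M-step:

    p_j = sum_i W_i d_ij / sum_i W_i
    q_j = sum_i (1-W_i)(1-d_ij) / sum_i (1-W_i)

Iteration stops when max |delta p, delta q| < tol or at max_iter. Parameters
are clamped to [EPS, 1-EPS] so unanimous all-true/all-false inputs stay
finite; clamping is flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import BinaryMask

__all__ = ["RaterAnnotations", "StapleResult", "staple_fuse", "majority_vote", "staple_log_likelihood"]

EPS = 1e-6
INIT_PERFORMANCE = 0.99999


@dataclass
class RaterAnnotations:
    """R same-shape binary masks from independent raters."""

    masks: list[BinaryMask]
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) < 1:
            raise ValueError("at least one rater required")
        shape = self.masks[0].shape
        for m in self.masks:
            if m.shape != shape:
                raise ValueError("all rater masks must share one shape")
        if not self.rater_ids:
            self.rater_ids = [f"rater{j}" for j in range(len(self.masks))]
        if len(self.rater_ids) != len(self.masks):
            raise ValueError("rater_ids length must equal number of masks")

    @property
    def n_raters(self) -> int:
        return len(self.masks)

    def decisions(self) -> np.ndarray:
        """(R, n_pixels) float array of flattened rater decisions."""
        return np.stack([m.pixels.ravel().astype(np.float64) for m in self.masks])


@dataclass
class StapleResult:
    consensus_probability: np.ndarray
    consensus_mask: BinaryMask
    sensitivities: np.ndarray
    specificities: np.ndarray
    n_iterations: int
    converged: bool
    clamped: bool
    log_likelihood: float


def staple_log_likelihood(
    decisions: np.ndarray, p: np.ndarray, q: np.ndarray, prior: np.ndarray
) -> float:
    """Observed-data log-likelihood sum_i log(a_i + b_i) at given parameters."""
    log_p = np.log(np.clip(p, EPS, 1 - EPS))
    log_1p = np.log(np.clip(1 - p, EPS, 1 - EPS))
    log_q = np.log(np.clip(q, EPS, 1 - EPS))
    log_1q = np.log(np.clip(1 - q, EPS, 1 - EPS))
    log_a = np.log(prior) + decisions.T @ log_p + (1 - decisions).T @ log_1p
    log_b = np.log1p(-prior) + decisions.T @ log_1q + (1 - decisions).T @ log_q
    m = np.maximum(log_a, log_b)
    return float(np.sum(m + np.log(np.exp(log_a - m) + np.exp(log_b - m))))


def staple_fuse(
    annotations: RaterAnnotations,
    prior: float | np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    track_likelihood: bool = False,
) -> StapleResult:
    """Run binary STAPLE EM and return consensus + rater performance estimates.

    ``prior`` defaults to the mean annotation fraction (scalar); a per-pixel
    raster prior of the same shape is also accepted. The consensus mask is
    ``probability >= 0.5``.
    """
    shape = annotations.masks[0].shape
    d = annotations.decisions()  # (R, n)
    r, n = d.shape

    if prior is None:
        prior_flat = np.full(n, float(np.clip(d.mean(), EPS, 1 - EPS)))
    elif np.isscalar(prior):
        if not (0 < float(prior) < 1):
            raise ValueError("scalar prior must be in (0, 1)")
        prior_flat = np.full(n, float(prior))
    else:
        prior_arr = np.asarray(prior, dtype=np.float64)
        if prior_arr.shape != shape:
            raise ValueError("raster prior must match mask shape")
        prior_flat = np.clip(prior_arr.ravel(), EPS, 1 - EPS)

    p = np.full(r, INIT_PERFORMANCE)
    q = np.full(r, INIT_PERFORMANCE)
    clamped = False
    converged = False
    ll_trace: list[float] = []
    w = prior_flat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical stability
        log_p = np.log(p)
        log_1p = np.log(1 - p)
        log_q = np.log(q)
        log_1q = np.log(1 - q)
        log_a = np.log(prior_flat) + d.T @ log_p + (1 - d).T @ log_1p
        log_b = np.log1p(-prior_flat) + d.T @ log_1q + (1 - d).T @ log_q
        m = np.maximum(log_a, log_b)
        ea = np.exp(log_a - m)
        eb = np.exp(log_b - m)
        w = ea / (ea + eb)

        if track_likelihood:
            ll_trace.append(float(np.sum(m + np.log(ea + eb))))

        # M-step
        sw = w.sum()
        s1w = (1 - w).sum()
        new_p = (d @ w) / sw if sw > 0 else np.full(r, 0.5)
        new_q = ((1 - d) @ (1 - w)) / s1w if s1w > 0 else np.full(r, 0.5)
        lo, hi = EPS, 1 - EPS
        if (new_p < lo).any() or (new_p > hi).any() or (new_q < lo).any() or (new_q > hi).any():
            clamped = True
        new_p = np.clip(new_p, lo, hi)
        new_q = np.clip(new_q, lo, hi)

        delta = max(np.abs(new_p - p).max(), np.abs(new_q - q).max())
        p, q = new_p, new_q
        if delta < tol:
            converged = True
            break

    prob = w.reshape(shape)
    result = StapleResult(
        consensus_probability=prob,
        consensus_mask=BinaryMask(
            pixels=prob >= 0.5, pixel_size_um=annotations.masks[0].pixel_size_um
        ),
        sensitivities=p,
        specificities=q,
        n_iterations=it,
        converged=converged,
        clamped=clamped,
        log_likelihood=staple_log_likelihood(d, p, q, prior_flat),
    )
    if track_likelihood:
        result.likelihood_trace = ll_trace  # type: ignore[attr-defined]
    return result


def majority_vote(annotations: RaterAnnotations) -> BinaryMask:
    """Pixel true iff strictly more than half the raters mark it true."""
    votes = np.sum([m.pixels for m in annotations.masks], axis=0)
    return BinaryMask(
        pixels=votes > annotations.n_raters / 2,
        pixel_size_um=annotations.masks[0].pixel_size_um,
    )
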