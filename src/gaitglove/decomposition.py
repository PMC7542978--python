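"""Per-run PCA of the 19-channel matrix and cross-run sign alignment.

Each analysis-ready run (800 frames x 19 channels) is column-mean centered
and decomposed by SVD into 19 components, each a sensor expression-coefficient
(EC) vector, an orthogonal time course and an eigenvalue.  Because the signs
of an (EC, time-course) pair are jointly indeterminate, ECs are aligned in
two stages — within the runs of a subject, then across subjects — before any
cohort statistics, and finally given a canonical global sign (summed loading
over thumb-cross plus finger MCP/PIP channels positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .errors import AnalysisError, ValidationError
from .glove_io import SensorRun

__all__ = [
    "Decomposition",
    "decompose_run",
    "guttman_kaiser",
    "align_within_subject",
    "align_across_subjects",
    "canonical_sign",
]


@dataclass
class Decomposition:
    """Full PCA of one run: ECs, time courses and variance accounting."""

    ecs: np.ndarray  # (channels, K) orthonormal columns
    time_courses: np.ndarray  # (frames, K) orthonormal columns
    eigenvalues: np.ndarray  # (K,) non-increasing
    var_fraction: np.ndarray  # (K,) sums to 1
    channel_mean: np.ndarray  # (channels,) removed before SVD
    subject_id: str = ""
    hand: str = ""
    run_index: int = 0
    channels: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.ecs.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Centered-data reconstruction from all components."""
        scale = np.sqrt(self.eigenvalues)
        return self.time_courses @ np.diag(scale) @ self.ecs.T

    def flipped(self, signs: np.ndarray) -> "Decomposition":
        """Apply one sign per component jointly to EC and time-course columns."""
        signs = np.asarray(signs, dtype=float)
        return Decomposition(
            ecs=self.ecs * signs,
            time_courses=self.time_courses * signs,
            eigenvalues=self.eigenvalues.copy(),
            var_fraction=self.var_fraction.copy(),
            channel_mean=self.channel_mean.copy(),
            subject_id=self.subject_id,
            hand=self.hand,
            run_index=self.run_index,
            channels=self.channels,
        )


def decompose_run(run: SensorRun) -> Decomposition:
    """SVD of the column-centered run matrix.

    ECs are the right singular vectors, time courses the left singular
    vectors, eigenvalues the squared singular values; variance fractions are
    eigenvalues normalized to unit sum.
    """
    X = run.data
    n, p = X.shape
    if n < p:
        raise ValidationError(
            f"run has fewer frames ({n}) than channels ({p}); PCA rank-deficient"
        )
    mean = X.mean(axis=0)
    resid = X - mean
    col_var = resid.var(axis=0)
    zero = np.flatnonzero(col_var < 1e-24)
    if zero.size:
        names = [run.layout.labels[i] for i in zero]
        warnings.warn(
            f"constant channel(s) {names} carry no variance; retained with "
            "zero loadings",
            stacklevel=2,
        )
    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    # deterministic sign convention prior to any alignment: largest-|EC|
    # entry positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    eig = s**2
    total = eig.sum()
    if total <= 0:
        raise AnalysisError("run matrix has zero total variance")
    return Decomposition(
        ecs=Vt.T,
        time_courses=U,
        eigenvalues=eig,
        var_fraction=eig / total,
        channel_mean=mean,
        subject_id=run.subject_id,
        hand=run.hand,
        run_index=run.run_index,
        channels=run.layout.labels,
    )


def guttman_kaiser(d: Decomposition) -> int:
    """Number of eigenvalues strictly exceeding the run's mean eigenvalue.

    Scale-free generalization of the eigenvalue-greater-than-one rule to a
    covariance PCA.
    """
    mean = d.eigenvalues.mean()
    return int(np.sum(d.eigenvalues > mean))


# ---------------------------------------------------------------------------
# sign alignment
# ---------------------------------------------------------------------------

def _pairwise_r(vectors: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of row vectors (constant rows -> 0)."""
    V = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    V = V / norms[:, None]
    return V @ V.T


def _objective(r: np.ndarray, signs: np.ndarray) -> float:
    """Sum over pairs of sign-adjusted correlations."""
    s = signs.astype(float)
    return 0.5 * (s @ r @ s - np.trace(r))


def _align_signs(r: np.ndarray, exact_limit: int = 12) -> np.ndarray:
    """Signs maximizing the summed pairwise correlation of sign-flipped rows.

    Exact enumeration over 2^(n-1) patterns for n <= exact_limit, else a
    greedy anchor-plus-sweep iterated to a fixed point.  Deterministic; ties
    keep +1 (identity preferred).
    """
    n = r.shape[0]
    if n == 1:
        return np.ones(1)
    if n <= exact_limit:
        best_signs = np.ones(n)
        best_obj = _objective(r, best_signs)
        for pattern in product((1.0, -1.0), repeat=n - 1):
            signs = np.concatenate([[1.0], pattern])
            obj = _objective(r, signs)
            if obj > best_obj + 1e-12:
                best_obj, best_signs = obj, signs
        return best_signs
    signs = np.ones(n)
    for _ in range(100):
        changed = False
        for i in range(1, n):
            field = signs @ r[:, i] - signs[i] * r[i, i]
            want = 1.0 if field >= 0 else -1.0
            if want != signs[i]:
                signs[i] = want
                changed = True
        if not changed:
            break
    return signs


def align_within_subject(
    ds: list[Decomposition], component: int
) -> np.ndarray:
    """Per-run signs aligning one component's ECs across a subject's runs.

    Maximizes the summed pairwise Pearson correlation among the signed EC
    vectors; a single run gets the identity flip.
    """
    if not ds:
        raise ValidationError("no decompositions to align")
    subjects = {d.subject_id for d in ds}
    hands = {d.hand for d in ds}
    if len(subjects) > 1 or len(hands) > 1:
        raise ValidationError(
            f"within-subject alignment mixes subjects {subjects} / hands {hands}"
        )
    vecs = np.array([d.ecs[:, component] for d in ds])
    return _align_signs(_pairwise_r(vecs))


def canonical_sign(ec: np.ndarray, positive_idx: np.ndarray) -> float:
    """+1 if the summed loading over the designated channels is >= 0, else -1."""
    return 1.0 if float(ec[positive_idx].sum()) >= 0.0 else -1.0


def align_across_subjects(
    subject_ecs: list[np.ndarray],
    positive_idx: np.ndarray | None = None,
) -> np.ndarray:
    """One sign per subject, plus a global canonical sign.

    ``subject_ecs`` are the within-subject-aligned mean EC vectors, one per
    subject.  Signs maximize the summed inter-subject pairwise correlation;
    afterwards all signs are multiplied by the canonical sign of the signed
    cohort-mean EC so the summed loading over ``positive_idx`` (thumb-cross
    plus finger MCP/PIP channels) is positive.
    """
    vecs = np.array(subject_ecs)
    signs = _align_signs(_pairwise_r(vecs))
    if positive_idx is not None and len(positive_idx) > 0:
        mean_ec = (signs[:, None] * vecs).mean(axis=0)
        signs = signs * canonical_sign(mean_ec, np.asarray(positive_idx))
    return signs
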