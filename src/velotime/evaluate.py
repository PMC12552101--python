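"""Benchmark metrics for pseudotime and velocity estimates.

Pseudotime accuracy is scored by Pearson correlation on linear
trajectories and by circular cross-correlation (maximized over shifts
and orientation) on cyclic ones.  Velocity accuracy is the mean
per-cell Pearson correlation across genes against the ground truth.
Robustness studies use the per-cell cosine similarity between velocity
fields from perturbed and unperturbed data.

Four boundary metrics score a velocity field against annotated
cell-type transitions: CBDir (embedding space, via the standard
transition-probability projection of velocities), CBDir2 (expression
space), TransCosine (alignment between the velocity-derived neighbor
score vector and the to-label indicator) and LenAcc (correlation of
velocity magnitude with local forward displacement).  Their exact
published definitions live in evaluation suites not reproduced here;
these operationalizations preserve the roles and value ranges and are
this package's own.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np

from .data_io import OmicsDataset, knn_indices
from .errors import DataError
from .simulate import SimulationTruth
from .train import FitResult

__all__ = [
    "EvaluationReport",
    "pearson_pseudotime",
    "circular_cross_correlation",
    "velocity_correlation",
    "stability_cosine",
    "boundary_metrics",
    "run_benchmark",
]


@dataclass
class EvaluationReport:
    pearson_t: Optional[float] = None
    circular_xcorr_t: Optional[float] = None
    velocity_corr: Optional[float] = None
    cbdir: Optional[float] = None
    cbdir2: Optional[float] = None
    transcosine: Optional[float] = None
    lenacc: Optional[float] = None
    stability_cosine_median: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls(**json.loads(s))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        raise DataError("degenerate: constant input to correlation")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_pseudotime(t_est, t_true) -> float:
    """Pearson correlation between estimated and true pseudotime."""
    t_est = np.asarray(t_est, float)
    t_true = np.asarray(t_true, float)
    if len(t_est) != len(t_true) or len(t_est) < 3:
        raise DataError("shape-mismatch: need equal length >= 3")
    return _pearson(t_est, t_true)


def circular_cross_correlation(t_est, t_true) -> float:
    """Pseudotime accuracy on the circle.

    Maximizes Pearson(t_est, frac(sigma * t_true + tau)) over n evenly
    spaced shifts tau and both orientations sigma = +/-1, so the score
    is invariant to the arbitrary origin and direction of a cyclic
    trajectory.
    """
    t_est = np.asarray(t_est, float)
    t_true = np.asarray(t_true, float)
    n = len(t_est)
    if n != len(t_true) or n < 3:
        raise DataError("shape-mismatch: need equal length >= 3")
    if t_est.std() == 0 or t_true.std() == 0:
        raise DataError("degenerate: constant input to correlation")
    taus = np.arange(n) / n
    best = -1.0
    e = t_est - t_est.mean()
    se = np.sqrt((e**2).sum())
    for sign in (1.0, -1.0):
        shifted = np.mod(sign * t_true[None, :] + taus[:, None], 1.0)
        sc = shifted - shifted.mean(axis=1, keepdims=True)
        denom = np.sqrt((sc**2).sum(axis=1)) * se
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (sc @ e) / denom
        corr = corr[np.isfinite(corr)]
        if corr.size:
            best = max(best, float(corr.max()))
    return best


def velocity_correlation(Vs_est, Vs_true) -> float:
    """Mean per-cell Pearson correlation across genes."""
    A = np.asarray(Vs_est, float)
    B = np.asarray(Vs_true, float)
    if A.shape != B.shape:
        raise DataError("shape-mismatch")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    valid = den > 0
    if not valid.any():
        raise DataError("degenerate: all rows constant")
    if not valid.all():
        warnings.warn(f"{(~valid).sum()} constant rows skipped")
    corr = (Ac * Bc).sum(axis=1)[valid] / den[valid]
    return float(corr.mean())


def stability_cosine(Vs_a, Vs_b) -> np.ndarray:
    """Per-cell cosine similarity between two velocity fields."""
    A = np.asarray(Vs_a, float)
    B = np.asarray(Vs_b, float)
    if A.shape != B.shape:
        raise DataError("shape-mismatch")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    zero = (na == 0) | (nb == 0)
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-velocity rows scored 0")
    den = np.where(zero, 1.0, na * nb)
    out = (A * B).sum(axis=1) / den
    out[zero] = 0.0
    return out


# ----------------------------------------------------------------------
# boundary metrics
# ----------------------------------------------------------------------

def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _transition_probs(Vs_i: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Softmax over neighbors of cosine(velocity, displacement)."""
    dnorm = np.linalg.norm(disp, axis=1)
    vnorm = np.linalg.norm(Vs_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = disp @ Vs_i / (dnorm * vnorm + 1e-12)
    cos = np.nan_to_num(cos)
    ex = np.exp(cos - cos.max())
    return ex / ex.sum()


def boundary_metrics(Vs: np.ndarray, S_smoothed: np.ndarray,
                     embedding: Optional[np.ndarray],
                     cell_labels, transitions: List[Tuple[str, str]],
                     knn_k: int = 30
                     ) -> Tuple[float, float, float, float]:
    """(CBDir, CBDir2, TransCosine, LenAcc) for declared transitions.

    A *boundary cell* is a from-label cell with at least one to-label
    cell among its k nearest neighbors in expression space.
    """
    Vs = np.asarray(Vs, float)
    S = np.asarray(S_smoothed, float)
    labels = np.asarray([str(c) for c in cell_labels])
    n = len(labels)
    k = min(knn_k, n - 1)
    nbrs = knn_indices(S, k + 1)[:, 1:]

    cbdir_vals, cbdir2_vals, trans_vals = [], [], []
    any_boundary = False
    for frm, to in transitions:
        cells = np.flatnonzero(labels == frm)
        found = False
        for i in cells:
            nb = nbrs[i]
            to_mask = labels[nb] == to
            if not to_mask.any():
                continue
            found = True
            any_boundary = True
            disp = S[nb] - S[i]
            # CBDir2: expression-space cosine to each to-label neighbor
            cbdir2_vals.extend(_cosine(Vs[i], d) for d in disp[to_mask])
            # TransCosine: score vector vs to-label indicator
            dnorm = np.linalg.norm(disp, axis=1)
            vnorm = np.linalg.norm(Vs[i])
            with np.errstate(invalid="ignore", divide="ignore"):
                scores = disp @ Vs[i] / (dnorm * vnorm + 1e-12)
            scores = np.nan_to_num(scores)
            trans_vals.append(_cosine(scores, to_mask.astype(float)))
            # CBDir: embedding-space projected arrow vs displacement
            if embedding is not None:
                probs = _transition_probs(Vs[i], disp)
                edisp = embedding[nb] - embedding[i]
                arrow = probs @ edisp - edisp.mean(axis=0)
                cbdir_vals.extend(_cosine(arrow, d)
                                  for d in edisp[to_mask])
        if not found:
            warnings.warn(f"transition {frm}>{to}: no boundary cells, "
                          "skipped")
    if not any_boundary:
        raise DataError("no-boundaries")

    # LenAcc: velocity magnitude vs mean displacement to forward neighbors
    vnorms = np.linalg.norm(Vs, axis=1)
    fwd_disp = np.empty(n)
    for i in range(n):
        disp = S[nbrs[i]] - S[i]
        proj = disp @ Vs[i]
        sel = proj > 0 if (proj > 0).any() else np.ones(len(disp), bool)
        fwd_disp[i] = np.linalg.norm(disp[sel], axis=1).mean()
    if vnorms.std() == 0 or fwd_disp.std() == 0:
        lenacc = float("nan")
    else:
        lenacc = float(np.corrcoef(vnorms, fwd_disp)[0, 1])

    cbdir = float(np.mean(cbdir_vals)) if cbdir_vals else float("nan")
    cbdir2 = float(np.mean(cbdir2_vals))
    transcos = float(np.mean(trans_vals))
    return cbdir, cbdir2, transcos, lenacc


def run_benchmark(ds: OmicsDataset, truth: SimulationTruth, fit: FitResult,
                  topology: str = "linear",
                  transitions: Optional[List[Tuple[str, str]]] = None,
                  knn_k: int = 30) -> EvaluationReport:
    """Score a fit against simulation ground truth."""
    report = EvaluationReport()
    if topology == "circular":
        report.circular_xcorr_t = circular_cross_correlation(
            fit.t, truth.t_true)
    else:
        report.pearson_t = pearson_pseudotime(fit.t, truth.t_true)
    report.velocity_corr = velocity_correlation(fit.velocity.Vs,
                                                truth.Vs_true)
    if transitions and ds.cell_labels is not None:
        cb, cb2, tc, la = boundary_metrics(
            np.asarray(fit.velocity.Vs, float), ds.S, ds.embedding,
            ds.cell_labels, transitions, knn_k)
        report.cbdir, report.cbdir2 = cb, cb2
        report.transcosine, report.lenacc = tc, la
    return report
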