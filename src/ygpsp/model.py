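"""Composition-based degron probability model.

A ridge-regularised logistic regression maps a 17-residue peptide to the
probability that it acts as a degron.  Features are the peptide's
amino-acid composition (counts of each of the 20 residues, or counts/17 in
frequency mode), so predictions are invariant to residue order within the
window.  Training labels come from the screen: peptides with PSI < 2.2 are
degrons (label 1), PSI > 2.8 non-degrons (label 0); mid-range peptides and
peptides with fewer than 50 combined raw reads are excluded.

The fit minimises the mean logistic loss plus (lambda/2)*||w||^2 with the
intercept unpenalised, by damped Newton iteration — a deterministic convex
optimisation, so refits are bit-identical with no random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .library import STANDARD_AA
from .psi import ResidueProfile, running_median

__all__ = [
    "AMINO_ACIDS",
    "TrainingSet",
    "DegronCall",
    "DegronClassifier",
    "encode_peptide",
    "encode_peptides",
    "build_training_set",
    "scan_protein",
    "call_degrons",
    "save_model",
    "load_model",
]

AMINO_ACIDS = tuple(STANDARD_AA)  # alphabetical, fixed feature order
PEPTIDE_LENGTH = 17
FLANK_EXCLUDED = 8  # residues at each end of a protein without a centred window

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Raised when Newton iteration fails to reach the gradient tolerance."""

    def __init__(self, grad_norm: float, max_iter: int):
        super().__init__(
            f"no convergence after {max_iter} iterations (|grad| = {grad_norm:.3e})"
        )
        self.grad_norm = grad_norm


def encode_peptide(peptide: str, mode: str = "counts") -> np.ndarray:
    """20-component amino-acid composition vector (alphabetical order)."""
    if len(peptide) != PEPTIDE_LENGTH:
        raise ModelError(
            f"expected a {PEPTIDE_LENGTH}-mer, got length {len(peptide)}"
        )
    v = np.zeros(len(AMINO_ACIDS))
    for aa in peptide:
        idx = _AA_INDEX.get(aa)
        if idx is None:
            raise ModelError(f"non-standard residue {aa!r}")
        v[idx] += 1.0
    if mode == "freqs":
        v /= PEPTIDE_LENGTH
    elif mode != "counts":
        raise ModelError(f"unknown feature mode {mode!r}")
    return v


def encode_peptides(peptides: Sequence[str], mode: str = "counts") -> np.ndarray:
    return np.vstack([encode_peptide(p, mode) for p in peptides])


@dataclass
class TrainingSet:
    """Labelled 17-mers with screen provenance (PSI and read totals)."""

    peptides: list[str]
    labels: np.ndarray
    psi: np.ndarray
    total_reads: np.ndarray
    n_low_reads: int = 0
    n_midrange: int = 0
    n_boundary: int = 0

    @property
    def class_balance(self) -> tuple[int, int]:
        n1 = int(self.labels.sum())
        return len(self.labels) - n1, n1


def build_training_set(
    psis: pd.DataFrame,
    peptides: Mapping[str, str],
    min_reads: int = 50,
    lo: float = 2.2,
    hi: float = 2.8,
) -> TrainingSet:
    """Filter and label screen peptides for training.

    Peptides with fewer than ``min_reads`` combined raw reads are dropped;
    PSI < ``lo`` labels 1 (degron), PSI > ``hi`` labels 0 (stable);
    mid-range peptides, including the boundary values themselves, are
    excluded (boundary hits counted separately).
    """
    seqs: list[str] = []
    labels: list[int] = []
    psi_kept: list[float] = []
    reads_kept: list[int] = []
    n_low = n_mid = n_boundary = 0
    for r in psis.itertuples(index=False):
        if r.total_reads < min_reads:
            n_low += 1
            continue
        if r.psi == lo or r.psi == hi:
            n_boundary += 1
            continue
        if lo < r.psi < hi:
            n_mid += 1
            continue
        seqs.append(peptides[r.peptide_id])
        labels.append(1 if r.psi < lo else 0)
        psi_kept.append(r.psi)
        reads_kept.append(int(r.total_reads))
    ts = TrainingSet(
        peptides=seqs,
        labels=np.array(labels, dtype=int),
        psi=np.array(psi_kept),
        total_reads=np.array(reads_kept, dtype=int),
        n_low_reads=n_low,
        n_midrange=n_mid,
        n_boundary=n_boundary,
    )
    n0, n1 = ts.class_balance
    if n0 == 0 or n1 == 0:
        raise ModelError(
            f"training set lacks a class after filtering (stable={n0}, degron={n1}; "
            f"dropped: {n_low} low-read, {n_mid} mid-range, {n_boundary} boundary)"
        )
    return ts


class DegronClassifier(ClassifierMixin, BaseEstimator):
    """Ridge logistic regression on amino-acid composition.

    Parameters
    ----------
    ridge_lambda : float, default 0.001
        L2 penalty on the 20 residue weights (mean-loss scale); the
        intercept is never penalised.
    feature_mode : {'counts', 'freqs'}, default 'counts'
        Encode peptides as residue counts or counts/17.
    tol : float
        Convergence threshold on the 2-norm of the penalised-loss gradient.
    max_iter : int
        Newton iteration cap.

    Fitted attributes
    -----------------
    coef_ : (1, 20) weight matrix; intercept_ : (1,) array;
    weights_ : dict residue letter -> weight; n_iter_ : iterations used.
    """

    def __init__(
        self,
        ridge_lambda: float = 0.001,
        feature_mode: str = "counts",
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.ridge_lambda = ridge_lambda
        self.feature_mode = feature_mode
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------
    def _as_features(self, X) -> np.ndarray:
        if len(X) and isinstance(X[0], str):
            return encode_peptides(X, self.feature_mode)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(AMINO_ACIDS):
            raise ModelError(
                f"feature matrix must have {len(AMINO_ACIDS)} columns, got {X.shape}"
            )
        return X

    @staticmethod
    def _loss_grad(theta, X, y, lam):
        n = len(y)
        z = theta[0] + X @ theta[1:]
        p = expit(z)
        # mean log-loss + (lam/2)||w||^2, intercept unpenalised
        eps = 1e-300
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        loss += 0.5 * lam * theta[1:] @ theta[1:]
        r = (p - y) / n
        grad = np.concatenate(([r.sum()], X.T @ r + lam * theta[1:]))
        return loss, grad, p

    def fit(self, X, y):
        """Fit by damped Newton iteration on the penalised mean log-loss."""
        Xm = self._as_features(X)
        classes, y = np.unique(np.asarray(y), return_inverse=True)
        if len(classes) != 2:
            raise ModelError("need exactly two classes")
        y = y.astype(float)
        self.classes_ = classes
        n, d = Xm.shape
        lam = self.ridge_lambda
        theta = np.zeros(d + 1)
        loss, grad, p = self._loss_grad(theta, Xm, y, lam)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            gnorm = np.linalg.norm(grad)
            if gnorm <= self.tol:
                break
            w = p * (1 - p) / n
            X1 = np.hstack([np.ones((n, 1)), Xm])
            H = X1.T @ (X1 * w[:, None])
            H[1:, 1:] += lam * np.eye(d)
            H[np.diag_indices_from(H)] += 1e-12  # guard near-singular Hessian
            step = np.linalg.solve(H, grad)
            # backtracking line search for global convergence
            t = 1.0
            for _ in range(50):
                cand = theta - t * step
                new_loss, new_grad, new_p = self._loss_grad(cand, Xm, y, lam)
                if new_loss <= loss - 1e-4 * t * (grad @ step):
                    break
                t *= 0.5
            theta, loss, grad, p = cand, new_loss, new_grad, new_p
        else:
            raise ConvergenceError(float(np.linalg.norm(grad)), self.max_iter)
        if np.linalg.norm(grad) > self.tol:
            raise ConvergenceError(float(np.linalg.norm(grad)), self.max_iter)
        self.n_iter_ = n_iter
        self.intercept_ = np.array([theta[0]])
        self.coef_ = theta[1:][None, :]
        self.weights_ = {aa: float(wv) for aa, wv in zip(AMINO_ACIDS, theta[1:])}
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self._as_features(X) @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def predict_peptide(self, peptide: str) -> float:
        """Degron probability for a single 17-mer."""
        return float(self.predict_proba([peptide])[0, 1])

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ModelError("model is not fitted")


def scan_protein(
    model: DegronClassifier,
    sequence: str,
    smooth: bool = False,
    spline_smoothing: float | None = None,
) -> ResidueProfile:
    """Per-residue degron probability along a protein.

    Residue i (1-based) in [9, L-8] receives the probability of the 17-mer
    centred on it; the terminal eight residues at each end have no centred
    window and stay undefined.  ``smooth=True`` additionally fits a cubic
    smoothing spline through the defined positions (the discrete track is
    the canonical output).
    """
    L = len(sequence)
    if L < PEPTIDE_LENGTH:
        raise ModelError(f"protein shorter than {PEPTIDE_LENGTH} residues (L={L})")
    windows = [sequence[i : i + PEPTIDE_LENGTH] for i in range(L - PEPTIDE_LENGTH + 1)]
    probs = model.predict_proba(windows)[:, 1]
    raw = np.full(L, np.nan)
    raw[FLANK_EXCLUDED : L - FLANK_EXCLUDED] = probs
    if smooth:
        from scipy.interpolate import UnivariateSpline

        pos = np.nonzero(~np.isnan(raw))[0]
        s = spline_smoothing if spline_smoothing is not None else len(pos) * 1e-3
        spl = UnivariateSpline(pos, raw[pos], k=3, s=s)
        smoothed = np.full(L, np.nan)
        smoothed[pos] = np.clip(spl(pos), 0.0, 1.0)
    else:
        smoothed = raw.copy()
    coverage = (~np.isnan(raw)).astype(int)
    return ResidueProfile(protein_id="", raw=raw, smoothed=smoothed, coverage=coverage)


@dataclass(frozen=True)
class DegronCall:
    """A maximal run of residues whose degron probability exceeds the cutoff."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    peak_probability: float
    cutoff: float


def call_degrons(
    profile: ResidueProfile | np.ndarray,
    cutoff: float = 0.85,
    min_length: int = 1,
    protein_id: str = "",
) -> list[DegronCall]:
    """Maximal above-cutoff runs over the defined part of a probability track."""
    if isinstance(profile, ResidueProfile):
        track = profile.raw
        protein_id = protein_id or profile.protein_id
    else:
        track = np.asarray(profile, dtype=float)
    above = np.where(np.isnan(track), False, track > cutoff)
    calls: list[DegronCall] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                calls.append(
                    DegronCall(
                        protein_id=protein_id,
                        start=start + 1,
                        end=i,
                        peak_probability=float(np.nanmax(track[start:i])),
                        cutoff=cutoff,
                    )
                )
            start = None
    return calls


# ---------------------------------------------------------------------------
# model persistence

def save_model(model: DegronClassifier, path: str | Path, metadata: dict | None = None) -> None:
    model._check_fitted()
    payload = {
        "weights": model.weights_,
        "intercept": float(model.intercept_[0]),
        "lambda": model.ridge_lambda,
        "feature_mode": model.feature_mode,
        "metadata": metadata or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path: str | Path) -> DegronClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    m = DegronClassifier(
        ridge_lambda=payload["lambda"], feature_mode=payload["feature_mode"]
    )
    m.classes_ = np.array([0, 1])
    m.intercept_ = np.array([payload["intercept"]])
    m.coef_ = np.array([[payload["weights"][aa] for aa in AMINO_ACIDS]])
    m.weights_ = {aa: float(payload["weights"][aa]) for aa in AMINO_ACIDS}
    m.n_iter_ = 0
    return m
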