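"""Residual classification per band, cross-band majority voting, metrics.

A test signal is projected into each band's subspace and reconstructed by
each class's projected sub-dictionary via regularized least squares; the
class with the smallest reconstruction residual wins that band. The final
label is the modal per-band label, with residual-based tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding_scatter import DictionaryModel
from .data_model import MultiBandDataset
from .optimize import MBCCModel


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray          # C x C counts, rows = true labels
    per_band_accuracy: np.ndarray  # length M
    n_test: int

    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized view (rows = true labels sum to 1)."""
        sums = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.maximum(sums, 1)


def _band_residuals(Zm: np.ndarray, Gm: np.ndarray,
                    dictionary: DictionaryModel,
                    eps: float = 1e-8) -> np.ndarray:
    """C x n squared reconstruction residuals in band ``m``'s subspace.

    For class ``j``: project dictionary block and signals
    (``D~_j = Gm^T D_j``, ``z^ = Gm^T z``), reconstruct by eps-regularized
    least squares, and return ``||z^ - D~_j coef||^2`` per sample.
    """
    Zp = Gm.T @ Zm
    C = dictionary.n_classes
    out = np.empty((C, Zp.shape[1]))
    for j in range(1, C + 1):
        Dj = Gm.T @ dictionary.sub_dictionary(j)
        gram = Dj.T @ Dj + eps * np.eye(Dj.shape[1])
        recon = Dj @ np.linalg.solve(gram, Dj.T @ Zp)
        out[j - 1] = np.sum((Zp - recon) ** 2, axis=0)
    return out


def band_predict(z: np.ndarray, Gm: np.ndarray,
                 dictionary: DictionaryModel,
                 eps: float = 1e-8) -> tuple[int, np.ndarray]:
    """Classify one signal in one band; returns (label, per-class residuals).

    Ties in the minimal residual go to the smallest class index.
    """
    res = _band_residuals(np.asarray(z, dtype=float).reshape(-1, 1),
                          Gm, dictionary, eps)[:, 0]
    return int(np.argmin(res)) + 1, res


def majority_vote(band_labels: np.ndarray,
                  band_residuals: np.ndarray) -> int:
    """Modal label across bands with residual tie-breaking.

    ``band_residuals`` is M x C. Among labels with the maximal vote count,
    the winner is the one whose voting bands have the smallest summed
    winning residuals; remaining ties go to the smallest class index.
    """
    band_labels = np.asarray(band_labels, dtype=int)
    band_residuals = np.atleast_2d(np.asarray(band_residuals, dtype=float))
    C = band_residuals.shape[1]
    counts = np.bincount(band_labels, minlength=C + 1)[1:]
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if tied.size == 1:
        return int(tied[0])
    scores = []
    for lab in tied:
        voters = np.flatnonzero(band_labels == lab)
        scores.append(band_residuals[voters, lab - 1].sum())
    return int(tied[int(np.argmin(scores))])


def predict(model: MBCCModel, ds: MultiBandDataset,
            eps: float = 1e-8) -> np.ndarray:
    """Predicted labels for every sample column of ``ds``."""
    labels, _, _ = predict_detailed(model, ds, eps)
    return labels


def predict_detailed(model: MBCCModel, ds: MultiBandDataset,
                     eps: float = 1e-8
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels plus per-band labels (M x n) and residuals (M x C x n)."""
    M = model.projections.n_bands
    if ds.n_bands != M:
        raise ValueError(
            f"dataset has {ds.n_bands} bands, model expects {M}")
    if ds.n_features != model.dictionary.D.shape[0]:
        raise ValueError(
            f"dataset has {ds.n_features} features, model expects "
            f"{model.dictionary.D.shape[0]}")
    C = model.dictionary.n_classes
    n = ds.n_samples
    residuals = np.empty((M, C, n))
    for m in range(M):
        residuals[m] = _band_residuals(ds.Z[m], model.projections.per_band(m),
                                       model.dictionary, eps)
    band_labels = residuals.argmin(axis=1) + 1      # M x n
    labels = np.array([
        majority_vote(band_labels[:, j], residuals[:, :, j].T)
        for j in range(n)])
    return labels, band_labels, residuals


def evaluate(model: MBCCModel, test: MultiBandDataset,
             eps: float = 1e-8) -> EvalReport:
    """Accuracy, confusion matrix (rows = true) and per-band accuracies."""
    labels, band_labels, _ = predict_detailed(model, test, eps)
    C = model.dictionary.n_classes
    n = test.n_samples
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(test.labels, labels):
        confusion[t - 1, p - 1] += 1
    per_band = (band_labels == test.labels[None, :]).mean(axis=1)
    return EvalReport(accuracy=float(np.trace(confusion)) / n,
                      confusion=confusion, per_band_accuracy=per_band,
                      n_test=n)
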