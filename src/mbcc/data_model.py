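"""Containers and file I/O for multi-band feature datasets.

A multi-band dataset holds one feature matrix per EEG frequency band. All
bands share the sample axis: column ``j`` of every band describes the same
epoch. Samples are COLUMNS throughout the package, i.e. each band matrix is
``d x n`` (features in rows), matching the convention of subspace methods
that project signals as ``G^T z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when dataset contents violate a structural invariant."""


@dataclass
class MultiBandDataset:
    """Per-band feature matrices sharing a sample axis, plus class labels.

    Parameters
    ----------
    band_names : list of str
        One identifier per band, e.g. ``["delta", "theta", ...]``.
    Z : list of ndarray
        ``M`` matrices, each ``d x n`` (features x samples).
    labels : ndarray
        Length-``n`` integer class labels in ``1..C``.
    original_labels : ndarray, optional
        Label values as they appeared on input, before remapping to the
        contiguous range ``1..C``; kept for reporting.
    """

    band_names: list[str]
    Z: list[np.ndarray]
    labels: np.ndarray
    original_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = [np.asarray(z, dtype=float) for z in self.Z]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.Z) == 0:
            raise DataValidationError("at least one band is required")
        if len(self.band_names) != len(self.Z):
            raise DataValidationError(
                f"{len(self.band_names)} band names for {len(self.Z)} bands"
            )
        shape = self.Z[0].shape
        if len(shape) != 2 or min(shape) < 1:
            raise DataValidationError(f"band matrices must be 2-D, got {shape}")
        for name, z in zip(self.band_names, self.Z):
            if z.shape != shape:
                raise DataValidationError(
                    "inconsistent band shapes: "
                    f"band '{name}' is {z.shape}, expected {shape}"
                )
        if self.labels.shape != (shape[1],):
            raise DataValidationError(
                f"label/sample mismatch: {self.labels.size} labels "
                f"for {shape[1]} samples"
            )
        c = self.n_classes
        present = np.unique(self.labels)
        if present[0] < 1 or not np.array_equal(present, np.arange(1, c + 1)):
            raise DataValidationError(
                f"labels must cover 1..{c} contiguously, got {present.tolist()}"
            )
        if self.original_labels is None:
            self.original_labels = self.labels.copy()

    @property
    def n_bands(self) -> int:
        return len(self.Z)

    @property
    def n_features(self) -> int:
        return self.Z[0].shape[0]

    @property
    def n_samples(self) -> int:
        return self.Z[0].shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def subset(self, idx: np.ndarray) -> "MultiBandDataset":
        """Dataset restricted to the sample columns in ``idx`` (kept order)."""
        idx = np.asarray(idx, dtype=int)
        return MultiBandDataset(
            band_names=list(self.band_names),
            Z=[z[:, idx] for z in self.Z],
            labels=self.labels[idx],
            original_labels=self.original_labels[idx],
        )

    def zscore(self, eps: float = 1e-12) -> "MultiBandDataset":
        """Per-feature, per-band standardization (mean 0, sd 1).

        Off by default everywhere in the package; exposed because band-power
        features can differ by orders of magnitude across channels.
        """
        Zs = []
        for z in self.Z:
            mu = z.mean(axis=1, keepdims=True)
            sd = z.std(axis=1, keepdims=True)
            Zs.append((z - mu) / np.maximum(sd, eps))
        return MultiBandDataset(list(self.band_names), Zs, self.labels.copy(),
                                self.original_labels.copy())


@dataclass
class ModelConfig:
    """Hyperparameters of the multi-band classifier.

    ``alpha`` weighs the PCA-like variance-retention regularizer on the
    shared projection component; ``sigma`` mixes shared and band-specific
    projection components (``G^m = (1-sigma) G^0 + sigma G~^m``) and defaults
    to ``1 - alpha``. ``lambda_code`` is the ridge coding penalty,
    ``atoms_per_class`` the per-class dictionary size, and ``p`` the subspace
    dimension (defaults to 90% of the feature dimension at fit time).
    """

    alpha: float = 0.5
    sigma: float | None = None
    lambda_code: float = 0.01
    atoms_per_class: int = 15
    p: int | None = None
    lambda_rho: float = 0.5
    eta: float = 1e-2
    max_iter: int = 50
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        # alpha = 0 drops the variance-retention term entirely (the
        # band-specific reduction of the model) and is allowed.
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.sigma is None:
            self.sigma = 1.0 - self.alpha
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        for name in ("lambda_code", "lambda_rho", "eta", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("atoms_per_class", "max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.p is not None and self.p < 1:
            raise ValueError(f"p must be a positive integer, got {self.p}")

    def resolve(self, d: int, n: int, C: int) -> "ModelConfig":
        """Fill data-dependent defaults and sanity-check against (d, n, C)."""
        p = self.p if self.p is not None else max(1, round(0.9 * d))
        if p > d:
            raise ValueError(f"p={p} exceeds feature dimension d={d}")
        if self.atoms_per_class * C > n:
            warnings.warn(
                f"dictionary size K={self.atoms_per_class * C} exceeds the "
                f"number of training samples n={n}; the coding problem is "
                "underdetermined", stacklevel=2)
        out = ModelConfig(
            alpha=self.alpha, sigma=self.sigma, lambda_code=self.lambda_code,
            atoms_per_class=self.atoms_per_class, p=p,
            lambda_rho=self.lambda_rho, eta=self.eta,
            max_iter=self.max_iter, tol=self.tol, seed=self.seed)
        return out

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "sigma": self.sigma,
            "lambda_code": self.lambda_code,
            "atoms_per_class": self.atoms_per_class, "p": self.p,
            "lambda_rho": self.lambda_rho, "eta": self.eta,
            "max_iter": self.max_iter, "tol": self.tol, "seed": self.seed,
        }


# ---------------------------------------------------------------- file I/O

def _read_matrix(path: str | Path, header: bool = False) -> np.ndarray:
    """Read a delimited numeric matrix (comma or tab auto-detected)."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first \
        else ","
    try:
        # C engine + round_trip parsing keeps save -> load bit-exact
        df = pd.read_csv(path, sep=sep, header=0 if header else None,
                         comment="#", float_precision="round_trip")
        mat = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataValidationError(
            f"could not parse numeric matrix from {path}: {exc}") from exc
    if mat.ndim != 2:
        raise DataValidationError(f"{path}: expected a 2-D matrix")
    if not np.all(np.isfinite(mat)):
        bad = np.argwhere(~np.isfinite(mat))[0]
        raise DataValidationError(
            f"{path}: non-finite value at row {bad[0] + 1}, "
            f"column {bad[1] + 1}")
    return mat


def _read_labels(path: str | Path) -> np.ndarray:
    raw = Path(path).read_text().split()
    try:
        labels = np.array([int(tok) for tok in raw])
    except ValueError as exc:
        raise DataValidationError(
            f"could not parse integer labels from {path}: {exc}") from exc
    return labels


def remap_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary integer labels to contiguous 1..C.

    Classes are numbered by order of first appearance. Returns
    ``(remapped, original)``.
    """
    labels = np.asarray(labels, dtype=int)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    lut = {orig: i + 1 for i, orig in enumerate(order)}
    return np.array([lut[v] for v in labels]), labels


def load_multiband_dataset(
    band_paths: list[str | Path],
    labels_path: str | Path,
    band_names: list[str] | None = None,
    header: bool = False,
) -> MultiBandDataset:
    """Load per-band delimited matrices (d x n, samples in columns) + labels.

    Labels are remapped to contiguous ``1..C`` preserving order of first
    appearance; original values are retained on the dataset.
    """
    Z = [_read_matrix(p, header=header) for p in band_paths]
    labels, original = remap_labels(_read_labels(labels_path))
    if band_names is None:
        band_names = [Path(p).stem for p in band_paths]
    return MultiBandDataset(band_names=band_names, Z=Z, labels=labels,
                            original_labels=original)


def save_multiband_dataset(ds: MultiBandDataset, out_dir: str | Path,
                           delimiter: str = ",") -> dict[str, Path]:
    """Write one ``<band>.csv`` per band plus ``labels.txt``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, z in zip(ds.band_names, ds.Z):
        p = out_dir / f"{name}.csv"
        np.savetxt(p, z, delimiter=delimiter, fmt="%.17g")
        paths[name] = p
    lp = out_dir / "labels.txt"
    np.savetxt(lp, ds.original_labels, fmt="%d")
    paths["labels"] = lp
    return paths


def stratified_split(
    ds: MultiBandDataset, train_fraction: float, seed: int
) -> tuple[MultiBandDataset, MultiBandDataset]:
    """Per-class random split into train/test column subsets.

    Per-class proportions are preserved to within one sample, and every
    class keeps at least one sample on each side. Deterministic given seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in range(1, ds.n_classes + 1):
        members = np.flatnonzero(ds.labels == c)
        if members.size < 2:
            raise DataValidationError(
                f"class {c} has {members.size} sample(s); "
                "need at least 2 to split")
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))
    return ds.subset(train_idx), ds.subset(test_idx)
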