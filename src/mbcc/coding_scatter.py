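"""Class-aware coding, reconstruction scatter matrices and stacked operators.

The discriminative core of the model is a Fisher criterion on coded
reconstruction errors. For a sample with code ``a``, the delta mask keeps
only coefficients on atoms of the sample's own class and the xi mask keeps
the complementary coefficients, so the within-class residual is
``z - D delta(a)`` and the between-class residual ``z - D xi(a)``. Per band
these residual outer-product sums give the scatters ``Ww^m`` and ``Wb^m``;
stacking them through the block selectors that realize
``G^m = (1 - sigma) G^0 + sigma G~^m`` yields the operators Lambda, Theta
and H of the stacked trace-ratio problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DictionaryModel:
    """Shared dictionary partitioned into per-class sub-dictionaries.

    ``D`` is ``d x K`` with unit-Euclidean-norm atoms (columns); atoms
    ``class_offsets[c] .. class_offsets[c+1]-1`` (0-based) belong to class
    ``c+1``. ``K = C * atoms_per_class`` when classes are balanced, but
    unequal block sizes are allowed.
    """

    D: np.ndarray
    class_offsets: np.ndarray  # length C+1, offsets[0]=0, offsets[C]=K

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.class_offsets = np.asarray(self.class_offsets, dtype=int)
        if self.class_offsets[0] != 0 or self.class_offsets[-1] != self.K:
            raise ValueError("class offsets must partition 0..K")
        if np.any(np.diff(self.class_offsets) < 1):
            raise ValueError("every class needs at least one atom")
        norms = np.linalg.norm(self.D, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("dictionary atoms must have unit Euclidean norm")

    @property
    def K(self) -> int:
        return self.D.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_offsets) - 1

    def class_block(self, c: int) -> np.ndarray:
        """Atom indices (0-based) of class ``c`` (1-based label)."""
        return np.arange(self.class_offsets[c - 1], self.class_offsets[c])

    def sub_dictionary(self, c: int) -> np.ndarray:
        return self.D[:, self.class_block(c)]

    def atom_classes(self) -> np.ndarray:
        """Length-K vector giving each atom's class label (1-based)."""
        out = np.empty(self.K, dtype=int)
        for c in range(1, self.n_classes + 1):
            out[self.class_block(c)] = c
        return out


@dataclass
class ScatterSet:
    """Per-band reconstruction scatters plus the stacked operators."""

    Ww: list[np.ndarray]          # M within-class scatters, d x d
    Wb: list[np.ndarray]          # M between-class scatters, d x d
    Theta_band: list[np.ndarray]  # M data Grams Z^m (Z^m)^T, d x d
    Lambda: np.ndarray            # (M+1)d x (M+1)d stacked within operator
    Theta: np.ndarray             # stacked PCA-regularizer operator
    H: np.ndarray                 # stacked between operator


def normalize_atoms(D: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Rescale columns to unit Euclidean norm (zero columns left at eps)."""
    norms = np.maximum(np.linalg.norm(D, axis=0, keepdims=True), eps)
    return D / norms


def class_support_masks(labels: np.ndarray,
                        dictionary: DictionaryModel
                        ) -> tuple[np.ndarray, np.ndarray]:
    """K x n binary masks: own-class (delta) and other-class (xi) support.

    ``delta[k, j] = 1`` iff atom ``k`` belongs to the class of sample ``j``;
    ``xi = 1 - delta``, so ``delta(a) + xi(a) = a`` for any code.
    """
    labels = np.asarray(labels, dtype=int)
    C = dictionary.n_classes
    if labels.min() < 1 or labels.max() > C:
        raise ValueError(
            f"labels must lie in 1..{C}, got range "
            f"[{labels.min()}, {labels.max()}]")
    atom_cls = dictionary.atom_classes()
    delta = (atom_cls[:, None] == labels[None, :]).astype(float)
    return delta, 1.0 - delta


def ridge_code(Zp: np.ndarray, Dp: np.ndarray,
               lambda_code: float) -> np.ndarray:
    """Closed-form ridge coding ``A = (Dp^T Dp + lam I)^{-1} Dp^T Zp``.

    The unique minimizer of ``||Zp - Dp A||_F^2 + lam ||A||_F^2``; ``lam > 0``
    makes the system strictly positive definite regardless of ``Dp`` rank.
    """
    if lambda_code <= 0:
        raise ValueError("lambda_code must be positive")
    Zp = np.asarray(Zp, dtype=float)
    Dp = np.asarray(Dp, dtype=float)
    K = Dp.shape[1]
    gram = Dp.T @ Dp + lambda_code * np.eye(K)
    return np.linalg.solve(gram, Dp.T @ Zp)


def ista_code(Zp: np.ndarray, Dp: np.ndarray, lambda_code: float,
              max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """l1-penalized coding by ISTA (iterative soft thresholding).

    Provided for fidelity experiments against the stated l1 objective
    ``||Zp - Dp A||_F^2 + lam ||A||_1``; the training loop uses the ridge
    closed form.
    """
    Zp = np.asarray(Zp, dtype=float)
    Dp = np.asarray(Dp, dtype=float)
    L = max(np.linalg.norm(Dp, 2) ** 2 * 2.0, 1e-12)  # Lipschitz of grad
    A = np.zeros((Dp.shape[1], Zp.shape[1]))
    thr = lambda_code / L
    for _ in range(max_iter):
        grad = 2.0 * (Dp.T @ (Dp @ A - Zp))
        A_new = A - grad / L
        A_new = np.sign(A_new) * np.maximum(np.abs(A_new) - thr, 0.0)
        if np.max(np.abs(A_new - A)) < tol:
            A = A_new
            break
        A = A_new
    return A


def reconstruction_scatters(Z: np.ndarray, dictionary: DictionaryModel,
                            A: np.ndarray, delta_mask: np.ndarray,
                            xi_mask: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Within/between reconstruction scatters of one band.

    ``Ww = Rw Rw^T`` with ``Rw = Z - D (A * delta)``, and ``Wb`` likewise
    with the xi mask. Both are symmetric PSD by construction; they are
    symmetrized explicitly to shed accumulated round-off.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != dictionary.D.shape[0] or A.shape != delta_mask.shape \
            or A.shape[0] != dictionary.K or A.shape[1] != Z.shape[1]:
        raise ValueError(
            f"shape mismatch: Z {Z.shape}, D {dictionary.D.shape}, "
            f"A {A.shape}")
    Rw = Z - dictionary.D @ (A * delta_mask)
    Rb = Z - dictionary.D @ (A * xi_mask)
    Ww = Rw @ Rw.T
    Wb = Rb @ Rb.T
    return 0.5 * (Ww + Ww.T), 0.5 * (Wb + Wb.T)


def band_gram(Z: np.ndarray) -> np.ndarray:
    """Data Gram ``Theta^m = Z Z^T`` of one band (the PCA-regularizer seed)."""
    Z = np.asarray(Z, dtype=float)
    Th = Z @ Z.T
    return 0.5 * (Th + Th.T)


def band_selector(m: int, M: int, d: int, sigma: float) -> np.ndarray:
    """Block selector realizing ``G^m = Omega^m G`` on the stacked G.

    ``d x (M+1)d`` with ``(1-sigma) I`` in block 0 (the shared component)
    and ``sigma I`` in block ``m`` (that band's specific component); zeros
    elsewhere. ``m`` is 1-based.
    """
    Om = np.zeros((d, (M + 1) * d))
    Om[:, :d] = (1.0 - sigma) * np.eye(d)
    Om[:, m * d:(m + 1) * d] += sigma * np.eye(d)
    return Om


def stack_operators(Ww: list[np.ndarray], Wb: list[np.ndarray],
                    Theta_band: list[np.ndarray], sigma: float
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the stacked operators Lambda, Theta and H.

    With ``Omega^m`` the two-block selector above and ``Delta^m`` selecting
    the shared block only:

    - ``Lambda = sum_m (Omega^m)^T Ww^m Omega^m``
    - ``H      = sum_m (Omega^m)^T Wb^m Omega^m``
    - ``Theta  = sum_m (Delta^m)^T Theta^m Delta^m``  (block (0,0) only)

    so that ``Tr(G^T Lambda G) = sum_m Tr((G^m)^T Ww^m G^m)`` for any
    stacked ``G = [G^0; G~^1; ...; G~^M]`` with
    ``G^m = (1-sigma) G^0 + sigma G~^m``, and analogously for H/Wb. Rather
    than materializing the selectors, the four nonzero blocks each band
    contributes are written directly:

    block(0,0) += (1-s)^2 W,  block(0,m) += s(1-s) W,
    block(m,0) += s(1-s) W,   block(m,m) += s^2 W.
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must be in [0, 1], got {sigma}")
    M = len(Ww)
    if M < 1 or len(Wb) != M or len(Theta_band) != M:
        raise ValueError("need matching non-empty scatter lists")
    d = Ww[0].shape[0]
    size = (M + 1) * d
    Lambda = np.zeros((size, size))
    H = np.zeros((size, size))
    Theta = np.zeros((size, size))
    s, t = sigma, 1.0 - sigma
    for m in range(1, M + 1):
        for W, Out in ((Ww[m - 1], Lambda), (Wb[m - 1], H)):
            Out[:d, :d] += t * t * W
            Out[:d, m * d:(m + 1) * d] += t * s * W
            Out[m * d:(m + 1) * d, :d] += s * t * W
            Out[m * d:(m + 1) * d, m * d:(m + 1) * d] += s * s * W
        Theta[:d, :d] += Theta_band[m - 1]
    return Lambda, Theta, H


def build_scatter_set(Z_bands: list[np.ndarray], dictionary: DictionaryModel,
                      codes: list[np.ndarray], delta_mask: np.ndarray,
                      xi_mask: np.ndarray, sigma: float) -> ScatterSet:
    """Per-band scatters + stacked operators in one pass (training helper)."""
    Ww, Wb, Th = [], [], []
    for Z, A in zip(Z_bands, codes):
        ww, wb = reconstruction_scatters(Z, dictionary, A, delta_mask, xi_mask)
        Ww.append(ww)
        Wb.append(wb)
        Th.append(band_gram(Z))
    Lambda, Theta, H = stack_operators(Ww, Wb, Th, sigma)
    return ScatterSet(Ww=Ww, Wb=Wb, Theta_band=Th,
                      Lambda=Lambda, Theta=Theta, H=H)
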