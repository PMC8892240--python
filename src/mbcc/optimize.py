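"""Trace-ratio projection solver and alternating training loops.

Training alternates three blocks until the objective stalls:

1. ridge coding of every band against the shared dictionary;
2. rebuilding the reconstruction scatters, stacking them, and solving the
   trace-ratio problem
   ``min_G Tr(G^T (Lambda - alpha Theta) G) / Tr(G^T H G), G^T G = I``
   via the scalar root ``F(rho) = min_G Tr(G^T (Lambda - alpha Theta
   - rho H) G) = 0`` with eigen-decompositions;
3. a backtracked gradient step on each per-class sub-dictionary that can
   only decrease the objective.

The baseline variant learns fully independent per-band projections from a
per-band eigen-problem with an adaptive Fisher weight, sharing the coding,
scatter and dictionary machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .coding_scatter import (
    DictionaryModel,
    build_scatter_set,
    class_support_masks,
    normalize_atoms,
    ridge_code,
)
from .data_model import ModelConfig, MultiBandDataset


class DegenerateScatterError(RuntimeError):
    """Between-class scatter vanished on the current subspace."""


@dataclass
class ProjectionSet:
    """Shared + band-specific projection components.

    Band ``m`` projects with ``G^m = (1 - sigma) G^0 + sigma G~^m``. For the
    jointly-learned model the STACKED matrix ``[G^0; G~^1; ...; G~^M]`` has
    orthonormal columns (that is what the eigen-solver returns); the
    per-band baseline instead makes each ``G^m`` orthonormal on its own,
    indicated by ``stacked_orthonormal=False``.
    """

    G0: np.ndarray
    Gtilde: list[np.ndarray]
    sigma: float
    stacked_orthonormal: bool = True

    @property
    def n_bands(self) -> int:
        return len(self.Gtilde)

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.G0] + list(self.Gtilde))

    def per_band(self, m: int) -> np.ndarray:
        """Effective projection of band ``m`` (0-based)."""
        return (1.0 - self.sigma) * self.G0 + self.sigma * self.Gtilde[m]

    def band_projections(self) -> list[np.ndarray]:
        return [self.per_band(m) for m in range(self.n_bands)]

    @classmethod
    def from_stacked(cls, G: np.ndarray, M: int, d: int,
                     sigma: float) -> "ProjectionSet":
        if G.shape[0] != (M + 1) * d:
            raise ValueError(
                f"stacked matrix has {G.shape[0]} rows, expected {(M+1)*d}")
        return cls(G0=G[:d], Gtilde=[G[(m + 1) * d:(m + 2) * d]
                                     for m in range(M)], sigma=sigma)


@dataclass
class TraceRatioResult:
    G: np.ndarray          # (M+1)d x p, orthonormal columns
    rho_star: float
    gamma: np.ndarray      # p smallest eigenvalues at rho_star
    iterations: int
    residual: float        # |F(rho_star)|


@dataclass
class MBCCModel:
    """A trained multi-band classifier: projections + shared dictionary."""

    config: ModelConfig
    projections: ProjectionSet
    dictionary: DictionaryModel
    history: list[dict]
    band_names: list[str]
    kind: str = "mbcc"

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` archive of named arrays."""
        meta = {"config": self.config.to_dict(), "kind": self.kind,
                "band_names": self.band_names, "history": self.history,
                "sigma": self.projections.sigma,
                "stacked_orthonormal": self.projections.stacked_orthonormal}
        np.savez(
            path, G0=self.projections.G0,
            Gtilde=np.stack(self.projections.Gtilde),
            D=self.dictionary.D,
            class_offsets=self.dictionary.class_offsets,
            meta=np.array(json.dumps(meta)))

    @classmethod
    def load(cls, path: str | Path) -> "MBCCModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            proj = ProjectionSet(
                G0=f["G0"], Gtilde=list(f["Gtilde"]), sigma=meta["sigma"],
                stacked_orthonormal=meta["stacked_orthonormal"])
            dictionary = DictionaryModel(D=f["D"],
                                         class_offsets=f["class_offsets"])
        return cls(config=ModelConfig(**meta["config"]), projections=proj,
                   dictionary=dictionary, history=meta["history"],
                   band_names=meta["band_names"], kind=meta["kind"])


# ------------------------------------------------------- trace-ratio solver

def _check_symmetric(mat: np.ndarray, name: str, atol: float = 1e-8) -> None:
    if np.max(np.abs(mat - mat.T)) > atol:
        raise ValueError(f"{name} is not symmetric (asymmetry > {atol})")


def _fix_signs(G: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: largest-|entry| made positive.

    ``np.argmax`` already resolves magnitude ties at the lowest row index.
    """
    idx = np.argmax(np.abs(G), axis=0)
    signs = np.sign(G[idx, np.arange(G.shape[1])])
    signs[signs == 0] = 1.0
    return G * signs


def f_rho(rho: float, Anum: np.ndarray, H: np.ndarray,
          p: int) -> tuple[float, np.ndarray]:
    """Evaluate ``F(rho) = min_{G^T G = I} Tr(G^T (Anum - rho H) G)``.

    The minimum is the sum of the ``p`` smallest eigenvalues of
    ``Anum - rho H``; the minimizer is the corresponding orthonormal
    eigenvector block. ``F`` is non-increasing in ``rho`` whenever ``H`` is
    PSD and nonzero.
    """
    _check_symmetric(Anum, "Anum")
    _check_symmetric(H, "H")
    if not 1 <= p <= Anum.shape[0]:
        raise ValueError(f"p={p} out of range for size {Anum.shape[0]}")
    shifted = Anum - rho * H
    evals, evecs = np.linalg.eigh(0.5 * (shifted + shifted.T))
    return float(evals[:p].sum()), _fix_signs(evecs[:, :p])


def solve_projection(Lambda: np.ndarray, Theta: np.ndarray, H: np.ndarray,
                     alpha: float, p: int, lambda_rho: float = 0.5,
                     tol: float = 1e-8, max_iter: int = 100,
                     rho0: float = 0.0,
                     eps_reg: float = 0.0) -> TraceRatioResult:
    """Solve the stacked trace-ratio problem for the projection matrix.

    Iterates the damped Newton update ``rho <- rho + lambda_rho * F(rho) /
    Tr(G^T H G)`` (``F'(rho) = -Tr(G^T H G)``) from ``rho0``, falling back
    to bisection whenever the update leaves the sign-change bracket, until
    ``|F(rho)| <= tol * (1 + |Tr(G^T Anum G)|)``. Returns the eigenvectors
    of the final solve; deterministic (eigenvector signs are fixed).

    When ``H`` is singular enough that a p-dimensional subspace can null the
    denominator (its p-smallest eigen-sum is ~0 — always the case for the
    stacked operators, whose common null space carries a negative variance
    term, making the raw ratio unbounded below), the solve is restricted to
    ``range(H)``, the standard remedy for a singular Fisher denominator.
    ``eps_reg > 0`` instead adds ``eps_reg * I`` to ``H``.
    """
    Anum = Lambda - alpha * Theta
    Anum = 0.5 * (Anum + Anum.T)
    _check_symmetric(H, "H")
    basis = None
    if eps_reg:
        H = H + eps_reg * np.eye(H.shape[0])
    else:
        h_evals, h_evecs = np.linalg.eigh(0.5 * (H + H.T))
        cut = max(1e-10 * max(h_evals[-1], 0.0), 1e-12)
        if h_evals[:p].sum() <= cut * p:
            keep = h_evals > cut
            rank = int(keep.sum())
            if rank < p:
                raise DegenerateScatterError(
                    f"between-class operator has rank {rank} < p={p}; "
                    "re-run with eps_reg > 0 to regularize H")
            basis = h_evecs[:, keep]
            Anum = basis.T @ Anum @ basis
            H = basis.T @ H @ basis
            Anum = 0.5 * (Anum + Anum.T)
            H = 0.5 * (H + H.T)
    rho = float(rho0)
    lo, hi = -np.inf, np.inf      # F(lo) > 0 > F(hi); F non-increasing
    value, G = f_rho(rho, Anum, H, p)
    it = 0
    for it in range(1, max_iter + 1):
        scale = tol * (1.0 + abs(float(np.trace(G.T @ Anum @ G))))
        if abs(value) <= scale:
            break
        denom = float(np.trace(G.T @ H @ G))
        if denom <= 1e-12:
            raise DegenerateScatterError(
                "degenerate between-class scatter: Tr(G^T H G) ~ 0; "
                "re-run with eps_reg > 0 to regularize H")
        if value > 0:
            lo = max(lo, rho)
        else:
            hi = min(hi, rho)
        rho_new = rho + lambda_rho * value / denom
        if not (lo < rho_new < hi):
            if np.isfinite(lo) and np.isfinite(hi):
                rho_new = 0.5 * (lo + hi)          # bracketing fallback
            else:
                rho_new = np.clip(rho_new, lo, hi)
                if not np.isfinite(rho_new):
                    rho_new = rho + np.sign(value)
        rho = float(rho_new)
        value, G = f_rho(rho, Anum, H, p)
    evals = np.linalg.eigh(Anum - rho * H)[0][:p]
    if basis is not None:
        G = _fix_signs(basis @ G)
    return TraceRatioResult(G=G, rho_star=rho, gamma=evals,
                            iterations=it, residual=abs(value))


# ------------------------------------------------- dictionary update block

def fisher_energies(Z_bands: list[np.ndarray], D: np.ndarray,
                    codes: list[np.ndarray], delta_mask: np.ndarray,
                    xi_mask: np.ndarray, G_bands: list[np.ndarray]
                    ) -> tuple[float, float]:
    """Projected within/between residual energies summed over bands.

    ``N = sum_m ||(G^m)^T (Z^m - D (A^m * delta))||_F^2`` and ``B`` likewise
    with the xi mask — the numerator and denominator of the Fisher quotient
    as a function of the dictionary at fixed codes and projections.
    """
    N = B = 0.0
    for Z, A, G in zip(Z_bands, codes, G_bands):
        Rw = Z - D @ (A * delta_mask)
        Rb = Z - D @ (A * xi_mask)
        N += float(np.sum((G.T @ Rw) ** 2))
        B += float(np.sum((G.T @ Rb) ** 2))
    return N, B


def dictionary_gradient(dictionary: DictionaryModel, cls: int,
                        Z_bands: list[np.ndarray], codes: list[np.ndarray],
                        delta_mask: np.ndarray, xi_mask: np.ndarray,
                        G_bands: list[np.ndarray]) -> np.ndarray:
    """Gradient of the Fisher quotient w.r.t. the class-``cls`` block.

    With ``N``/``B`` the projected within/between residual energies, the
    quotient rule gives ``dJ/dDj = (dN/dDj * B - N * dB/dDj) / B^2`` where
    ``dN/dDj = -2 sum_m G^m (G^m)^T Rw^m (Aw^m[block_j])^T`` (and the xi
    analogue for ``B``). Validated against central finite differences.
    """
    D = dictionary.D
    block = dictionary.class_block(cls)
    N, B = fisher_energies(Z_bands, D, codes, delta_mask, xi_mask, G_bands)
    if B <= 1e-12:
        raise DegenerateScatterError(
            "degenerate between-class residual energy in dictionary update; "
            "re-run with eps_reg > 0")
    gN = np.zeros((D.shape[0], block.size))
    gB = np.zeros_like(gN)
    for Z, A, G in zip(Z_bands, codes, G_bands):
        Aw = A * delta_mask
        Ab = A * xi_mask
        M = G @ G.T
        gN += -2.0 * M @ (Z - D @ Aw) @ Aw[block].T
        gB += -2.0 * M @ (Z - D @ Ab) @ Ab[block].T
    return (gN * B - N * gB) / (B * B)


def dictionary_step(dictionary: DictionaryModel,
                    gradients: list[np.ndarray], eta: float,
                    objective: Callable[[np.ndarray], float],
                    max_halvings: int = 10
                    ) -> tuple[DictionaryModel, float]:
    """Backtracked simultaneous gradient step on all class blocks.

    Tries ``D_j <- D_j - eta * grad_j`` for every class at once, re-normalizes
    atoms to unit norm, and accepts the first step size (halving ``eta`` up
    to ``max_halvings`` times) for which the supplied objective does not
    increase. If none qualifies the dictionary is returned unchanged with
    ``eta_used = 0``.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    D0 = dictionary.D
    base = objective(D0)
    full_grad = np.zeros_like(D0)
    for c, g in enumerate(gradients, start=1):
        full_grad[:, dictionary.class_block(c)] = g
    step = eta
    for _ in range(max_halvings + 1):
        D_new = normalize_atoms(D0 - step * full_grad)
        if objective(D_new) <= base + 1e-12:
            return DictionaryModel(D=D_new,
                                   class_offsets=dictionary.class_offsets), step
        step *= 0.5
    return dictionary, 0.0


# --------------------------------------------------------- training loops

def init_dictionary(train: MultiBandDataset,
                    atoms_per_class: int) -> DictionaryModel:
    """Seed the dictionary from the band-averaged training data.

    Per class: the ``atoms_per_class`` columns of largest Euclidean norm
    (ties broken by column index), unit-normalized. Deterministic.
    """
    Zbar = np.mean(train.Z, axis=0)
    C = train.n_classes
    blocks = []
    for c in range(1, C + 1):
        members = np.flatnonzero(train.labels == c)
        norms = np.linalg.norm(Zbar[:, members], axis=0)
        # stable argsort on -norms keeps lowest column index among ties
        order = np.argsort(-norms, kind="stable")[:atoms_per_class]
        chosen = Zbar[:, members[np.sort(order)]]
        if chosen.shape[1] < atoms_per_class:
            reps = -(-atoms_per_class // chosen.shape[1])
            chosen = np.tile(chosen, reps)[:, :atoms_per_class]
        blocks.append(normalize_atoms(chosen))
    offsets = np.arange(C + 1) * atoms_per_class
    return DictionaryModel(D=np.hstack(blocks), class_offsets=offsets)


def _code_bands(Z_bands: list[np.ndarray], D: np.ndarray,
                lam: float) -> list[np.ndarray]:
    """Per-band ridge codes against the original-space dictionary.

    The coding update's closed form keeps the dictionary Gram in the
    original d-dimensional space, which is also where the reconstruction
    scatters live; coding against projected dictionaries instead feeds the
    rank of the current projection back into the codes and (because the
    per-band projections of the stacked solve can be far from isometries)
    destabilizes the alternation.
    """
    return [ridge_code(Z, D, lam) for Z in Z_bands]


def fit_mbcc(train: MultiBandDataset, cfg: ModelConfig,
             eps_reg: float = 0.0) -> MBCCModel:
    """Train the joint shared/band-specific subspace + dictionary model.

    Alternates per-band ridge coding, the stacked trace-ratio projection
    solve, and a backtracked dictionary step, until the relative change of
    the trace-ratio objective falls below ``cfg.tol`` or ``cfg.max_iter``
    is reached. History records the objective, rho, the dictionary step
    size actually used, and the orthonormality defect of the stacked G.
    """
    cfg = cfg.resolve(train.n_features, train.n_samples, train.n_classes)
    dictionary = init_dictionary(train, cfg.atoms_per_class)
    delta_mask, xi_mask = class_support_masks(train.labels, dictionary)
    Z_bands = train.Z
    M = train.n_bands
    G_bands: list[np.ndarray] | None = None
    proj: ProjectionSet | None = None
    history: list[dict] = []
    prev_obj = np.inf
    rho = 0.0
    for it in range(1, cfg.max_iter + 1):
        codes = _code_bands(Z_bands, dictionary.D, cfg.lambda_code)
        scat = build_scatter_set(Z_bands, dictionary, codes,
                                 delta_mask, xi_mask, cfg.sigma)
        try:
            res = solve_projection(scat.Lambda, scat.Theta, scat.H,
                                   cfg.alpha, cfg.p,
                                   lambda_rho=cfg.lambda_rho,
                                   rho0=rho, eps_reg=eps_reg)
        except DegenerateScatterError as exc:
            raise DegenerateScatterError(
                f"iteration {it}: {exc}") from exc
        rho = res.rho_star
        G = res.G
        ortho_defect = float(np.max(np.abs(G.T @ G - np.eye(cfg.p))))
        proj = ProjectionSet.from_stacked(G, M, train.n_features, cfg.sigma)
        G_bands = proj.band_projections()

        Anum = scat.Lambda - cfg.alpha * scat.Theta
        obj_before = float(np.trace(G.T @ Anum @ G)
                           / np.trace(G.T @ scat.H @ G))
        # Dictionary step: descent direction from the Fisher quotient,
        # backtracking monitored on the full objective (the variance term
        # is constant in D at fixed G, codes).
        theta_term = cfg.alpha * float(np.trace(G.T @ scat.Theta @ G))

        def full_objective(D: np.ndarray) -> float:
            N, B = fisher_energies(Z_bands, D, codes, delta_mask,
                                   xi_mask, G_bands)
            if B <= 1e-12:
                return np.inf
            return (N - theta_term) / B

        grads = [dictionary_gradient(dictionary, c, Z_bands, codes,
                                     delta_mask, xi_mask, G_bands)
                 for c in range(1, train.n_classes + 1)]
        dictionary, eta_used = dictionary_step(dictionary, grads, cfg.eta,
                                               full_objective)
        obj = full_objective(dictionary.D)
        history.append({"iteration": it, "objective": obj,
                        "objective_before_dictionary": obj_before,
                        "rho": rho, "eta": eta_used,
                        "ortho_defect": ortho_defect,
                        "rho_residual": res.residual})
        if np.isfinite(prev_obj) and \
                abs(prev_obj - obj) <= cfg.tol * (1.0 + abs(prev_obj)):
            break
        prev_obj = obj
    return MBCCModel(config=cfg, projections=proj, dictionary=dictionary,
                     history=history, band_names=list(train.band_names),
                     kind="mbcc")


def fit_opfddl(train: MultiBandDataset, cfg: ModelConfig,
               eps_reg: float = 0.0) -> MBCCModel:
    """Train the per-band baseline (independent projections, shared dict).

    Each band's projection comes from the ``p`` smallest eigenvectors of
    ``lam^2 Ww^m - lam Wb^m`` with the adaptive weight
    ``lam = tr(G^T Wb G) / (2 tr(G^T Ww G))`` summed over bands; the
    dictionary uses the same finite-difference-validated gradient and
    backtracking as the joint model. Stored as a ProjectionSet with
    ``sigma = 1`` (all band-specific), per-band orthonormal.
    """
    cfg = cfg.resolve(train.n_features, train.n_samples, train.n_classes)
    dictionary = init_dictionary(train, cfg.atoms_per_class)
    delta_mask, xi_mask = class_support_masks(train.labels, dictionary)
    Z_bands = train.Z
    d = train.n_features
    G_bands: list[np.ndarray] | None = None
    history: list[dict] = []
    lam = 1.0
    prev_obj = np.inf
    for it in range(1, cfg.max_iter + 1):
        codes = _code_bands(Z_bands, dictionary.D, cfg.lambda_code)
        scat = build_scatter_set(Z_bands, dictionary, codes,
                                 delta_mask, xi_mask, 1.0)
        G_bands = []
        for m in range(train.n_bands):
            shifted = lam * lam * scat.Ww[m] - lam * scat.Wb[m]
            evals, evecs = np.linalg.eigh(0.5 * (shifted + shifted.T))
            G_bands.append(_fix_signs(evecs[:, :cfg.p]))

        def fisher_objective(D: np.ndarray) -> float:
            N, B = fisher_energies(Z_bands, D, codes, delta_mask,
                                   xi_mask, G_bands)
            return N / B if B > 1e-12 else np.inf

        grads = [dictionary_gradient(dictionary, c, Z_bands, codes,
                                     delta_mask, xi_mask, G_bands)
                 for c in range(1, train.n_classes + 1)]
        dictionary, eta_used = dictionary_step(dictionary, grads, cfg.eta,
                                               fisher_objective)
        tw = sum(float(np.trace(G.T @ W @ G))
                 for G, W in zip(G_bands, scat.Ww))
        tb = sum(float(np.trace(G.T @ W @ G))
                 for G, W in zip(G_bands, scat.Wb))
        if tw <= 1e-12:
            tw = 1e-12
        lam = tb / (2.0 * tw)
        obj = fisher_objective(dictionary.D)
        history.append({"iteration": it, "objective": obj, "rho": lam,
                        "eta": eta_used,
                        "ortho_defect": max(
                            float(np.max(np.abs(G.T @ G - np.eye(cfg.p))))
                            for G in G_bands)})
        if np.isfinite(prev_obj) and \
                abs(prev_obj - obj) <= cfg.tol * (1.0 + abs(prev_obj)):
            break
        prev_obj = obj
    proj = ProjectionSet(G0=np.zeros((d, cfg.p)), Gtilde=G_bands,
                         sigma=1.0, stacked_orthonormal=False)
    return MBCCModel(config=cfg, projections=proj, dictionary=dictionary,
                     history=history, band_names=list(train.band_names),
                     kind="opfddl")
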