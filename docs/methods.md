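# Methods

## Model

Observed data are `M` feature matrices `Z^m ∈ R^{d×n}` (one per frequency
band; samples in columns, column `j` of every band is the same epoch) with
class labels `1..C`. The model couples three ingredients.

**Shared dictionary with class blocks.** A dictionary `D ∈ R^{d×K}` with
unit-norm atoms is partitioned into per-class sub-dictionaries `D_j`
(`K = C · atoms_per_class`). For a sample with code `a`, the δ-mask keeps
only coefficients on the atoms of the sample's own class and the ξ-mask
the complement, giving a within-class residual `z − D·δ(a)` and a
between-class residual `z − D·ξ(a)`. Per band these accumulate into the
scatters `W_w^m` and `W_b^m` (sums of residual outer products, symmetric
PSD).

**Shared + specific projections.** Band `m` projects with
`G^m = (1−σ)·G⁰ + σ·G̃^m`. Stacking `G = [G⁰; G̃¹; …; G̃^M]` and using
two-block selectors (`(1−σ)I` at the shared block, `σI` at band `m`), the
per-band Fisher criterion becomes a single trace ratio over the stacked
operators `Λ` (within), `H` (between) and `Θ` (the data Gram placed in the
shared block, a PCA-like term with weight `α` that rewards variance
retained by `G⁰`):

```
min_G  [Tr(GᵀΛG) − α·Tr(GᵀΘG)] / Tr(GᵀHG),   GᵀG = I.
```

The correctness of the block layout is enforced by a tested identity:
`Tr(GᵀΛG) = Σ_m Tr((G^m)ᵀ W_w^m G^m)` for arbitrary stacked `G` (and the
`H`/`W_b` analogue).

**Classification.** Per band, a test signal is projected
(`ẑ = (G^m)ᵀ z`), each class reconstructs it with its projected
sub-dictionary by ε-regularized least squares (ε = 1e-8, tolerating
rank-deficient projected blocks), and the class of smallest squared
residual wins the band. The final label is the modal band label; ties are
broken by the smallest sum of winning residuals among the tied labels'
voting bands, then by the smallest class index.

## Optimization

Training alternates three exact/monotone blocks until the relative change
of the objective falls below `tol` (default 1e-6) or `max_iter` is hit:

1. **Coding.** Per band, ridge codes
   `A^m = (DᵀD + λI)⁻¹ Dᵀ Z^m` (λ = `lambda_code`, default 0.01). The
   ℓ1 objective stated alongside the model is implemented by its ridge
   closed form, matching the update the derivation actually uses; an ISTA
   ℓ1 coder is available for fidelity experiments. Coding happens in the
   original d-space: the closed form's dictionary Gram is in d-space, and
   coding against the projected dictionary instead proved unstable — the
   per-band projections of the stacked solve are not isometries (see
   "Degeneracies" below), and projected codes feed that rank loss back
   into the scatters, measurably degrading accuracy over iterations.
2. **Projection.** Rebuild scatters and stacked operators, then solve the
   trace ratio through its scalar root: `F(ρ)` = sum of the `p` smallest
   eigenvalues of `Λ − αΘ − ρH`, which is non-increasing in ρ; a damped
   Newton iteration `ρ ← ρ + λ_ρ·F(ρ)/Tr(GᵀHG)` (λ_ρ = 0.5, `F′(ρ) =
   −Tr(GᵀHG)`) with a sign-change bracket and bisection fallback drives
   `|F(ρ)| ≤ 1e-8·(1 + |Tr(GᵀA G)|)`, capped at 100 inner iterations. The
   eigenvector block of the final solve is the new `G`; eigenvector signs
   are fixed (largest-magnitude entry positive, ties at the lowest row
   index) so the whole fit is deterministic. ρ is warm-started across
   outer iterations.
3. **Dictionary.** The gradient of the Fisher quotient
   `N(D)/B(D)` (projected within / between residual energies) w.r.t. each
   class block follows the quotient rule,
   `∂N/∂D_j = −2 Σ_m G^m(G^m)ᵀ R_w^m (A_w^m[block_j])ᵀ`, and is validated
   against central finite differences (relative error ≤ 1e-4). All blocks
   step simultaneously with step `η` (default 1e-2), atoms are
   re-normalized, and `η` is halved (≤ 10 times) until the objective does
   not increase; if no step qualifies the dictionary is left unchanged.
   Inside the joint fit the backtracking monitors the *full* objective
   (including the `−αΘ` term, constant in `D` at fixed `G` and codes), so
   the recorded objective is non-increasing across every dictionary
   update by construction.

**Initialization** is deterministic: per class, the `atoms_per_class`
largest-norm columns of the band-averaged data (ties by column index),
unit-normalized; `G` from the first eigen-solve at ρ = 0.

**Baseline.** The per-band variant learns an independent orthonormal
`G^m` per band from the `p` smallest eigenvectors of
`λ²W_w^m − λW_b^m`, with the adaptive weight
`λ = tr(G̃ᵀW̃_b G̃) / (2·tr(G̃ᵀW̃_w G̃))` recomputed each iteration, and
shares the coding/dictionary machinery. Its printed gradient suffers the
same shape inconsistencies as the joint model's, so the same
finite-difference-validated quotient-rule gradient is used.

## Degeneracies of the stacked relaxation, and how they are handled

The stacked orthonormality constraint (`GᵀG = I` on the stacked matrix,
the form the eigen-solver naturally provides) admits a structural null
space: directions with `(1−σ)g⁰ + σg̃^m = 0` for every band have exactly
zero per-band projection, hence zero response in both `Λ` and `H`, while
the variance term `−αΘ` still rewards them. Two consequences:

- *Unbounded ratio.* On such directions the ratio tends to −∞, so the raw
  ρ iteration diverges. The solver therefore restricts the eigen-solves to
  `range(H)` whenever a p-dimensional subspace could null the denominator
  — the standard treatment of a singular Fisher denominator. Full-rank
  inputs are untouched. An `eps_reg` ridge on `H` exists as an explicit
  alternative, but it legalizes the exact collapse directions and is not
  used by the fit.
- *Near-collapse columns.* Inside `range(H)`, directions dominated by the
  shared block still trade a large variance bonus against a small
  denominator; some learned columns act as low-information fillers, and
  the per-band `G^m` are not isometries. This is intrinsic to the stacked
  relaxation (the per-band orthonormality the model's constraint suggests
  would prevent it but has no closed-form solver). It is the reason coding
  stays in the original space, and the reason the learned shared block is
  *not* expected to coincide with the top-p PCA subspace of the data — at
  the trace-ratio root the `−ρH` term balances the variance preference by
  construction. Recovery of shared structure is therefore verified
  functionally (a σ = 0 model reaches ceiling accuracy on shared-truth
  data), not by subspace angles.

Related: `α` is scale-sensitive. If `α·Tr(GᵀΘG)` exceeds `Tr(GᵀΛG)` at
the optimum the numerator turns negative and minimizing the ratio then
*rewards small between-class energy* — anti-discriminative. `α` should be
small enough that ρ* ≥ 0; on the synthetic benchmark (where data variance
dwarfs coded residuals) this means `α ≈ 0.02`, whereas features with large
residual scatter tolerate the mid-range values that a grid search would
select on real recordings.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `alpha` | weight of the variance-retention term, in [0, 1]; 0 drops it | 0.5 (0.02 in the benchmark config) |
| `sigma` | shared/specific mixing of `G^m`, in [0, 1] | `1 − alpha` |
| `lambda_code` | ridge coding penalty | 0.01 |
| `atoms_per_class` | per-class dictionary size | 15 (8 in the benchmark config) |
| `p` | subspace dimension | `round(0.9·d)` (10 in the benchmark config) |
| `lambda_rho` | damping of the ρ Newton update | 0.5 |
| `eta` | initial dictionary step, backtracked | 1e-2 |
| `max_iter`, `tol` | outer loop control | 50, 1e-6 |

`σ = 1` with `α = 0` reduces the model to fully band-specific projections;
`σ = 0` forces one projection for all bands.

## Synthetic benchmark

The generator draws class-`c` samples as nonnegative block-sparse
combinations (`|N(0,1)| + 0.5`) of that class's `k_true` latent atoms,
observed per band through `B^m = (1−σ_true)·B⁰ + σ_true·B̃^m` (unit-norm
columns) plus `N(0, noise_sd²)` noise — exactly the structure the model
assumes. The canonical condition (`separable_preset`) uses 3 bands, 3
classes, 20 features, 4 atoms/class, mixing 0.5, noise sd 0.05, 40 train
and 40 test samples per class; the paired model config uses `p = 10`,
8 atoms/class, `α = 0.02`, `σ = 0.98`, 15 iterations. A nearest-subspace
oracle using the true mixings provides the performance ceiling (exact at
zero noise, degrading monotonically with noise).

What the generator does **not** emulate: realistic EEG spectra and their
1/f shape, channel covariance/topography, inter-subject and inter-session
variability, label noise, or any temporal structure. Passing tests
demonstrate the correctness of the optimization and decision machinery
under the model's own assumptions, not performance on real recordings.

## Band-power features

Raw epochs (channels × samples) become per-band feature vectors via an
order-4 zero-phase Butterworth band-pass (available separately) and Welch
PSD estimates (Hann window, default 1 s segments, 50% overlap) integrated
over each band with the trapezoidal rule — one nonnegative value per
channel. Band-power additivity and Parseval consistency hold to within the
usual ~10% windowing tolerance. Epoch slicing (window/step in seconds) and
an optional `log(1+x)` transform are provided; features are deterministic.
A band narrower than the frequency resolution falls back to the nearest
PSD bin scaled by the band width.

## Numerical choices

- Eigen-solves use symmetric `eigh`; operators are re-symmetrized before
  each solve to shed round-off.
- Classifier least squares are ε-regularized (1e-8); ridge coding is
  strictly PD for any λ > 0.
- Tie-breaks everywhere are deterministic (smallest index); eigenvector
  signs are canonicalized.
- `range(H)` rank cut: eigenvalues above `1e-10 × λ_max`.
- Delimited I/O parses floats in round-trip mode, so save → load is
  bit-exact.

## Known limitations

- The stacked-orthonormality relaxation leaves filler directions in `G`
  (see above); per-band projected dimensions below `p` are possible.
- At `σ = 1` the stacked solve distributes the `p` directions globally
  across bands while the baseline grants `p` per band, so the two agree
  only approximately.
- The Fisher quotient is optimized by alternating exact solves with a
  monotone dictionary step; no global convergence guarantee exists, and
  the objective is not a validated proxy for accuracy on real data.
- Raw-EEG ingest is limited to delimited text; EDF/BDF parsing is out of
  scope.
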