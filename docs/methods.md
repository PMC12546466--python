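# Methods

## Problem and observation model

EEG source imaging estimates the neural current field that generated a set
of scalp potentials.  The package works with the standard linear
observation model

    y = L x + n,        n ~ N(0, C),

where `y` (µV) collects the `m` referenced channel potentials, `x` (nAm)
stacks the three Cartesian moment components of `n` candidate dipole
locations, `L` (µV/nAm) is the lead field and `C` the noise covariance.
Units throughout: positions mm, moments nAm, potentials µV, conductivities
S/m.  The head frame is right/anterior/superior with the origin at the
sphere center; "anterior" is +y.

## Estimators

Six estimators are implemented behind one model/results interface.

**Unit-noise-gain (Borgiotti–Kaplan) beamformer.**  Per location the filter
minimizing the filtered covariance `wᵀΣw` subject to `wᵀL_kθ = τ` and
`wᵀw = 1` has the closed form `w = Σ⁻¹L_kθ / sqrt(θᵀL_kᵀΣ⁻²L_kθ)`; the
orientation is the top eigenvector of `(L_kᵀΣ⁻²L_k)⁻¹(L_kᵀΣ⁻¹L_k)`.  The
per-location score is the oriented filter's output power `wᵀΣw`.  Σ is
estimated either as the sample covariance of a time window plus Tikhonov
loading `0.05·trace(Σ)/m`, or — for single simulated vectors — as the
rank-one surrogate `yyᵀ + C`.  Both choices are recorded in the result's
provenance; the covariance estimator is not prescribed by the theory.

**Dipole scan.**  Per location the least-squares dipole fit is scored by
the residual-variance goodness `g_k = 1 − ‖y − L_kL_k⁺y‖² / ‖y‖² ∈ [0,1]`.
Pseudoinverses truncate singular values below `1e−10·s_max`.  The best
location is the argmax (lowest index on exact ties); locations within 1% of
the maximum are reported as near-ties.

**Hierarchical adaptive L1 regression (componentwise).**  A Laplace prior
with componentwise inverse scales `γ_i`, each gamma-distributed with shape
`β_i` and rate `θ_i`.  Expectation–maximization alternates

    γ_i = (β_i + 1) / (|x_i| + θ_i)
    x ← argmin ½(y−Lx)ᵀC⁻¹(y−Lx) + Σ γ_i |x_i| .

**Adaptive group lasso.**  The same hierarchy with the per-location
Euclidean norm replacing the componentwise magnitude:
`γ_k = (β_k + 3)/(‖x_k‖₂ + θ_k)` and the penalty `Σ γ_k ‖x_k‖₂`.  This
member is orientation invariant by construction.

**SVD-transformed hierarchy.**  Each sub-lead-field factorizes as
`L_k = U_k diag(s_k) V_kᵀ`; the right singular vectors order the moment
directions by output strength in the data space.  Stacking the `V_k` block
diagonally gives an orthogonal operator `V` with `x = V ξ`, and the
componentwise hierarchy is run on `ξ` with `A = L V`.  Sparsity is thereby
enforced in data-adapted axes rather than the arbitrary MRI/Cartesian ones,
which removes the axis alignment bias of the componentwise prior.

**Fitted two-step baseline.**  Group lasso picks the peak location; the
orientation is then re-fit among the three whitened singular directions of
that location (the candidate maximizing `|s_i·(u_iᵀỹ)|`), with scalar
least-squares amplitude.  Its role is demonstrative: splitting location and
orientation estimation loses accuracy relative to embedding the SVD bases
in the hierarchy.

### Interpretation of θ

The gamma density is written in shape–scale form in parts of the source
literature, but the expectation update `(β+1)/(|x|+θ)` and the
strength rule "θ/β equals the expected activity" are mutually consistent
only when θ acts as a rate.  The update formulas are implemented exactly as
printed above and θ is treated as a rate throughout.

### Hyperparameter selection

The subgradient conditions for the all-zero solution are

    componentwise:  |[LᵀC⁻¹y]_i| ≤ γ_i
    grouped:        ‖L_kᵀC⁻¹y‖₂ ≤ γ_k
    SVD basis:      |s_i (u_iᵀ ỹ)| ≤ γ_i   (whitened system)

Uniform `(β, θ)` are pinned by two requirements: `θ/β` equals the expected
dipole strength (10 nAm by default, the conventional magnitude of a
synchronized cortical patch), and the t = 0 update `(β+d)/θ` (`d` = 1
componentwise, 3 grouped) equals `margin · max_i(threshold)` with
`margin = 0.5`, so the iteration provably leaves the origin.  The margin
midpoint is a neutral choice; any value in (0, 1) satisfies the constraint.
All solvers whiten internally with a Cholesky factor of C, which is also
what reconciles the C-free form of the SVD-basis condition with the others.

## Numerical solution of the inner problems

The nonsmooth inner problems are solved by majorization–minimization with a
local quadratic approximation (MM-LQA): `|x| ≈ sqrt(x² + ε)` (groups:
`‖x_k‖ ≈ sqrt(‖x_k‖² + ε)`), majorized at the current iterate, giving a
weighted ridge system per iteration.  Implementation choices:

* The ridge system is solved in the dual m×m form when `3n > m` (the usual
  EEG regime), otherwise in the primal form.
* ε follows a geometric continuation from `1e8·ε₀` down through `1e−8·ε₀`
  with ε₀ = 1e−8 nAm²; the deep tail separates active from inactive
  components by many orders of magnitude.  The recorded objective trace is
  the smoothed objective at the active ε and is non-increasing.
* After MM, components below `1e−6` of the peak are zeroed and an exact
  active-set polish runs: sign-constrained reduced solves (componentwise)
  or smooth quasi-Newton solves on the support (grouped) with
  KKT-violation additions and sign-flip drops.  The polished point is kept
  only if the true nonsmooth objective does not increase.  This lands on
  the exact optimizer (verified against an independent proximal-gradient
  solver to 1e−6 in objective) while keeping MM-LQA as the main engine.
* If the zero-solution condition already holds at entry, the exact zero
  vector is returned without iterating.
* Stopping: outer EM cap 25, inner cap 100 per ε level, relative change
  tolerance 1e−5.  Estimates below `sqrt(ε)` are reported as exactly zero.

## Forward model

The lead field comes from the classical concentric-shell spherical
conductor.  For each Legendre degree up to `series_order` (default 60) the
shell-to-shell transfer follows from continuity of potential and of radial
current plus a no-flux scalp condition, solved as a small linear system per
degree in scalp-normalized radii (which also avoids overflow at high
degree).  The implementation was verified against an independently coded
textbook homogeneous-sphere series and, externally, against MNE-Python's
spherical model (0.4% agreement, MNE using the Berg multipole
approximation).  Degree-60 truncation is accurate to ~1e−10 relative for
sources within 80% of the brain shell and ~5e−6 at 95%.

**Simulated noise.**  "p% noise" is defined as i.i.d. channel noise with
standard deviation `p/100` times the maximum absolute clean-signal channel
amplitude, `C = σ²I`.  This makes the percentage scale free, and the choice
is recorded on every `Measurement`.  With `p = 0` the covariance floor
`(1e−6·max|Lx|)²·I` keeps whitened solvers defined.

## The synthetic study fixture and what it does (not) emulate

The deterministic fixture is a 64-channel quasi-uniform cap (Fibonacci
spiral down to z/R = −0.25 on a 92 mm scalp sphere, common-average
referenced) and 200 source nodes with directions uniform in a 30° cone
under the cap axis and radii 50–72 mm, plus one designated superficial
right-anterior test location for the rotation experiments.

Two geometry choices place this desk-scale substitute in the regime the
SVD orientation bases assume, namely that the radial direction is the
*weakest* output direction of every sub-lead-field:

* skull conductivity 0.002 S/m (brain:skull ≈ 165:1, the resistive end of
  the published range; shells 80/85/92 mm at 0.33/0.002/0.33 S/m), and
* sources confined to the cortical patch directly beneath the montage.

In concentric-sphere conductors with realistic cap coverage the
radial-weakest ordering is otherwise marginal or reversed — superficial
radial dipoles produce scalp signals comparable to tangential ones — while
realistic FEM head models exhibit it robustly.  With the choices above the
ordering holds over the entire fixture patch (worst tangential/radial norm
ratio 1.02).  Consequences for interpreting results: passing tests show the
algorithmic claims (equivariance, bias removal, error orderings) under a
forward model that reproduces the physiological direction ordering; they do
not quantify performance on realistic anatomy, where source spaces are
larger, lead fields are FEM-based, and the radial-weakest effect is
stronger.  Mean errors from the bundled studies are therefore not
comparable in magnitude to values obtained with subject-specific FEM
models at 74 channels and 80,000 sources.

**Experiment designs.**  Rotation case A sweeps the test dipole inside the
tangent plane from the anterior reference toward the medial in-plane
direction; case B sweeps from anterior through the radial axis (fully
radial at 90°/270°).  Statistical studies draw locations uniformly from
nodes at ≥60% of the brain-shell radius, orientations uniform in the
tangent plane (tangential study) or ±radial (radial study), with 10 nAm
strength, and run at the stated noise percentage (desk default 100 cases;
seeds derive from the study seed and the case counter, so reruns are
bitwise identical).

## Error metrics

Localization error is the Euclidean distance between true and estimated
node positions (mm).  Orientation errors live in the local frame (a1, a2,
r): a1 is the normalized tangent-plane projection of the anterior axis, a2
= r × a1.  The estimated moment's sign is first flipped if it opposes the
true moment (eigenvector estimators are sign-ambiguous).  The azimuthal
error Δφ ∈ [0, 180]° is the angle between the tangent-plane projections —
deliberately *not* folded to [0, 90], so the characteristic indefiniteness
spikes of near-radial estimates remain visible.  The polar error
Δθ ∈ [0, 90]° is the absolute elevation difference after azimuthal
alignment, folded at 90°.  A moment projecting to numerical zero in the
tangent plane has no azimuth; 90° is reported with an explicit flag.  In
the spherical fixture the radial statistical study hits this degeneracy by
construction (the true moment is exactly radial, so the scalp normal and
the moment coincide), and its azimuthal summaries are therefore the flagged
90° constant; in realistic head models cortical normals deviate from the
scalp normal and the radial-case azimuth stays informative.
Sources whose radial axis is parallel to the anterior axis get a substitute
in-plane reference, are flagged, and are excluded from angular summaries
(counted separately).

## Degenerate inputs and tie handling

* Near-equal singular values `(s_i − s_{i+1})/s₁ < 1e−6` set a per-location
  degeneracy flag; the decomposition itself is used as computed, with signs
  fixed so the largest-magnitude entry of each `u_i` is positive (ties by
  lowest channel index).  SVD signs are otherwise arbitrary and the
  convention makes estimates reproducible across LAPACK builds.
* The UNG orientation eigenproblem with (near-)isotropic spectrum returns
  the strongest output direction `v₁` as a deterministic fallback, flagged.
* Scan argmaxes break ties toward the lowest index and report all tied
  indices.

## Known limitations

* The spherical conductor is a stand-in: no CSF, no skull inhomogeneity,
  no realistic cortical geometry or orientation constraints.
* Single-time-sample estimation only; no spatiotemporal priors, no MCMC
  over the hierarchy.
* The fixture's source patch is small by design (see above), which bounds
  attainable localization errors from above and keeps the radial-weakest
  regime valid; conclusions about absolute error magnitudes do not
  transfer to whole-head source spaces.
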