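# Methods

`tlsvalid` validates the results of TLS (Translation–Libration–Screw)
refinement by *explicit interpretation*: it extracts the elemental rigid-body
motions a set of TLS matrices encodes, samples those motions into an explicit
atomic ensemble, converts both descriptions to per-atom anisotropic
displacement parameters (ADPs), and measures their agreement.  TLS matrices
refined without constraints frequently encode motion parameters that violate
the harmonic rigid-body assumptions behind the model; this package makes such
violations measurable.

## The motion model

A rigid group's harmonic motion is carried by three matrices about a group
origin: `T` (Å², net vibration), `L` (rad², libration) and `S` (Å·rad,
rotation–translation correlation).  The analytic per-atom ADP is

    U_n = T + A_n L A_nᵗ + A_n S + Sᵗ A_nᵗ

where `A_n` is the antisymmetric matrix built from the atom position
`p = r_n − origin` with the convention `A q = q × p` (equivalently
`A = [[0, p_z, −p_y], [−p_z, 0, p_x], [p_y, −p_x, 0]]`).  The sign of this
convention is not observable in `T` or `L` terms; it is pinned by requiring
that the analytic ADPs of a screw libration agree with an ensemble sampled
with the exact coupled screw transform (see below) — a flipped sign inverts
the S cross terms and fails that check.

Equivalently, the motion is parameterized *directly* by elemental motions:
three independent screw librations (RMS amplitude `d_k` in rad about unit
axis `l_k` through the lab point `w_k`, with pitch `s_k` in Å/rad) and three
independent vibrations (`t_j` in Å along orthonormal `v_j`).  Composition
uses the per-axis unit-rotation translation vector
`a_k = s_k l_k + (w_k − origin) × l_k`:

    L = Σ_k d_k² l_k l_kᵗ
    S = Σ_k d_k² l_k a_kᵗ
    T = Σ_k d_k² a_k a_kᵗ + Σ_j t_j² v_j v_jᵗ

and the direct per-atom ADP is `U_n = Σ_k d_k² b_k b_kᵗ + Σ_j t_j² v_j v_jᵗ`
with `b_k(r) = l_k × (r − w_k) + s_k l_k`.  The two routes are algebraically
identical; tests hold them together to 1e-10.  Cross-libration correlations
are zero by construction: the librations are independent oscillators about
the eigenaxes of `L`.

## Decomposition and the sigma gauge

Libration amplitudes and axes come from the eigendecomposition of `L`
(eigenvalues below 1e-9 rad² count as zero — the rounding level of deposited
matrices printed to 4–5 decimals).  Axes are ordered by **ascending**
amplitude, matching the convention of the published parameter tables this
package ships (`d_x ≤ d_y ≤ d_z`; the famous 303.63 Å/rad pitch belongs to
the *smallest* libration of its group).  Eigenvector signs are fixed by
making each axis's largest-magnitude component positive, restoring
right-handedness by flipping the last axis if needed; this makes
decomposition deterministic.

A scalar σ added to the diagonal of `S` changes no ADP but changes the
extracted pitches `s_k = (S′_kk − σ)/d_k²` (primes denote the `[L]` basis)
and, through them, the residual vibration matrix
`C(σ) = T′ − Σ_k d_k² a_k(σ) a_k(σ)ᵗ`, whose eigen-split yields `t_j, v_j`.
`C(σ)` is a quadratic matrix polynomial in σ; the set of σ keeping it
positive semi-definite (tolerance 1e-8 Å²) is located by a 513-point scan of
its smallest eigenvalue over an analytic outer bracket, with endpoints
refined by Brent root-finding.  If the scan sees a disconnected feasible
region — not observed in practice for this one-parameter family — the
component containing the unconstrained optimum is returned with a warning.

Three strategies pick σ, each projected onto the feasible interval:

* **trace** — σ = tr(S′)/3, the traditional trace-free choice;
* **t_min** — implemented as the trace σ projected onto the feasible
  interval.  The published vibration-minimizing criterion involves
  constraint algebra not reproduced here; because every strategy is
  projected, `t_min` and `trace` coincide in this implementation.  This
  stand-in is deliberate and flagged here rather than hidden.
* **s_min** — σ minimizing `|s|²`, in closed form the `1/d_k⁴`-weighted mean
  of the S′ diagonal.  The weights favour the weakest libration, so the
  minimizer essentially annihilates the pitch on the axis least able to
  support one — exactly the pathological case.  Projection onto the feasible
  interval preserves optimality by convexity.

A fixed σ can also be supplied (`sigma_override`) for gauge scans and for
re-decomposing at a known composing gauge.  Gauge consistency holds exactly:
decomposing `(T, L, S + cI)` shifts σ by `c` and changes nothing else.
Only `d`, axes, axis points and the per-atom ADPs are gauge invariants;
`s` and `t` are gauge-dependent, which is the method's leverage.

Failure classification is total: non-finite input → `wrong_content`;
all-zero matrices → `matrices_all_zero`; an `L` eigenvalue below −1e-9 rad²
→ `L_not_psd`; empty feasible interval or non-PSD residual →
`T_residual_not_psd`; all-zero `L` with usable `T` → `libration_undefined`
(pure-vibration motions are still returned).  Libration amplitudes above
0.15 rad and pitches above a configurable cap (default 100 Å/rad) warn but
never fail — the survey still measures such groups.

## Ensemble sampling — the validation convention

Each ensemble model draws Gaussian amplitudes and applies the three finite
screw rotations (exact Rodrigues rotations about the axis points, in fixed
axis order x→y→z; non-commutativity is second-order in the amplitudes) and
then the vibrations.  Per-model draws occupy a fixed slice of a
counter-based (Philox) stream, so enlarging an ensemble extends it without
reshuffling, and every subset comparison uses an independent substream of
one root seed.

The load-bearing choice is what the screw shift is coupled to.  Two
conventions are implemented:

* `couple_screw=True`: the exact rigid screw — the axial advance is
  `θ_k s_k l_k` with the *same* angle that drives the rotation.  This
  reproduces the analytic ADPs for **any** pitch at harmonic amplitudes
  (the advance is linear in θ), so it can verify sign conventions and the
  harmonic limit but is blind to pathological pitches.
* `couple_screw=False` (default): every elemental component draws its own
  independent amplitude — rotation angles `θ_k ~ N(0, d_k²)`, axial shifts
  `η_k s_k l_k` with independent `η_k ~ N(0, d_k²)`, vibrations
  `ξ_j ~ N(0, t_j²)`.  The ensemble covariance then reproduces every term
  of the analytic ADP *except* the rotation–shift cross terms
  `d_k² s_k (l_k ⊗ (l_k × (r − w_k)) + sym)` carried by the off-gauge part
  of the S diagonal.

The default is the validation convention because the diagnostic lives in
exactly those cross terms: a group whose pitches are large relative to its
libration arms shows a large, ensemble-size-independent R_U, and the
`s_min` gauge minimizes precisely the unreproduced content — which is why
minimizing |s| minimizes R_U.  On the shipped reconstruction of the 4muy
group-6 motion set, the screw-x subset gives R_U ≈ 0.96 at the deposited
gauge and ≈ 0.02 after `s_min`, with the pure rotations at 0.01–0.02
throughout; these are the magnitudes the published analysis reports for
this group.  Under the coupled convention the same group would score ≈ 0.02
everywhere and the pathology would be invisible.

ADPs are recovered from an ensemble as second moments about the per-atom
ensemble mean (proper covariance).  Measuring about the template position
instead is supported (`about="template"`); for anharmonic librations the
finite rotation pulls the mean off the template and the two differ, but
within the harmonic regime the difference is below the sampling floor.

## Agreement metrics

The primary metric is an R-factor-style discrepancy over all nine matrix
elements of every atom pair:

    R_U = Σ |a_ij − b_ij| / [ ½ Σ (|a_ij| + |b_ij|) ]

symmetric, scale-invariant, zero iff identical.  The symmetrized ½(|a|+|b|)
denominator is fixed by the calibration levels it must reproduce: pure
sampling noise gives mean R_U ≈ 0.8·√(2/M) with this form, i.e. ≈ 0.011 at
M = 10⁴ (single-atom vibration) and a ≈ 0.02 libration plateau at M = 5000,
the published anchor values.  The compliance threshold **R_U ≤ 0.05** was
calibrated against those levels and is the package default, with secondary
reporting bands at 0.10 and 0.20.

Two regularized cross-checks require inverting U (impossible for the
rank-deficient ADP of a single motion), hence the isotropic inflation
`U_ε = U + εI` with ε defaulting to 1e-6 Å² (results are stable over
1e-8–1e-6):

* `KL_ε = ε · tr(U_ε V_ε⁻¹ + V_ε U_ε⁻¹ − 2I)` per atom, summed over atoms
  (a per-atom mean is available); the ε prefactor keeps the scale
  comparable to R_U.
* `CC_ε = 2^{3/2} [det U_ε⁻¹ det V_ε⁻¹]^{1/4} / det(U_ε⁻¹ + V_ε⁻¹)^{1/2}`
  per atom, averaged — the real-space overlap of the two Gaussian clouds,
  in (0, 1], markedly ε-sensitive.

On the libration amplitude scan all three metrics flag the same anharmonic
regime (discrepancy metrics rise, correlation falls, beyond ~0.15 rad).

## Calibration experiments and study sizes

Two single-atom experiments fix the operating point.  A vibration along one
axis isolates pure sampling noise: mean R_U over 100 seeded trials falls as
M^(−1/2), reaching ≈ 0.011 at M = 10⁴.  A pure libration of an atom on a
1 Å arm (the arm length is irrelevant: both ADP sets scale with it) at
M = 5000 sits on a plateau whose mean over the amplitude grid
{0.02, 0.05, 0.10, 0.15} rad is ≈ 0.02–0.026; at 0.15 rad — the harmonic
limit itself — the anharmonic bias (E[sin²θ] < d², variance of cos θ > 0)
already contributes ≈ 2% and the curve begins to rise, climbing steeply
beyond (≈ 0.34 at 0.5 rad).  Ensembles of 5000 models are the package
default; compliance-sensitive tests use 10 000, the upper end of the range
within which second moments are stable.

## The validation battery and survey

`validate_group` decomposes, then for each of eight diagnostic subsets —
full motion, librations-without-vibrations, each screw libration alone,
each pure libration alone — recomposes the *subset's own* motions, computes
analytic and ensemble ADPs and R_U.  A group is `compliant` iff
decomposition succeeded and every computed subset passes the threshold;
other verdicts mirror the decomposition taxonomy.  `survey` batch-runs
groups without ever aborting (per-group failures are recorded), tallying a
partition — wrong content / all-zero / other non-decomposable / libration
undefined / decomposed — plus pass counts for overall motion, overall
libration, individual screws and individual librations.

## Synthetic data

The generators produce everything the tests need at run time.
`random_valid_motions` draws amplitudes uniformly below caps chosen to span
realistic refined groups while staying decomposable by construction
(librations 0.02–0.1 rad, within the harmonic regime; vibrations up to
0.5 Å; pitches up to 5 Å/rad; axis offsets up to 10 Å perpendicular to each
axis): composing and re-decomposing such a set must succeed, because the
residual vibration at the composing gauge is the PSD vibration term itself.
`toy_chain` emits a helical pseudo-backbone (1.5 Å rise, ~100° turn, 2.3 Å
radius, small seeded jitter; 56 points matches a single-domain C-alpha
trace) whose geometry keeps all libration axes well conditioned — a
collinear group would make rotation about its own axis unobservable.

What the synthetic fixtures do *not* emulate: real covalent geometry,
multi-group partitioning, experimental noise in observed ADPs, and the
compactness of real domains (the helical stand-in is more extended than a
globular group of equal atom count, which inflates libration arms — visible
when published motion sets are replayed on it).  Passing tests therefore
demonstrate the correctness of the machinery and the reproduction of the
single-group mechanisms, not archive-scale statistics.

## Reference parameter sets

The package ships the published elemental-motion tables for the 2igd
C-alpha and main-chain groups and 4muy group 6, each under the `t_min` and
`s_min` gauges.  Printed to three decimals, their axis triplets are
re-orthonormalized to the nearest rotation (SVD Procrustes) and axis points
are converted from the printed `[L]`-basis pairs; the group centre of mass
(unknown without the deposited structures) is taken as the coordinate
origin, which only fixes the frame.  Printed rounding bounds what replay
can achieve: the 4muy `d_x` has one significant digit, so the `s_min` pitch
lands at ≈ 0.05 Å/rad where the published table prints 0.11.

## TLS fitting

`fit_tls` solves the linear least-squares problem for the 20 free TLS
elements (S gauge fixed by trace(S) = 0; any gauge fits identically well)
against observed per-atom U matrices, unweighted by default with a weights
hook, origin defaulting to the group centroid.  The fit is unconstrained:
non-PSD results are findings for the downstream decomposition, not errors.
Rank below 20 (collinear geometry) raises a dedicated error.  Exactly
TLS-generated observations are recovered with zero residual, T and L
exactly and S up to the diagonal gauge; adding `cI` to every observation
moves only `T`.

## Numerical choices

* Tolerances: L eigenvalues 1e-9 rad², residual vibration 1e-8 Å² (both at
  the rounding level of deposited matrices); route-equivalence 1e-10;
  ANISOU quantization 1e-4 Å² (integers are U×10⁴).
* The final PSD check of C(σ) is padded to 2×1e-8 because a projected σ can
  sit exactly on the bisected boundary, where the smallest eigenvalue
  equals −1e-8 up to root-finding error.
* Deposition units (T in Å², L in deg², S in Å·deg) are converted at the
  I/O boundary only; internally everything is Å and rad.
* Zero-amplitude axes carry undefined pitches, stored as 0 and flagged;
  single-motion subsets with zero amplitude are skipped rather than
  sampled.

## Known limitations

* The `t_min` gauge is a stand-in (projected trace), not the published
  vibration-minimizing criterion.
* Published composite R_U values (full-motion rows of the case-study
  tables) are not reproducible from printed motion parameters alone: they
  depend on the deposited matrices and the real structures, and the giant
  libration arms both ADP sets share dilute the relative discrepancy on
  stand-in geometry.  The per-screw mechanism and its repair are
  reproduced quantitatively.
* mmCIF TLS records and selection grammar beyond
  `chain X and resseq i:j` (clauses joined by `or`) are not parsed.
* No local search beyond the closed-form σ; no refinement against
  diffraction data; no TLS-group boundary optimization.
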