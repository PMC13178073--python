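# Methods

This note documents the models implemented in `posedelta`, the defaults
they ship with, and the reasoning behind the genuinely open design
choices. Units throughout: Å, kcal/mol, elementary charges, Kelvin, molar;
Coulomb constant 332.0637 kcal·Å/(mol·e²), k_B = 0.0019872 kcal/(mol·K).

## Single-trajectory MM-GBSA

The binding free energy is estimated end-point style,

ΔG_bind = G_complex − (G_receptor + G_ligand) = ΔH − TΔS,
ΔH = ΔE_MM + ΔG_solv,

with all three species evaluated at the *complex* frame geometry (the
single-trajectory protocol). Under that convention every bonded and
intramolecular nonbonded term cancels between complex and separated
species, so ΔE_MM reduces to the receptor–ligand intermolecular Coulomb
and Lennard-Jones sums. This matches the reporting convention in which the
gas-phase enthalpy is tabulated as E_int split into (E^ELE, E^vdW) with no
bonded contribution. No distance cutoff is applied — the rescored systems
are finite, and a cutoff is an engine-level device for periodic dynamics,
not for rescoring.

The interior dielectric defaults to ε_in = 2 and is shared between the
gas-phase Coulomb term and the GB contrast. Whether an MM-GBSA package
applies the solute dielectric to the gas-phase term as well is
convention-dependent; here both are governed by the single `eps_in` key so
the choice is explicit and logged.

Lennard-Jones uses the 12-6 form ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶]
with Lorentz–Berthelot combining (r_min halves additive, ε geometric).
Parameters travel in a JSON sidecar keyed by atom serial, because PQR has
no LJ columns; the schema is frozen in `posedelta/io.py`.

## Generalized-Born solvation (OBC-II / igb=2)

Effective Born radii come from Hawkins–Cramer–Truhlar pairwise
descreening with Onufriev–Bashford–Case tanh rescaling:

ψ = Ĩ·ρ̃_i, 1/R_i = 1/ρ̃_i − tanh(αψ − βψ² + γψ³)/ρ_i,

with α = 0.8, β = 0, γ = 2.909125 (the OBC-II parameter set) and
ρ̃_i = ρ_i − 0.09 Å (the conventional intrinsic-radius offset; an isolated
atom's effective radius is therefore its intrinsic radius minus 0.09 Å).
The HCT integral is implemented in its closed form, including the
buried-atom correction, and was verified against direct numerical
quadrature of the 1/r⁴ descreening integral during development. HCT
screening factors are per-atom (`gb_screen`, default 0.8, a mid-range
element-typical value) and can be overridden through the sidecar; the
closed-form limits used by the test oracles (isolated ion, far-separated
atoms) are independent of the screen.

Polar energies use the Still pairwise form with
f_GB = √(r² + R_iR_j·e^{−r²/(4R_iR_j)}) and self terms included. Salt
screening (Debye κ) is available but off by default: the 0.15 M KCl of a
solvated MD box is an engine setting, not necessarily an MM-GBSA one.

The nonpolar term is γ·SASA + b with γ = 0.0072 kcal/mol/Å², b = 0,
probe 1.4 Å — the widespread MM-GBSA convention. SASA uses a deterministic
golden-spiral Shrake–Rupley scheme with 960 points by default (point-count
stability ≤0.5% against 5000 points is asserted in tests). The reported
ΔG_solv column includes the nonpolar term, mirroring the usual summary
output of MM-GBSA tools.

## Interaction entropy

−TΔS = k_B·T·ln⟨e^{βΔE_int}⟩ with ΔE_int = E_int − ⟨E_int⟩, evaluated in
log space (logsumexp with max-shift) because β|ΔE| can exceed the
double-precision exponent range. By Jensen's inequality the estimator is
nonnegative on any input; for Gaussian fluctuations it converges to
σ²/(2k_B·T), which the tests use as a closed-form oracle. The estimator is
famously sampling-fragile once σ exceeds a few k_B·T: a single frame can
dominate the exponential average. Two diagnostics address this — a sigma
heuristic (converged only if σ ≤ 2k_B·T) and contiguous-block agreement
(blocks must agree within 2k_B·T). Default temperature 298 K. Entropy is
computed from the same snapshot window as the enthalpy; replicas are
estimated separately and averaged with reported spread, rather than
pooled, so replica-to-replica variability stays visible.

## Pose inference

Per replica: per-frame ΔH averaged, −TΔS from that replica's E_int
samples, ΔG = ΔH − TΔS. Replicas aggregate as mean ± population SD for
every column (conventionally only ΔG carries the ± in summary tables; we
keep the SD for all columns). Poses of one ligand are ranked by mean ΔG;
the margin is second-best minus best; exact ties break toward the lower
replica SD, then lexicographic pose label, and are flagged. No
significance test is attached to the margin — with n = 3 replicas typical
of such studies any test would be decorative.

## Trajectory metrics

Kabsch superposition (SVD with determinant correction, proper rotations
only; ≥3 non-collinear fit atoms required). RMSD series superpose each
frame on a fit selection and measure over a possibly different selection —
fitting on the backbone while measuring the ligand reproduces the usual
ligand-RMSD convention. Backbone = atoms named N/CA/C/O (the term
"protein backbone" rarely comes with an atom list). Binding site =
residues with any atom within 5 Å of the ligand in the reference frame
(the radius is a config key; published pocket definitions seldom state
one). RMSF is computed about the mean structure after superposition and
averaged per residue; region summaries (e.g. helices H11/H12, default
residue windows 225–275 and 350–370 plus a configurable C-terminal tail)
are labelled approximate because exact helix boundaries are a matter of
annotation. Reference defaults to the first frame; an external (X-ray)
reference can be supplied.

## Circular fingerprints

Native ECFP-style generation: initial invariants (atomic number, heavy
degree, attached H, formal charge, ring flag), iterative neighbourhood
hashing over sorted (bond order, neighbour id) tuples, CRC32 mixing (so
fingerprints are bit-identical across platforms), deduplication of
environments that cover an already-seen bond set, folding modulo 2048
bits. Chirality is ignored (default ECFP behaviour); aromaticity comes
from the SDF perception step.

Similarity is Tanimoto, in two variants. On folded bitsets the dense,
highly repetitive environments of fused polycyclic scaffolds collide and
truncate, which systematically deflates similarity between large
triterpenoids — e.g. hederagenin vs betulinic acid drops to ≈0.35 folded
but reads ≈0.47 on unfolded environment counts, and only the count
variant reproduces the expected 0.4–0.8 band for triterpenoid pairs
alongside <0.1 against rosiglitazone. The count multiset (Σmin/Σmax) is
therefore the default for reports; the folded variant remains available.
The native implementation is cross-checked in the test suite against an
independent cheminformatics library on the packaged fixtures (agreement
within 0.05 on all pairs).

## Dose–response pharmacology

Responses are 520/495 TR-FRET ratios (the kit-standard readout; fitting a
single channel would conflate signal with dispensing volume). The 4PL
model y = bottom + (top−bottom)/(1 + 10^{hill·(log_mid − log₁₀x)}) is fit
by least squares with multi-start initialisation (6 Hill slopes × 3
midpoint quantiles) to avoid the local minima that plague sigmoid fits;
the 95% CI on log_mid comes from the covariance at the optimum. Flat or
degenerate data raise a fit error carrying the best residual; a midpoint
outside the tested dose range only sets a warning flag.

Cheng–Prusoff: K_i = IC50/(1 + [tracer]/K_d). Defaults [tracer] = 5 nM,
K_d = 2.8 nM — the published constants of the competitive-binding kit,
validated in-suite against two printed (IC50, K_i) pairs, both of which
imply the same tracer factor 2.786. A third printed pair (the reference
full agonist) is excluded from exact checks because its IC50 is printed to
two significant figures, making back-calculation inconsistent at the
third digit.

Efficacy is 100·span/span_ref against a reference agonist (coactivator
assays) or inverse agonist (corepressor assays). Classification uses an
explicit threshold table (defaults: partial ≥10%, full ≥80%), since the
underlying reasoning in the literature is qualitative; thresholds are
config and always logged. A binder below the partial threshold on both
coregulators is a neutral (silent) antagonist.

## Synthetic generators

The host–guest system stands in for microsecond MD trajectories, which
are deliberately out of scope: it is a ~15-residue (60-atom) ring
receptor with three pocket residues carrying excess negative charge, plus
a 10-atom +1e guest. Pose A sits inside the ring with near-optimal LJ
contacts and electrostatic complementarity; pose B docks at the uncharged
outer rim. The planted ordering ΔH(A) < ΔH(B) follows from construction,
not tuning. Frames are the rigid pose plus isotropic Gaussian jitter
(default σ = 0.1 Å, a small-amplitude thermal wobble that leaves contacts
intact); default 50 frames per ensemble. Parameters are physically sane
(charges ≤ 1e, radii 1.2–2.2 Å) but make no claim of chemical realism.

What passing the recovery tests shows: the full pipeline (energies →
solvation → entropy → ranking) correctly orders pose hypotheses whose
energetic separation (~1.5–2 kcal/mol here) exceeds the sampling noise.
What it does not show: behaviour under conformational drift, pose
interconversion, force-field error, or entropy estimates in the
large-fluctuation regime where the exponential average is known to
diverge — real trajectories have all of these and the synthetic frames
have none.

Gaussian energy streams exercise the entropy estimator against its
lognormal closed form; 4PL plates span 1 pM–100 μM (the experimentally
tested range) with Gaussian response noise. All generators are pure
functions of (spec, seed); byte-identical reruns are asserted in tests.

## Problem sizes and numerical choices

Default test-suite problem sizes — 40 recovery seeds × 50 frames,
20 entropy seeds × 10⁵ samples, 100 dose–response seeds — were chosen so
the statistical assertions (≥95% recovery, 3% closed-form agreement,
≥90% CI coverage) are well-resolved while the whole suite runs in a
couple of minutes on one CPU.

Degenerate inputs are hard errors with named culprits: coincident atoms
(r < 10⁻⁶ Å), nonpositive radii, empty masks, collinear fit selections,
mismatched model atom counts, missing sidecar serials. Energies are
evaluated in double precision with no cutoffs or neighbour lists (systems
are small); the entropy estimator clamps −0.0 roundoff to exactly 0.

## Known limitations

* Single-trajectory only: no separate receptor/ligand trajectories, so
  strain energy is invisible by construction.
* GB is OBC-II only (igb=2); PB, igb=5/7/8 and explicit solvent are not
  implemented (a config hook names the model for forward compatibility).
* The interaction-entropy estimator is biased low at small n and unstable
  for σ ≫ k_BT; the convergence flags report, but cannot repair, this.
* Fingerprints ignore stereochemistry; molecules differing only at
  stereocentres are identical to the similarity module.
* The 4PL CI is a local (covariance) interval, not profile likelihood;
  coverage is verified by simulation at 2% noise, not guaranteed at
  arbitrary noise levels.
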