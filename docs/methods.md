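# Methods

This note documents the models implemented in `idpfrag`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Scientific setting

The package analyses NMR fragment screens against intrinsically disordered
protein (IDP) targets, using the kinase-inhibitory domain of the cell-cycle
regulator p27 (p27-KID, residues 22–105; Cdk2-binding sub-domain D2,
residues 58–105) as the reference system. Fragments bind weakly (mM) but
specifically to transient clusters of aromatic residues: a localised site at
the F87–Y88–Y89 motif (sub-region D2.3) and a distributed site additionally
involving W60/N61 (D2.1) and E75–W76–Q77 (D2.2). The analysis stages are:
library curation, chemical-shift-perturbation (CSP) mapping, global K_d
fitting, displacement/functional assays, and MD distance-state analysis.

## Fragment-library curation (`idpfrag.curation`)

Molecules are sanitised (valid structure; organic elements only — H, B, C,
N, O, F, P, S, Cl, Br, I; no isotope labels), abstracted to Murcko
scaffolds, filtered at the scaffold level, and ranked by complexity.

*Murcko scaffolds with alpha atoms.* The scaffold is computed by iterative
pruning of terminal non-ring heavy atoms, leaving ring systems plus linkers;
with `keep_alpha` (default on) the heavy atoms directly bonded to that
framework are retained. Alpha preservation keeps substitution-pattern
information when counting how often a scaffold occurs in a reference HTS
collection. Acyclic molecules yield an empty scaffold and fail the ring
filter. The pruning is implemented directly on the molecular graph because
stock Murcko decompositions discard the alpha atoms.

*Filter cascade.* A scaffold passes iff: zero reactive-substructure (REOS)
matches; rotatable bonds ≤ 3; heavy atoms ≥ 10; rings ≥ 1; more than one
ring substitution for single-ring systems; HTS frequency ≥ 8. Boundary
semantics are exactly as stated (`<`, `≤`, `≥` as written; Rule of Three is
MW < 300 strictly, HBD ≤ 3, HBA ≤ 3, clogP ≤ 3). "Ring substitution" is
counted as a bond from a ring atom to a non-ring heavy atom of the
scaffold — the most literal reading. The published REOS filter sets are
cited in the literature but not enumerated; the shipped default SMARTS list
covers the classic electrophile/unstable classes (acyl halides, aldehydes,
Michael acceptors, alkyl halides, peroxides, epoxides, anhydrides,
isocyanates, azides, diazonium, thiols, nitroso, hydrazines, sulfonyl
halides) and is user-overridable, since any fixed list is a proxy for the
original. Whether the rotatable-bond/heavy-atom thresholds apply to the
scaffold or the parent molecule is ambiguous in the source protocol;
scaffold-level is the default, with `FilterConfig.filter_level="molecule"`
as the alternative.

*Complexity ranking.* The original complexity metric is cited, not defined.
The implemented scorer is a documented additive score
(2·rings + 1.5·ring-fusion bonds + 1·heteroatoms + 2·stereocentres +
0.5·branch atoms, weights configurable) and the ranking function accepts
any scorer with the same signature. Only the ordering matters to the
pipeline; ties break lexicographically by id for determinism.

*Profiling.* Library summaries report mean ± sample SD (n−1 denominator)
of MW, heavy atoms ("number of atoms" is interpreted as heavy atoms, the
fragment-community convention), clogP, TPSA, HBA, HBD. A singleton library
reports SD 0 with a warning.

## CSP significance and binding-pattern classification (`idpfrag.csp`)

CSPs are evaluated **per dimension** (¹H and ¹⁵N separately), not as a
combined shift: for these weak binders the ¹H perturbations dominate and a
combined value would dilute them. A `combined_csp` helper (weight 0.14 on
¹⁵N) exists for cross-comparison but is off the main path.

A residue is significant in a dimension iff its |Δδ| (in Hz) strictly
exceeds both (i) the digital spectral resolution of that dimension and
(ii) Δδ_ave + 2σ, with mean and σ computed over all observed residues of
the spectrum pair. Working in Hz lets printed resolution floors (2.4/1.7 Hz
at 800 MHz; 3.5/5.7 Hz at 600 MHz) apply directly; ppm↔Hz conversion uses
the ¹⁵N/¹H gyromagnetic ratio 0.10136767. σ is the sample SD; the source
protocol's wording ("standard deviation of the mean") conflicts with its
own formula (Δδ_ave + 2σ), and the formula wins — `use_sem=True` selects
the SEM variant. At least 3 residues are required (σ is unstable below
that). Tryptophan side-chain indole NH peaks enter as extra rows keyed
`s-<residue>` and are used in the statistics only when present in both
lists.

Footprint classification: **group1** iff all significant residues fall in
D2.3; **group2** iff D2.3 plus at least one of D2.1/D2.2; **nonbinder** if
nothing is flagged; **ambiguous** otherwise (including any flag outside
D2). The sub-region boundaries are never tabulated in the source; defaults
extend the marker residues symmetrically (D2.1 58–70, D2.2 71–81, D2.3
85–90) and are overridable.

## Global K_d fitting (`idpfrag.titration`)

Fast exchange is assumed (justified by mM affinity): the observed shift of
resonance *r* at titration point *p*, relative to the zero-ligand point, is

    y_rp = Δδ_max,r · f_bound(P_tot, L_p, K_d) + ε_rp

with f_bound from the 1:1 ligand-depletion quadratic
[PL] = ((P+L+K) − √((P+L+K)² − 4PL))/2. δ_free is fixed at the zero-ligand
point rather than fitted (shifts are reported relative to it), removing one
parameter per resonance. All resonances passing the significance screen at
the endpoint are fitted globally — one shared K_d, one Δδ_max per
resonance — weighted by the per-point position uncertainty
(linewidth / SNR).

*Numerics.* For fixed K_d the model is linear in each Δδ_max, so Δδ_max is
profiled out in closed form (variable projection) and the fit reduces to a
1-D search over K_d: a 50-point log-spaced grid spanning 10⁻²–10³ × P_tot,
then bounded scalar minimisation in log₁₀K_d (xatol 1e-12). A grid-boundary
optimum raises a warning (the ladder does not constrain K_d). This is exact
for the weighted least-squares problem, fast enough for Monte-Carlo
resampling, and has no multi-start fragility.

*Monte-Carlo uncertainty.* Each of n_iter (default 500, seed mandatory)
replicates multiplies every ligand total by Normal(1, 0.10) — independently
per point by default; `shared_conc_scale=True` applies one common scale —
adds Normal(0, σ_pos) to every observed shift, and refits; the reported
uncertainty is the sample SD of replicate K_d values. More than 20%
non-convergent replicates is an error.

*Statistical limits.* A Cramér–Rao analysis of the canonical design
(16 points, ratios 1:0…1:30 at P = 100 µM, position noise 2.4 Hz)
shows the relative K_d uncertainty is bounded below by roughly 7% (K_d =
2.2 mM) and 16% (K_d = 4.8 mM) even with eight strong responders at
80 Hz saturation shift. Recovery at the experiment's reported
uncertainties is therefore a ~1–1.6σ statement per replicate, not a
guarantee; the test suite asserts median-error behaviour at module level
and documents per-replicate coverage in the end-to-end suite.

## Displacement and functional assays (`idpfrag.assays`)

*Ratiometric NMR displacement.* In slow exchange, free and bound resonances
coexist; p_f = I_free/(I_free+I_bound) per residue, averaged over
replicates. Ratios R_f = p_f(with)/p_f(without) and R_b analogously; a
residue is "displaced" iff R_f > 1 and R_b < 1 with each inequality
exceeding one propagated replicate SD (configurable `n_sd`; no formal test
is named in the source, which reports triplicate mean ± SD).

*Fluorescence anisotropy.* Direct binding is fitted as
r = r_free + (r_bound − r_free)·f_bound with probe depletion (the
hyperbolic approximation would be nearly identical at probe 20 nM ≪ K_d
73 nM, but the depletion quadratic is exact and costs nothing).
Fluorescence-intensity change on binding is ignored (no quantum-yield data).
An unsaturated ladder warns and flags the fit.

*Dose response.* Four-parameter logistic
bottom + (top − bottom)/(1 + (x/IC50)^h), IC50 fitted in log space, hill
slope floating, asymptotic (covariance) uncertainties via the delta method.
Replicate tables are averaged before fitting.

*Ternary competition.* C + D ⇌ CD, D + L ⇌ DL, optionally C + L ⇌ CL,
parameterised by dissociation constants throughout. Solved by damped
fixed-point iteration on the free concentrations
(C_free ← C_tot/(1 + D/K_CD + L/K_CL), geometric damping 0.5 keeps
iterates positive), converged when every mass balance is satisfied to
10⁻¹⁰ × max(totals). With the NMR-fitted compound affinity (2.2 mM) and no
compound:kinase binding, the model predicts a displacement IC50 of ~11 mM —
more than 20× the measured 475 µM. This gap is kept as a regression test:
it is the quantitative expression of the interpretation that the compound
also binds the kinase.

*Kinase activity.* Relative change = 100·(treated − baseline)/baseline on
percent activities; positive = activation. The reference case 13% → 20% is
a +53.8% activation.

## MD distance states (`idpfrag.mdstates`)

Input is a multi-model PDB (read with MDAnalysis) or a precomputed distance
CSV — the package analyses trajectories, it never runs MD. Cβ–Cβ distances
for the pairs W60–W76, W60–Y88, W76–Y88 are extracted per frame (default
stride 2 ps); window averages are non-overlapping block means (default 1 ns),
with a trailing partial block averaged and flagged.

*Compact/extended classification.* Default rule: a frame is compact iff
min(d(W60,Y88), d(W76,Y88)) < 20 Å (strict). The literal "any pair within
20 Å" rule is selectable, but W60–W76 averages 16.5 Å throughout, so the
literal rule labels nearly every frame compact and erases the two-state
split the distributions actually show; the default keys on the Y88–W
contacts that distinguish the states. Occupancies, per-pair histograms
(0.5 Å bins over 0–50 Å), per-state means, contact co-occurrence fractions
and Pearson trace correlations (reported as undefined for constant traces)
complete the summary. Window-averaging **then** classifying is deliberately
not equivalent to frame-wise classification (a block mean can cross the
cutoff); this is asserted as a documented non-property.

## Synthetic generators (`idpfrag.synthetic`)

All generators are seeded and bit-reproducible.

*Titrations.* Observed shifts follow the fast-exchange depletion model with
additive Gaussian position noise per dimension (default 2.4 Hz ¹H / 1.7 Hz
¹⁵N — the digital resolutions of the 800 MHz experiment), over the
canonical 16-point ladder at P_tot = 100 µM. Ligand concentrations are
exact in simulation; the 10% concentration error exists only inside the
Monte-Carlo resampler, mirroring the error analysis it emulates.
Per-residue saturation shifts are not tabulated anywhere; the defaults
place the eight responders of a Group 2-like footprint at 45–80 Hz — the
upper half of the plausible 20–80 Hz band — because the design's
Cramér–Rao bound shows weaker responders could not have produced the
experiment's reported ~14% relative K_d uncertainty at 2.4 Hz position
noise. Reported per-point uncertainties are linewidth/SNR (defaults 24 Hz /
SNR 10 for ¹H). Not emulated: lineshapes, exchange broadening, peak overlap,
assignment errors.

*Two-state trajectories.* A discrete-frame two-state Markov chain
(geometric dwell; `default_two_state_spec` uses 400/600 frames, giving
nanosecond-scale state stability and 40% compact occupancy) emits
per-pair Gaussian distances per state; true labels are retained. Two
parameterisations ship: `fig9_printed_spec` uses the published per-pair
statistics (16.5 ± 2.3, 20.5 ± 5.5, 19.6 ± 4.0 Å) identically in both
states, so marginals reproduce the printed values exactly and the sample
mean obeys the i.i.d. SD/√n law (Markov dwell autocorrelation would
otherwise inflate the variance of the mean far beyond SD/√n);
`default_two_state_spec` places the Y88-pair states symmetric about the
20 Å cutoff, ~4 pooled SDs apart, for label-recovery tests. Not emulated:
force-field physics, secondary structure, continuous-time dynamics.

*Libraries.* Combinatorial scaffold × substituent SMILES with exact
per-scaffold multiplicities; member *j* of a scaffold combines substituent
*j mod k* with a *j div k*-methylene spacer, all attached through carbon at
one fixed aromatic CH, so every member shares a single alpha-preserved
scaffold (this is what makes the mock HTS frequency table — count =
multiplicity — exact ground truth for the frequency filter). Decoys
(invalid/inorganic/isotope, cycled deterministically) are appended to make
up the requested fraction of the final library and flagged in the truth
table.

## Known limitations

- Single-site 1:1 fast-exchange binding only; no multi-site, cooperative or
  exchange-regime models.
- The REOS list and complexity scorer are documented stand-ins for cited
  but unpublished originals; absolute verdicts/scores are configuration-
  dependent even though the pipeline's behaviour on the shipped defaults is
  fully tested.
- CSP statistics assume a common field strength and resolution per spectrum
  pair; no peak picking or assignment transfer.
- The ternary solver assumes well-mixed mass-action equilibrium with known
  totals; it does not fit K_d values from displacement data.
- Passing tests on generated data demonstrate correctness of the estimators
  under the stated noise models, not robustness to the artefacts real
  spectra and plates contain (baseline drift, overlap, pipetting bias).
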