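# Methods

## Effective-atom reduction

A residue's effective atom is the unweighted mean of **all** its heavy
(non-hydrogen) atom coordinates, backbone included. Averaging only side-chain
atoms is the other defensible reading; including the backbone keeps glycine
well-defined without special-casing, so it is the package's choice and is
applied uniformly. Alternate locations are resolved per atom name by highest
occupancy (tie → first in file); the first model of an ensemble is used
unless a model number is requested. Waters, ligands and nucleic acids are
dropped; a *polymer* residue whose name is neither standard nor in the alias
table (MSE→MET, SEC→CYS, …) is an error rather than silently skipped, so a
truncated selection can never be produced unnoticed.

## Intrinsic hydrophobicity scale

The model needs a per-amino-acid hydrophobicity in [0, 1] but is not tied to
a particular table. The bundled default, `kd-unit`, is the Kyte–Doolittle
hydropathy index min–max rescaled to [0, 1]; `eisenberg-unit` (Eisenberg
consensus, same rescaling) ships as an alternative, and any two-column text
file is accepted. Because published RD/K values depend on the scale and the
original computations' exact table is not fixed by the model definition,
every output records the scale name; numerical agreement with published
per-protein values is expected only to within a few hundredths of RD, with
rank order across environments (aqueous < enzyme < periplasmic < membrane)
the robust signal.

## Gaussian reference field

Centre = centroid of the effective atoms. Axes = principal axes of the
centered cloud (eigenvectors of the scatter matrix), ordered by descending
spread; each axis' sign is chosen so its largest-magnitude component is
positive, then the third axis is flipped if needed to make the frame
right-handed — together these make the frame, and hence all downstream
numbers, reproducible under permutation and rigid motion of the input.
`σ_axis = max|centered coordinate along axis| / 3`, so the molecule spans
±3σ: the conventional way to "adapt the Gaussian to the dimensions and shape
of the protein". A zero extent on one axis (a perfectly planar cloud) borrows
the smallest positive extent and records a warning; an all-coincident cloud
is an error.

## Observed profile

The Levitt contact weight `g(x) = 1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸)` for
`x = r/c` is 1 at contact, 0 at the cutoff, and monotone between. The pair
sum runs over `j ≠ i`: the observed profile expresses *inter*-residue
interaction. A self-term flag (`include_self=True`) exists purely for
sensitivity checks. Cutoff default `c = 9 Å`. If no pair falls inside the
cutoff (or all hydrophobicities are zero) the profile cannot be normalized
and the error names the cause.

## Divergence, RD and exclusion

Divergences are base-2 (`bits`), with `0·log(0/q) = 0`; T is strictly
positive, so `D_KL(O|T)` is always finite. `RD` is undefined only when O
equals both references (reported as an error, not a number). Residue
exclusion (e.g. catalytic residues) removes the named residues **before**
the Gaussian field is fitted: the published lysozyme recalculation changes
both RD and K, which implies full re-derivation rather than merely dropping
terms from the sums. The exclusion list uses author numbering
(`CHAIN:RESNUM[ICODE]`), matching how residues are cited in the literature.

## The mixed field M(K) and the K fit

The doubly-normalized form is read as: normalize the inverse distribution
`Tmax − T` first, scale by K, add to the normalized T, normalize the sum.
`M(0) = T` exactly; `M(K→∞) →` the normalized inverse. K is fitted by a grid
scan (default 0–3.0, step 0.1) because published K values are quoted to one
decimal and the whole `D_KL(O|M(K))` curve is itself a desired output; ties
break to the smallest K (the most water-like reading). An optional second
pass at step/10 around the coarse optimum is available but off by default so
grid-exact parameter recovery stays exact. A uniform T makes the inverse
field identically zero and is rejected for K > 0.

## Information accounting

`I = −log2 p` per symbol. The Ramachandran grid takes its cell count
directly (e.g. 359×359 for the 1° convention), so any binning convention is
representable without endorsing one. Frequency tables are user-supplied;
zero-probability symbols are pruned with a warning since their information
is undefined. The goal model `P = 1 − (1−p)^k` solves the inverse
(`required_repetitions`) in closed form with a one-step integer verification
to be exact at floating-point boundaries; the Monte-Carlo verifier draws
`trials × k` Bernoulli variables from a single seeded generator (chunked to
bound memory) and was calibrated to be unbiased with unit-variance
standardized error.

## Synthetic micelle generator

The generator emulates the spatial picture the model idealizes, not protein
geometry: `n` points uniform in an ellipsoid (`radius × aspect`, defaults
100 points, 15 Å, sphere — a small-domain scale), hydrophobicity a linear
ramp from 1 at the centre to 0 at the surface, quantized onto a real
amino-acid scale so the cloud carries valid residue names and round-trips
through the PDB writer and the CLI. The `discordance ∈ [0,1]` dial swaps
hydrophobicities of matched innermost/outermost pairs: 0 is the ideal
micelle, 1 the full inversion, and the *marginal* hydrophobicity
distribution is preserved exactly, isolating the spatial ordering that RD
measures. What passing tests on these clouds show is that the scoring
machinery behaves correctly (RD low for concordant ordering, high for
inverted, monotone in between, K larger for inverted clouds); they do not
show that any particular real protein family attains particular RD values —
real chains have bonded geometry, secondary structure and packing
correlations the generator deliberately omits.

## Problem sizes and tolerances

Tests and the acceptance script use 100-residue clouds with 20 replicate
seeds per condition, 50–60-entry profiles for K recovery, and 100 000
Monte-Carlo trials — sizes at which every property checked is stable from
seed to seed. Profile normalization is asserted to 1e-9, the brute-force
pair-sum oracle to 1e-12, rigid-motion invariance of RD to 1e-6, noisy K
recovery to two grid steps (0.2), and Monte-Carlo agreement to three
binomial standard errors.

## Known limitations

- Per-residue (effective-atom) resolution only: no all-atom field, no
  solvent-accessible surface, no energetics.
- The K fit is a distributional mixing parameter, not a physical membrane
  model.
- Scoring quality on real structures inherits the chosen hydrophobicity
  scale; comparisons across studies must fix the scale (it is recorded in
  every output for that reason).
- Missing residues in a deposited structure are used as-is; no modelling of
  gaps.
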