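# fodm — fuzzy-oil-drop hydrophobicity scoring for protein structures

`fodm` quantifies how closely a protein structure realizes the *micelle-like*
hydrophobicity arrangement — hydrophobic residues buried in the centre, polar
residues exposed — and how far its folding environment departs from pure
water. It is aimed at structural bioinformaticians studying hydrophobic-core
formation, membrane/periplasmic adaptation, and the residues whose local
misfit to the core encodes function (catalytic sites, binding cavities).

## The model

Each residue is reduced to an **effective atom** (mean of its heavy-atom
coordinates) carrying an intrinsic hydrophobicity `H^r ∈ [0,1]` from a named
scale. Three per-residue distributions, each normalized to sum 1, are
compared:

- **T** (theoretical): a 3D Gaussian fitted to the molecule (centroid,
  principal axes, `σ = extent/3` per axis) and evaluated at the effective
  atoms — the idealized micelle with maximal hydrophobicity density at the
  centre.
- **O** (observed): summed pairwise Levitt contact interactions
  `O_i ∝ Σ_{j≠i, r_ij≤c} (H_i^r + H_j^r) · g(r_ij/c)` with
  `g(x) = 1 − ½(7x² − 9x⁴ + 5x⁶ − x⁸)` and cutoff `c = 9 Å`.
- **R** (uniform): `1/N` per residue — no hydrophobicity differentiation.

Agreement is measured by base-2 Kullback–Leibler divergence
(`divergence entropy`) and summarized as the **Relative Distance**

```
RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))
```

`RD < 0.5` indicates a centric hydrophobic core. For non-aqueous
environments the reference is the mixed field

```
M(K) = normalize( T + K · normalize(Tmax − T) )
```

where `K = 0` is pure water and growing `K` means growing membrane-like
character; the best `K` minimizes `D_KL(O|M(K))` over a grid scan.

The package also includes the Shannon-information accounting for the coding
chain (bits per nucleotide triplet, per amino acid, per Ramachandran cell)
and the goal-attainment model `P = 1 − (1−p)^k` with a Monte-Carlo verifier.

## Worked example

Generate an ideal synthetic micelle (100 residues, hydrophobicity decreasing
with radius) and score it:

```
$ fodm synth --n 100 --discordance 0 --seed 1 --out micelle
wrote micelle.pdb and micelle_scale.txt (n=100, discordance=0.0, seed=1)
$ fodm score micelle.pdb --out-dir .
RD=0.299 K=0.2 (core_present, n=100)
```

`micelle_result.json` then contains (abridged):

```json
{
  "classification": "core_present",
  "dkl_OT_bits": 0.2616341753358609,
  "dkl_OR_bits": 0.6148286288654371,
  "rd": 0.29851144176538397,
  "k": 0.2,
  "n_residues": 100,
  "scale_name": "kd-unit"
}
```

The observed distribution is about 2.3× closer (in divergence) to the
Gaussian micelle reference than to the uniform one, so `RD ≈ 0.30 < 0.5`:
a centric hydrophobic core is present, and the small fitted `K = 0.2` says
the arrangement is essentially the aqueous (pure-water) one. Scoring the
same cloud with `--discordance 1` (hydrophobicity inverted onto the surface)
drives `RD` above 0.8 and `K` to the top of the scan grid.
`micelle_profiles.tsv` holds the per-residue `T/O/R/M` columns and
`micelle_kscan.tsv` the full `D_KL(O|M(K))` curve.

Real structures work the same way, e.g.
`fodm score 1lz1.pdb --chain A --exclude A:35,A:53,A:128` re-scores human
lysozyme with its catalytic/cavity residues removed before the field is
refitted.

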