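# ancestrybench

A toolkit for building and scoring a **blinded ancestry-label benchmark** on
fully synthetic genotype data, plus the accompanying admixture-distance
analysis:

- **`synthetic_data`** — Balding–Nichols ancestral allele-frequency panels,
  admixed phased founders, and simulated 9-component reference admixture
  cohorts (default profile: Mediterranean 57.7 ± 1.2 %, South West Asian
  23.9 ± 0.6 %, Sub-Saharan African 9.4 ± 0.5 %, Northern European
  3.2 ± 1.3 %, five minor components sharing the residual mass).
- **`pedigree_sim`** — forward-in-time simulation: random male–female pairing
  of 30 founders (half carrying a binary self-report label), block
  recombination at hotspots every 10,000 markers (one random parental
  haplotype per block), 4 offspring per pair with fair-coin sex, a
  sex-balanced cohort of 30 re-paired each round, for 2 generations.
- **`descent_rules`** — label propagation: the matrilineal rule (`halacha`,
  labeled iff the strict maternal-line founder is labeled) and the
  ≥1-labeled-grandparent rule (`law_of_return`, configurable threshold 1–4
  and grandparent basis), plus a patrilineal variant.
- **`benchmark_scoring`** — blinding (seeded id permutation; sex, pedigree and
  labels stripped from the public files) and scoring of
  `{blinded_id → bool}` submissions (accuracy / sensitivity / specificity /
  confusion counts per rule).
- **`ld_prune`** — windowed genotypic-r² pruning (window 200, step 25,
  r² > 0.4 by default; later-indexed member of each high-LD pair removed;
  re-scanned to convergence; windows never span chromosomes).
- **`admixture_distance`** — supervised admixture estimation against K fixed
  ancestral profiles via monotone projected-gradient simplex-constrained
  least squares; the distance statistic `d` (minimal Euclidean distance from
  an individual's admixture vector to any member of a target cohort); the
  undirected `d < 0.075` threshold graph with connected components; per-group
  mean ± SD component summaries.
- **`genotype_io`** — PLINK text `.ped`/`.map` I/O, sex/label sidecar TSVs,
  JSON answer keys, Q/F matrix TSVs, edge lists. Text formats are canonical;
  the counted allele is the first non-missing allele seen per marker in file
  order.

## CLI

```sh
ancestrybench prune --ped founders.ped --map founders.map --window 200 --step 25 --r2 0.4 --out kept.tsv
ancestrybench hybridize --ped founders.ped --map founders.map --meta founders.meta.tsv \
    --generations 2 --spacing 10000 --seed 1 --out-prefix release/challenge
ancestrybench score --rule halacha --key release/challenge.key.json --submission my_predictions.tsv
ancestrybench cohort --n 5000 --seed 1 --out reference_q.tsv
ancestrybench distance --q reference_q.tsv --threshold 0.075 --out edges.tsv
```

`hybridize` writes the blinded public `.ped`/`.map`, the private answer key
(JSON), the pedigree table and a release manifest. Submissions are TSVs of
`blinded_id <TAB> prediction` with predictions in `{0,1}`.

## Reproducibility

Every stochastic operation draws from a named substream of a single root
seed (`ancestrybench._rng.substream`), so results are bit-reproducible and
independent of call order.
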