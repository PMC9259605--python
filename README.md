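# tagkin

Tag-based (greenbeard) kin recognition in the haploid island model, with
partner search.

The package implements four connected pieces:

- **`tagkin.coalescence`** — the neutral identity-by-descent probabilities
  `F, phi, G, gamma` of the island demography (deme size `N`, gamete
  migration `m`, tag–trait recombination `r`), solved exactly as absorption
  probabilities of a backward-time lineage Markov chain, plus a
  mechanistic Monte-Carlo coalescent oracle for validation.
- **`tagkin.engine`** — deterministic infinite-island genotype-frequency
  recursions over `L_max` tags × {defect, help}: social-interaction
  expectations (interaction, help-received and abandonment "M-terms"),
  absolute fitness (population mean exactly 1), selection, recombination
  and mutation steps, iteration to equilibrium and trajectory summary
  statistics (effective tag number, helping frequency, tag diversity,
  tag–trait linkage disequilibrium, pedigree-relatedness deviation, tag
  excess helping). A fused numba kernel (optional, auto-detected) runs
  millions of generations per second-scale budgets; a pure-numpy reference
  path is always available and tested against it.
- **`tagkin.inclusive_fitness`** — regression relatedness of actors to
  recipients (`R_tag`) and to displaced competitors (`R_competitor`), and
  the Hamilton's-rule condition
  `R_tag*b - c - (b-c)*R_competitor > 0` predicting where kin
  discrimination is favoured, with the closed-form payoff of
  indiscriminate helping (always ≤ 0 in this lifecycle).
- **`tagkin.abm`** — a stochastic agent-based simulator of the identical
  lifecycle for finite populations, used to validate the deterministic
  recursion and to run tag-fixation-time / balancing-selection
  experiments (tag fixation ratio = selected / matched-neutral fixation
  time).
- **`tagkin.experiments`** — config-driven (m, r) stability scans,
  stable-vs-Hamilton-region comparison, area fractions, and the
  interaction-probability curve.

## CLI

The console script `tagkin` exposes the main operations:

```sh
tagkin ibd --N 30 --m 0.3 --r 0.1 --oracle --reps 100000 --seed 1
tagkin trajectory --N 30 --m 0.3 --r 0.08 --alpha 1 --b 0.3 --c 0.1 \
    --mu-trait 0.001 --L-max 100 --generations 50000 --out trajectory.csv
tagkin hamilton-map --grid-m 0.02,0.9,8 --grid-r 0,0.5,8
tagkin scan --config scan.json --out map.csv
tagkin abm-run --n-demes 200 --generations 200 --out abm.csv
tagkin abm-fixation --sizes 4,8,16 --alphas 0,1 --replicates 20 --out fix.csv
tagkin interaction-curve
```

`tagkin trajectory` and `tagkin scan` accept a JSON config file mirroring
the CLI flags; explicit CLI flags win.

## Model in one paragraph

Haploid individuals live in demes of `N`; each generation every individual
searches its deme for a social partner, abandoning tag-mismatched
partners with probability `alpha` (paying `c_search` per abandonment) and
helping tag-matched partners if it carries the helping allele (cost `c`,
benefit `b`); gametes migrate at rate `m`, fuse at random, recombine
between tag and trait loci at rate `r`, mutate, and `N` adults are
resampled per deme. Without partner search (`alpha = 0`) common tags are
favoured and recognition collapses; with cheap search, rare tags become
reliable kinship cues, acquire excess helpers, and are held in the
population by negative frequency dependence — kin recognition maintains
its own tag diversity.
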