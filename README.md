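# bimotif

Discovery of **bipartite RNA motifs** — two short sequence cores bound
cooperatively by a two-domain RNA-binding protein (RBP), separated by a
flexible linker of preferred length — from enriched vs. background sequence
sets (SELEX-style selections, or any bound/input contrast).

Many RBPs carry several RNA-binding domains or oligomerize, so they
recognize *pairs* of short, often degenerate cores at a characteristic
spacing rather than one long motif.  Tools built around a single
position-weight matrix miss both the second core and the geometry between
them.  `bimotif` addresses this with a statistical-mechanics model:

- each domain has a table of binding energies `E_A(m)`, `E_B(m)` (k_B·T)
  over all 4^k k-mers `m` (default k = 3);
- the effective concentration of the tethered second domain at spacer
  distance `d` is `c_B(d) = c_AB + S·NB(d; r, p)`, a scaled negative
  binomial over the linker length (free-protein concentration `c_AB ≡ 1`);
- the partition sum `Z(x)` over **all** binding configurations of zero, one
  or more proteins on sequence `x` is computed by an O(L²) dynamic program,
  and the occupancy is `p(bound|x) = 1 − 1/Z(x)`;
- parameters are fit by maximizing the one-round selection likelihood
  `LL = Σ_{x∈X+} ln(1−1/Z(x)) − N₊ ln Σ_{x'∈Xbg} p_bg(x')(1−1/Z(x'))`
  (plus a parameter-free library term) with analytic adjoint gradients and
  ADAM.

Intended users: anyone analyzing in-vitro selection (HTR-SELEX, RBNS-like)
or CLIP-style data who wants interpretable core motifs *and* the spacing
law between them, with honest uncertainty about whether a protein binds one
long site or two spaced ones.

## Worked example

Generate a synthetic benchmark (2×500 random 40-mers; the enriched set
carries `AAA`, a negative-binomial NB(4, 0.4) gap, then `CCC`), train, and
inspect the model — all in Python:

```python
from bimotif import (SyntheticConfig, TrainConfig, make_benchmark,
                     predict_scores, summarize_model, train)
from bimotif.analysis import render_motif_text

data = make_benchmark(SyntheticConfig(n_enriched=500, n_background=500, rng_seed=0))
model, trace = train(data, k=3, config=TrainConfig(minibatch_size=128, rng_seed=0))
print(f"stopped after {trace.n_iterations} iterations ({trace.termination_reason})")
print(render_motif_text(summarize_model(model), max_spacer_rows=8))
```

which prints:

```
stopped after 780 iterations (converged)
core A (top 5 k-mers, probabilities renormalized to 1):
  AAA   0.988  ########################################
  CCC   0.005  #
  AAC   0.003  #
  GAA   0.002  #
  AAG   0.001  #
core B (top 5 k-mers, probabilities renormalized to 1):
  CCC   0.992  ########################################
  AAA   0.004  #
  ACC   0.001  #
  CCG   0.001  #
  GCC   0.001  #
P(spacer > 0) = 0.9493  -> bipartite
core similarity (Pearson) = -0.0067
motif entropy = 0.1366 bits/position
repetitiveness = 0.0729
spacer length pmf:
  d=0     0.0507  ##
  d=1     0.0963  ####
  d=2     0.1216  #####
  d=3     0.1277  #####
  d=4     0.1205  #####
  d=5     0.1061  ####
  d=6     0.0889  ####
  d=7     0.0717  ###
  ... (93 more rows, tail mass 0.00e+00)
```

Reading the output: the minimum-energy k-mer of each core is the implanted
one (`AAA` upstream, `CCC` downstream, carrying ~99% of each core's
Boltzmann probability); the learned spacer distribution peaks at d = 3
(implanted law: mode 4, mass concentrated on 2–6) and `P(spacer > 0)` near
1 classifies the motif as bipartite rather than one adjacent block.  The
low entropy (0.14 bits/position vs. ~2 for a random model) says the motif
is sharply determined.

Scoring new sequences uses the mean binding probability over 50-nt windows
(stride 20):

```python
scores = predict_scores(model, [("enriched_0", data.enriched[0]),
                                ("background_0", data.background[0])])
# enriched_0    0.5012  (1 window)
# background_0  0.0043  (1 window)
```

## Command line

The same pipeline as four subcommands:

```bash
bimotif generate --out-enriched enr.fasta --out-background bg.fasta --seed 0
bimotif train enr.fasta bg.fasta --core-length 3 --seed 0 --out model.json
bimotif visualize model.json
bimotif predict model.json peaks.fasta --window 50 --stride 20 --out scores.tsv
```

FASTA or one-sequence-per-line input is accepted; DNA is read with `T → U`.
Models are versioned JSON files that round-trip bit-exactly; scores are TSV
(`id`, `score`, `n_windows`).

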