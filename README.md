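# clickselex

Analysis toolkit for doped-reselection (SELEX) experiments on
click-ligating deoxyribozymes (DNAzymes) — single-stranded DNAs selected
to join a 5′ alkyne and a 3′ azide into a triazole linkage. It is aimed at
in vitro selection groups who need to (i) simulate doped libraries and
activity-driven selection rounds with a known ground truth, (ii) process
deep-sequencing pools from a reselection, (iii) map functionally essential
nucleotides with the per-position **Variation Index**, and (iv) quantify
ligation activity from gel densitometry and time courses.

## The statistics at the core

**Variation Index.** A reselection library is synthesized around a winning
clone with every position of its 40-nt catalytic domain mutated at rate
*r* (here 45%). After selection, each position's observed mutation
frequency is normalized by the doping rate:

    VI = (1 − N/N_t) / r

where *N* counts sequences retaining the reference base at the position
and *N_t* counts all evaluable sequences. VI ≈ 1 is neutral drift,
VI < 1 marks functionally important (conserved) nucleotides, and VI > 1
mutation-tolerant ones.

**Gel metrics.** For a two-band lane, `Lig% = 100·lig/(lig + unlig)`.
For intramolecular circularization (three bands), the yield and
selectivity are `Y% = 100·CP/(unlig + CP + LLP)` and
`S% = 100·CP/(CP + LLP)` (CP: circular product, LLP: linear ligated
product), so S ≥ Y always.

**Kinetics.** Ligation time courses are fit by bounded nonlinear least
squares to the single-turnover saturation model
`Y(t) = Y_max · (1 − e^(−k_obs·t))`, reporting the observed rate constant
`k_obs` (h⁻¹) and plateau yield `Y_max` (%).

The selection simulator treats ligation as stochastic survival: a molecule
with rate *k* survives a round of duration *t* with probability
`1 − e^(−kt)`; re-amplification is multinomial resampling. The
sequence→rate map is a synthetic stand-in (multiplicative penalty per
violated base constraint) that exists so conservation recovery can be
tested against a known ground truth.

## Worked example

```python
import numpy as np
import clickselex as cx

spec = cx.LibrarySpec()                       # 21-nt PBS + 40-nt doped + 21-nt PBS
truth = cx.ActivityModel.from_reference(      # ground truth: 8 essential positions
    spec, [24, 28, 33, 38, 43, 48, 53, 58], k_max=0.5, mismatch_penalty=0.2)

result = cx.simulate_selection(spec, truth, cx.reselection_schedule(20000), seed=303)
print([round(f, 3) for f in result.trajectory])

trimmed, _ = cx.anchor_and_trim(result.final_pool, spec)
profile = cx.build_profile(trimmed, spec)
print(round(profile.vi_at(28), 3), round(profile.vi_at(29), 3))
print(round(float(np.median(profile.table["VI"])), 3))
```

prints

```
[0.069, 0.39, 0.624, 0.742, 0.764, 0.668, 0.495]
0.007 0.972
0.981
```

The trajectory is the per-round ligation fraction rising as the pool
enriches, then dipping as the reaction time is cut to 6, 3 and 1.5 h. The
constrained position 28 comes back with VI ≈ 0.01 (strongly conserved),
its unconstrained neighbor 29 sits at VI ≈ 1 (neutral drift), and the
pool-wide median VI stays near 1.

The same pipeline is available from the shell:

```sh
clickselex simulate --out-dir sim        # pool FASTA + trajectory TSV
clickselex analyze sim/final_pool.fasta  # trim, cluster, VI profile, element summary
clickselex fixtures --out-dir fx && clickselex quantify fx/timecourse.tsv
```

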