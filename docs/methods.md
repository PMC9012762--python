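# Methods

## Model structure

The simulator tracks a panmictic population with discrete, non-overlapping
generations through four stages: virgin adults → mothers (inseminated
females) → eggs → larvae → next generation's virgin adults. All demographic
bookkeeping is per diploid genotype over three allele states per locus
(wild-type W, drive D, cleavage-resistant resistance allele R); BED designs
use two unlinked autosomal loci (A: transactivator drive, B: effector drive),
single-drive designs one locus.

### Inheritance

Homing is modelled as pre-meiotic conversion of the germline genotype in
drive/wild-type heterozygotes followed by fair segregation: the wild-type
allele becomes a drive copy with probability *h*, a resistance allele with
probability *r*, and is left intact otherwise, giving marginal gamete
probabilities `pD = (1+h)/2`, `pR = r/2`, `pW = (1−h−r)/2`. This is
marginally identical to per-gamete conversion. Conversion acts identically in
both sexes and is evaluated lazily at egg creation (meiosis only matters for
mothers and mating males). Resistance alleles are cleavage-resistant by
definition and are never re-cut: D/R and W/R genotypes segregate Mendelianly.
We verified the alternative (re-cutting the R allele in D/R heterozygotes)
purges resistance so thoroughly that every reference scenario collapses —
qualitatively incompatible with the behaviour this model is meant to exhibit.
Loci segregate independently; the offspring distribution of a cross is the
product over loci of the outer product of parental gamete distributions.

### Fitness effects

*Intended effects* scale with a dominance multiplier on drive genotypes: 0
without both components (BED) or without a drive allele (SD); the dominance
degree *Dd* for double (or single-locus) heterozygotes; 1 for full
homozygotes; and the arithmetic midpoint `(1+Dd)/2` when exactly one BED
locus is drive-homozygous ("intermediate" is not otherwise specified). In
ffBED/ffSD the intended effect multiplies the mother's fecundity by
`1 − cost × multiplier`; in sBED it is the probability
`efficiency × multiplier` that a mating kills the female.

*Unintended costs* are dominant and act once per drive type carried:
`(1−u)^k` on male mating weight and mother fecundity, `(1−v)^k` on egg
survival (k = number of loci with ≥1 D allele), following the explicit
two-drive form `1 − (1−c)²`.

*Resistance functionality* ρ: in BED designs the targets are essential for
development, so eggs homozygous for R at any locus survive with probability
ρ (default 0 — nonfunctional r2 alleles); heterozygous carriers are
unaffected (recessive, conservative). In ffSD the target is a female
fertility gene: R-homozygous mothers keep a fraction ρ of fecundity,
R/W-heterozygous mothers are interpolated by *Dd* between ρ and 1.

*ffSD drive/resistance heterozygotes.* A D/R mother carries no functional
copy of the fertility gene under nonfunctional resistance, so by default she
pays the full intended cost exactly like a D/D mother
(`ffsd_dr_rule="as_drive_homozygote"`). The alternative reading — interpolate
between the D/D multiplier and wild type by *Dd*, which leaves D/R mothers
fully fertile when the disruption is recessive — is exposed as
`ffsd_dr_rule="interpolate"`. The default was chosen because the interpolated
rule creates a fertile refugium for drive+resistance genotypes that
neutralises the reference single drive entirely (0% elimination, load plateau
~0.52), contradicting the behaviour the design is known for; with the default
rule the reference ffSD eliminates ~97% of replicates and trails the seminal
BED by ~6 generations, as expected.

### Mating

Each generation, both the probability that a virgin female mates (*CM*) and
the scaling of her expected mate number (*NM*) equal the mate-finding Allee
sigmoid `1 − 1/(1 + e^{0.01(N − critical)})` — ½ at the critical population
size (default 250), saturating to 1 at large censuses, applied smoothly every
generation. The census argument is the total virgin-adult count by default
(`allee_argument="adults"`); the virgin-male count is available as a config
switch. The total-adult census was adopted after comparing both variants on
the reference scenarios: it reproduces the known polyandry-restriction
behaviour (elimination rates of ~1% within 36 and ~78% within 36–60
generations at polyandry degree 2) where the male-count census overshoots. A
critical size of 0 disables the effect entirely (factor 1) rather than
leaving the sigmoid's residual ≥½ floor, so that "no Allee effect" scenarios
mean what they say.

A mating female's mate count is Poisson(λ = 2·P·NM) truncated by
renormalisation to {1..P} (P = polyandry degree): at P = 3 and NM = 1 the
pmf is (0.1, 0.3, 0.6). Clamping out-of-range draws to the boundary was
considered and rejected: it concentrates nearly all mass on P and destroys
the polyandry sensitivity of the seminal design. Mates are drawn with
replacement (a male may inseminate any number of females), weighted by
`(1−u)^k`. In sBED each mate independently kills the female with his kill
probability; terminator kills are evaluated over the full mate set
(simultaneous polyandry), and killed females leave nothing. Surviving
mothers hold equal sperm shares from all mates.

### Reproduction, mortality, density dependence

Clutch size is Poisson with mean `F × fecundity multipliers`; each egg's
paternal gamete comes from a uniformly chosen mate. Eggs die from the
unintended viability cost and resistance lethality; the survivors (larvae)
undergo Beverton–Holt survival `Ls·N50/(N + N50)` with
`N50 = K/(Ls − 2/F)`. This denominator makes the printed N50 self-consistent:
at the wild-type equilibrium (K/2 mothers × F eggs) survival is exactly 2/F
and expected adult output is K. Baseline egg-to-larva mortality beyond these
terms is zero, since `Rm = F·Ls/2` leaves no room for another factor. Sex is
independent Bernoulli(½) per survivor.

### Records and collapse

Each generation records the virgin-adult census, per-locus allele
frequencies, and the realised genetic load
`1 − (0.5·Ls·viable eggs / virgin females)/Rm` — the proportional reduction,
density-dependent mortality excluded, of adult daughters per female relative
to Rm (zero in expectation drive-free; computed from realised counts, not
expectations). A replicate is eliminated when no female becomes a mother, no
viable egg is produced, or no adult virgin female emerges — exactly these
three conditions.

## Aggregated engine

States are integer count vectors over the 6 (SD) or 36 (BED) genotypes, and
every stochastic stage is an exact aggregation of the per-individual process:

- per-female Bernoulli gates → binomial draws per genotype;
- mate counts → multinomial over the truncated-Poisson pmf;
- terminator survival factorises over mates, so a surviving mother's mates
  remain i.i.d. from the kill-tilted male distribution (tilt ∝ 1 − kill);
  survival probability with k mates is s^k with s the mean per-mate survival;
- a Poisson clutch split uniformly over k mates is an independent
  Poisson(λ/k) per mate slot, and multinomial thinning of Poisson totals
  yields independent Poissons per offspring genotype.

A goodness-of-fit test against the exact cross distribution on a 200-mother
instance is part of the suite. The aggregation makes a full-scale replicate
(K = 50,000, 36 generations) run in a few milliseconds, so all benchmark
scenarios use the full published scale (100 replicates, K = 50,000).

## Defaults and derived quantities

| Parameter | Default | Meaning |
|---|---|---|
| fecundity F | 48 | Poisson clutch mean per mother |
| larval survival Ls | 0.5 | density-independent larva→adult survival |
| carrying capacity K | 50,000 | adult equilibrium census |
| critical population size | 250 | Allee midpoint (0 = disabled) |
| polyandry degree P | 3 | max/modal mates per female |
| homing efficiency h | 1 (ideal) / 0.9 (reference) | conversion probability |
| resistance formation r | 0 / 0.05 | R-allele creation probability |
| unintended costs u, v | 0 / 0.025 | per-drive dominant costs |
| dominance degree Dd | 0.6 (BED), 0 (ffSD) | heterozygote effect fraction |
| terminator efficiency | 0.95 (sBED) | kill probability of AABB mating |
| intended fecundity cost | 1 (ffBED, ffSD), 0 (sBED) | sterilisation strength |
| resistance functionality ρ | 0 | r2 (0) to r1 (1) alleles |

Derived: `Rm = F·Ls/2 = 12`, `Lc = 1 − 1/Rm ≈ 0.92`,
`N50 = K/(Ls − 2/F) ≈ 109,091`.

Releases default to a single bout at generation 0: homozygous males per
construct in BED (AAbb and aaBB; double homozygotes are hard to mass-rear),
drive heterozygotes in SD. Multi-bout schedules are supported in the release
config but unused by the benchmark scenarios. Relative population size is
reported against K; elimination "within G generations" counts collapse at any
generation index ≤ G (release = generation 0).

## What the simulations do and do not show

The generator *is* the study system: a hypothetical, demographically ordinary
insect. Real populations add spatial structure and non-random mating (which
can cluster drive-free refugia and stall BEDs), sequential rather than
simultaneous polyandry (females could oviposit between matings, weakening the
seminal design), age structure, seasonality, and density dependence deviating
from Beverton–Holt. Passing benchmarks therefore demonstrates correctness of
the stated model, not field efficacy.

## Numerical notes

- One `numpy` Generator per replicate, spawned from a root `SeedSequence`;
  identical seeds give bit-identical trajectories, and the vectorised
  aggregation preserves one-draw-per-decision distributional semantics.
- Probabilities arising from weighted dot products are clipped to [0, 1]
  against 1-ulp overshoot.
- Degenerate inputs: populations that cannot replace themselves
  (`Ls ≤ 2/F`, i.e. Rm ≤ 1) are rejected at configuration; empty male or
  female pools short-circuit to collapse; the genetic load of a
  zero-female generation is reported as 1.
- Mean trajectories count collapsed replicates as zero adults from the
  collapse generation onward; load and allele frequencies are undefined
  (NaN) there and excluded from plateau means.
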