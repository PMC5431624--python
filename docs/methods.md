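# Methods

This note documents the models behind each `mitohet` stage, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Double-peak heteroplasmy calling

A Sanger chromatogram of a heteroplasmic template superimposes two
haplotypes: at a site where they differ, two peaks appear whose heights are
roughly proportional to the two templates' abundances. The caller
operationalizes "both peaks clearly above background" with two thresholds:

* **noise floor** — the median of the non-maximal channel heights over a
  window of `w = 5` sites on each side of the focal site (the site itself
  excluded, windows truncated at sequence ends). Using neighbouring sites
  mimics how a human reader judges background from the surrounding clean
  trace; the median makes the floor robust to one stray peak in the window.
* **peak tests** — a site is heteroplasmic iff the two largest channel
  heights both exceed `k × floor` with `k = 3`, **and** the minor/major
  ratio is at least `r = 0.2`. If even the largest peak fails the noise
  test the call is `N`. Equal maximal peaks above noise are a heteroplasmic
  call with bases in alphabetical order, so output is deterministic.

`k`, `r` and `w` are exposed in `CallerParams`. The source procedure gives no
numeric thresholds, only "significantly higher than the basic noise level",
so these are this package's calibration: `k = 3` is the usual
three-sigma-style margin, `r = 0.2` rejects minor peaks that are plausible
bleed-through while keeping mixtures down to ~1:5, and `w = 5` gives a
30-value background sample. Both decision rules compare heights to scaled
heights, so calls are invariant to uniform rescaling of the trace (tested).
Heteroplasmy is *confirmed* only when an independent replicate read calls the
same ambiguity code at the same site, mirroring re-extraction/re-sequencing
practice; singleton polymorphisms (rare base in exactly one isolate) are
flagged for chromatograph re-inspection rather than silently accepted.

## Haplotype-mixture phasing and classification

Heteroplasmic isolates are treated exactly like unphased diploid genotypes:
an isolate with ambiguity codes at `s` sites is compatible with `2^(s-1)`
unordered haplotype pairs, and homoplasmic isolates contribute two copies of
their haplotype. `em_phase` runs the standard Excoffier–Slatkin EM on
haplotype frequencies: E-step weights each candidate pair `(a, b)` by
`2^[a≠b] f_a f_b`, M-step re-estimates `f` from expected copy counts;
iteration stops when the largest frequency change is below `tol = 1e-8`
(default `max_iter = 500`; running out sets a warning flag rather than
raising). The log-likelihood is non-decreasing and frequencies sum to one at
every iteration (tested). A coalescent-prior MCMC phaser would add nothing
here: the mixtures to resolve sit against abundant homoplasmic references,
where the maximum-likelihood resolution is already essentially determined by
the frequency spectrum, and at one ambiguous locus the unordered pair is
unique. `consistent_pairs` provides the deterministic counterpart: all
catalog pairs whose site-wise superposition equals the observed sequence,
with novel-haplotype completions offered only when no catalog pair fits.

Classification uses the **two-copies-per-isolate** bookkeeping: per
population, each homoplasmic isolate contributes 2 copies and each resolved
heterozygote 1 copy per constituent haplotype, so copy counts sum to twice
the sample size (the packaged survey satisfies this for every population).
Before classifying, each heterozygote's own copies are subtracted; a
haplotype counts as homoplasmically present when **≥ 1 residual copy**
remains. A genotype is *local* if both haplotypes are present in its own
population, else *global* if both are present somewhere in the sample, else
*unexplained*. The ≥1 threshold after subtraction is the only rule that
reproduces the packaged survey's full annotation pattern, including the
genotype whose second haplotype survives only as a single residual copy in a
different population. One population in the packaged survey carries an odd
single-copy count for haplotype 3 with no local heterozygote containing it;
it is treated as given data, not corrected.

## qPCR relative copy number

At the fluorescence detection threshold the amplified mass of every amplicon
is taken as equal and amplification as perfect doubling, so
`L_n · N_n · 2^ct_n = L_m · N_m · 2^ct_m`. With the single-copy nuclear
reference at `N_n = 2` per cell (dikaryotic cells: two nuclei, one copy
each), the target copy number is `N_m = (2 L_n 2^ct_n)/(L_m 2^ct_m)`. No
efficiency-calibration mode exists by design; deviations from doubling are
out of scope. Replicates are paired by index (replicate *i* of target vs
replicate *i* of reference) and summarized as mean ± sample SD; mismatched
replicate counts fall back to mean-Ct with the SD omitted. Ratios between
two variants are computed from mean copy numbers, not as a mean of
per-replicate ratios; against a published panel whose ratio row used
per-replicate averaging this produces a Jensen-inequality gap of up to
~10%, which the tests document rather than hide. Because per-replicate Ct
values are never printed, recomputation from mean Ct values can only be
checked to within one printed SD — which holds for every cell of the
packaged six-strain panel.

The idealized end-point detection model (`amplicon_detected`: detected iff
`copies × cells × 2^cycles ≥ threshold`) exists to reason about two-cycle
genotyping designs, where 25 cycles see only the abundant variant and 45
cycles also reveal a 10⁻⁴-copies-per-cell minor variant.

## Clonality and recombination statistics

For `n` isolates the mismatch distance between two rows is the number of
loci with different alleles, over loci typed in both (pairwise deletion;
a pair with no shared typed locus is dropped with a warning). With `V_O` the
variance over all isolate pairs of that distance, `var_j` the per-locus
mismatch-indicator variance and `V_E = Σ var_j`:

* `I_A = V_O / V_E − 1` (0 under linkage equilibrium),
* `r̄_d = (V_O − V_E) / (2 Σ_{j<k} √(var_j var_k))`, bounded in [−1, 1].

All variances use the population denominator (divide by the number of
pairs), matching the convention of the classic Multilocus implementation;
the choice only matters at small `n` and is isolated in one function if a
sample-denominator variant is ever needed. Monomorphic data (`V_E = 0`)
return an undefined-flagged result instead of a division by zero.
Significance comes from shuffling alleles independently within each locus
(missing cells stay in place), which preserves allele proportions while
destroying between-locus association; `p = (1 + b)/(1 + n_perm)` with
`n_perm = 500` by default, one-sided against high `I_A`.

Phylogenetic compatibility of two (possibly multi-allelic) loci is decided
on the bipartite graph whose vertices are the two loci's alleles and whose
edges are the observed allele combinations: compatible iff the graph is a
forest. This is equivalent to the printed-table "marked box" rule (leave a
marked cell and return to it by alternating horizontal/vertical moves
through marked cells) — note the moves must alternate, since two consecutive
same-direction moves would spuriously flag any row with three marked cells —
and reduces to the four-gamete test for biallelic loci. The test suite
checks the forest test against an independent brute-force path-search oracle
on a thousand random locus pairs. `PcP` is the fraction of compatible
unordered locus pairs; the incompatibility permutation test reports
`p = (1 + #{null ≤ observed})/(1 + n_perm)` — small when the data show
markedly *fewer* incompatible pairs than artificially recombined data, i.e.
look clonal — along with the opposite tail, because the compatibility null
("no recombination") runs in the opposite direction from the shuffling null
("free recombination").

Clone correction keeps the lexicographically smallest isolate id per
distinct multilocus genotype and is idempotent. Heterozygous cells are
excluded (masked to missing) from all association statistics by default;
callers who want them included must phase first. `sites_to_loci` turns an
alignment into one locus per polymorphic site for intra-genic tests,
rejecting two-base ambiguity codes outright and treating `N`/`-` as missing.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses assume:

* **Genotypes** — `clonal` replicates a founder set round-robin (explicit
  founders in equal numbers are reproduced exactly), `panmictic` draws loci
  independently from their allele frequencies, `mixed` interpolates via
  `clonal_fraction`. Populations are assigned round-robin.
* **Heteroplasmy** — injected at exactly one locus per selected isolate
  (matching the empirical observation that heteroplasmy at two different
  genes rarely co-occurs in one isolate), second allele drawn from the
  population's allele pool, with the full truth recorded for recovery tests.
  Because real mixing fractions behind observed double peaks are unknown,
  the default `mixing_fraction = 0.5` is a free parameter, and the caller's
  round-trip tests sweep it.
* **Traces** — major-base channel mean `signal`, minor-base channel mean
  `signal × mixing_fraction` at differing sites, plus half-normal
  (zero-truncated Gaussian) noise so fluorescence stays non-negative. The
  acceptance round trip uses noise SD at 3% of signal, a clean
  Sanger-quality read.
* **Ct panels** — exact inversion of the copy-number equation plus Gaussian
  replicate jitter; at zero jitter the estimator recovers injected copy
  numbers to floating-point accuracy (tested at 1e-9 relative).

Not emulated: coalescent genealogies and mutation processes, base-quality
modelling, indels, dye blobs or other chromatogram artifacts, PCR
efficiency below 2, plate effects. Passing round-trip tests therefore shows
the pipeline is *internally consistent* — each stage inverts the generative
model the others assume — not that it is robust to every failure mode of
real traces or real qPCR runs.

## Problem sizes and determinism

A single integer seed drives every generator (numpy PCG64); simulation
outputs embed their seed in provenance metadata, and CLI outputs carry a
version/seed/config-hash header, so identical inputs give identical bytes
for deterministic stages. The acceptance script derives independent child
seeds from `--seed` via `SeedSequence.spawn`. Its simulation sizes — 1000
random locus pairs for the oracle comparison, 50 panmictic datasets of 50
isolates × 5 loci with 200 permutations each for the type-I check, 150
isolates for the EM recovery run — are chosen so the binomial/Monte-Carlo
error bands quoted in the tests are meaningful while the whole script runs
in seconds on one core.

## Known limitations

* The published multilocus statistics for the real fungal sample cannot be
  recomputed here: the per-isolate genotypes exist only as sequence-archive
  accessions, not printed tables. The statistics are instead validated on
  data with known answers (hand-computed examples, oracle comparisons,
  calibration checks) — see `scripts/acceptance.py`.
* The EM phaser ignores linkage to other loci and any genealogical prior;
  with few homoplasmic references and many ambiguous sites its posterior can
  be flat, and the reported maximum-posterior pair should then be read with
  its posterior value.
* The caller assumes peak height is proportional to template abundance
  within a site; real dye- and context-dependent height biases would shift
  the effective mixing-fraction detection limit of ~`r = 0.2`.
* `I_A`/`r̄_d` p-values assume exchangeability of alleles within a locus
  across isolates; strong population structure violates this, which is why
  per-population and clone-corrected modes exist.
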