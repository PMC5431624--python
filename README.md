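# mitohet

Tools for detecting and analysing **mitochondrial heteroplasmy** — the
coexistence of two mitochondrial genotypes in one individual — and testing for
**mitochondrial recombination** in population samples of haploid genotypes,
such as fungal fruiting-body collections sequenced at a handful of
mitochondrial loci (12S rRNA, COX1, COX3). It is aimed at population
geneticists who have Sanger-quality trace data and multilocus genotype tables
and want a reproducible, scriptable version of the classic analysis chain:

1. **Double-peak calling** (`mitohet.caller`) — a site is heteroplasmic when
   its two largest chromatogram peaks both exceed *k*× the local noise floor
   (windowed median of non-maximal channels, default *k* = 3, window ±5 sites)
   and the minor/major height ratio is at least *r* = 0.2. Calls use IUPAC
   ambiguity codes; singleton polymorphisms are flagged for re-inspection and
   putative heteroplasmy can be confirmed against a replicate read.
2. **Haplotype-mixture phasing** (`mitohet.phasing`) — heteroplasmic isolates
   are resolved into unordered haplotype pairs with an
   Excoffier–Slatkin-style EM over haplotype frequencies, using homoplasmic
   isolates as references, then classified as *local* (both haplotypes
   homoplasmic in the same population), *global* (homoplasmic somewhere in
   the whole sample) or *unexplained*.
3. **qPCR copy numbers** (`mitohet.qpcr`) — with a diploid nuclear reference
   gene (2 copies/cell) and perfect doubling, equal amplified mass at the
   detection threshold gives the target's per-cell copy number

   `N_m = (2 · L_n · 2^ct_n) / (L_m · 2^ct_m)`

   where `L` are amplicon lengths (bp) and `ct` the threshold cycles.
4. **Clonality / recombination statistics** (`mitohet.recomb`) — pairwise
   mismatch distances, the index of association `I_A = V_O/V_E − 1` and its
   locus-count-corrected form `r̄_d = (V_O − V_E)/(2·Σ_{j<k}√(var_j var_k))`,
   a within-locus allele-shuffling permutation null (default 500 shuffles),
   the generalized four-gamete / phylogenetic-compatibility test with PcP
   (proportion of compatible locus pairs), clone correction, and a
   sites-as-loci mode for intra-genic tests.
5. **Synthetic data** (`mitohet.simulate`) — clonal/panmictic/mixed genotype
   matrices, injected heteroplasmic mixtures with a known mixing fraction,
   four-channel trace profiles, and Ct panels generated from the same
   threshold model the estimator inverts, so every stage is testable
   end-to-end with no external data.

## Worked example

```python
from mitohet import simulate_trace, call_trace, het_sites, relative_copy_number
from mitohet.io import load_cox3_survey
from mitohet.phasing import classify_all

# 1. call double peaks on a simulated 60:40 two-haplotype mixture
profile = simulate_trace("ACGTACGTACGT", "ACGAACGTACTT", mixing_fraction=0.4,
                         signal=100, noise_sd=3, seed=2)
print(het_sites(call_trace(profile)))   # -> [4, 11]  (the two differing sites)

# 2. per-cell mitochondrial copy number from mean Ct values
print(round(relative_copy_number(17.80, 11.33, 140, 165), 1))  # -> 150.4

# 3. classify the packaged COX3 heteroplasmic genotypes
labels = [c.label for c in classify_all(load_cox3_survey())]
print(labels.count("local"), labels.count("unexplained"))      # -> 3 2
```

The first line shows the caller recovering exactly the two sites where the
haplotypes differ. The copy number (150.4 per cell, vs the nuclear gene's 2)
is typical of a mitochondrion-rich fungal cell. The classifier finds 3
distinct locally explainable heteroplasmic genotypes and 2 with no
homoplasmic source anywhere in the sample.

The same stages are available from the shell:

```sh
mitohet simulate --config design.yaml --out out/ --seed 1
mitohet call-het --trace out/trace.tsv --out calls.tsv
mitohet phase --calls calls.fasta --out phased.tsv
mitohet classify                      # packaged COX3 survey by default
mitohet copynumber --panel out/ct_panel.tsv --out copies.tsv
mitohet recomb --genotypes out/genotypes.tsv --out report.json --n-perm 500
mitohet recomb-sites --alignment aln.fasta --out sites.json
```

The YAML passed to `simulate` may contain `genotypes:` (n_isolates, loci with
alleles/freqs, mode, clonal_fraction, het_rate, mixing_fraction), `trace:`
(major_seq, minor_seq, mixing_fraction, signal, noise_sd) and `ct:`
(true_copies, lengths, ref_ct, replicate_sd, n_reps) sections; every output
carries a provenance header (version, seed, config hash).

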