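# haplodrift

Population-genetic analysis of mitochondrial DNA haplotype data from the
Norway rat (*Rattus norvegicus*), built for the question of how chemical
rodent control and the evolution of anticoagulant (warfarin) resistance
reshape mtDNA diversity. The package bundles three things that are usually
spread across separate tools (DnaSP/Arlequin-style statistics plus a bespoke
simulator):

1. **Haplotype data handling** — read aligned D-loop/cyt-b FASTA plus a
   sample-to-population table, collapse sequences into haplotypes (partial
   sequences assigned by the minimal-distance rule), and work with
   haplotype × population count tables. The published occurrence tables for
   39 cyt-b haplotypes (161 samples) and 25 D-loop haplotypes (239 samples)
   ship as packaged fixtures.
2. **Diversity and demographic statistics** — Nei's unbiased haplotype
   diversity *H* = *n*/(*n*−1)·(1 − Σᵢ *p*ᵢ²), nucleotide diversity π,
   private-haplotype counts, haplotype-frequency F_ST with a permutation
   test; mismatch distributions with the Rogers–Harpending sudden-expansion
   model (parameters τ, θ₀, θ₁; SSD and Harpending's raggedness index with
   parametric-bootstrap p-values); Tajima's *D*, Fu's *F*s (via the Ewens
   sampling formula with exact Stirling numbers) and Ramos-Onsins & Rozas's
   *R*₂, each tested against a hand-coded Kingman-coalescent null
   conditioned on the observed number of segregating sites.
3. **Forward Wright–Fisher simulation** of mtDNA haplotype drift under
   rodenticide-driven demography: a constant-size population (scenario L),
   a population crashed to N_ei by rodent control and held there (M), and a
   crash followed by the evolution of an overdominant autosomal resistance
   locus and census recovery (R). The simulator sweeps the initial
   frequency *i* of a focal haplotype and reports the smallest *i* at which
   the haplotype reaches an observed present-day frequency (0.72) with a
   given probability.
4. **Synthetic data generation** — alignments whose haplotype spectrum
   matches any count table and whose segregating-site structure comes from
   a coalescent or star genealogy, so that every statistical stage is
   testable without sequence downloads.

## Worked example

```python
import haplodrift as hd

# printed haplotype count tables
cytb = hd.load_printed_table("cytb")
print(round(hd.haplotype_diversity(cytb.counts["Germany"]), 2))  # 0.11
print(hd.haplotype_summary(cytb, "Asia"))                        # (32, 30)

dloop = hd.load_printed_table("dloop")
print(round(float(dloop.frequencies("Germany")["D1"]), 2))       # 0.72

# forward simulation: can pure drift explain a haplotype at 0.72?
model = hd.DemographicModel(scenario="L")          # constant Ne = 10,000
res = hd.threshold_initial_frequency(model, target=0.72, alpha=0.05, seed=1)
print(round(res.threshold, 2))                     # 0.46
```

The first numbers are the haplotype diversity of the German cyt-b sample
(3 haplotypes among 36 rats — extremely low), the haplotype and
private-haplotype counts of the Asian sample (the centre of diversity), and
the frequency of the most common D-loop haplotype in Germany. The last
number is the verdict on neutral drift: a haplotype must already have been
at frequency ≈ 0.46 when rats colonised Europe for it to reach 0.72 in 500
generations with even 5% probability in a stable population — whereas with
a 99% control-induced crash (scenario M, `Nei=100`) the required starting
frequency drops to ≈ 0.06, and with a crash plus resistance-driven recovery
(scenario R) to ≈ 0.11.

A `haplodrift` command-line tool mirrors the library (`collapse`,
`diversity`, `neutrality`, `mismatch`, `simulate`, `threshold`,
`synth table`, `synth align`); run `haplodrift --help`.

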